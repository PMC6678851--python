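"""Cross-alignment analysis of reference amplicons.

All-vs-all global-identity matrices over a labelled sequence set, a
closest-species report (for each species, the most similar strain of any
other species), flagging of species pairs confusable at the OTU threshold
(>97% identity over the marker), and a neighbor-joining convenience tree
on d = 100 - identity distances for dataset QC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

from .cluster_assign import global_identity

__all__ = [
    "identity_matrix",
    "closest_species",
    "flag_confusable",
    "nj_tree",
    "write_matrix_tsv",
]


def identity_matrix(seqs: dict[str, str]) -> pd.DataFrame:
    """All-vs-all percent-identity matrix (symmetric, diagonal 100).

    Each unordered pair is aligned once; duplicate labels are an error.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    labels = list(seqs)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    n = len(labels)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = global_identity(seqs[labels[i]], seqs[labels[j]])
            values[i, j] = values[j, i] = ident
    return pd.DataFrame(values, index=labels, columns=labels)


def closest_species(
    matrix: pd.DataFrame, species_map: dict[str, str]
) -> pd.DataFrame:
    """Per-species closest-other-species report.

    For every species, reports the maximum identity between any of its
    strains and any strain of any *other* species, and that species' name
    (alphabetically first on ties). Every matrix label must be mapped to a
    species. With fewer than two species the report is empty (there is no
    cross-species comparator).
    """
    unmapped = [l for l in matrix.index if l not in species_map]
    if unmapped:
        raise ValueError(f"labels missing from species map: {', '.join(unmapped)}")
    labels = list(matrix.index)
    species = sorted({species_map[l] for l in labels})
    rows = []
    for sp in species:
        own = [l for l in labels if species_map[l] == sp]
        best_ident, best_sp = -1.0, None
        for a in own:
            for b in labels:
                other = species_map[b]
                if other == sp:
                    continue
                ident = float(matrix.at[a, b])
                if ident > best_ident or (ident == best_ident and
                                          best_sp is not None and other < best_sp):
                    best_ident, best_sp = ident, other
        if best_sp is None:
            continue  # singleton dataset: nothing to compare against
        rows.append({"species": sp, "closest_species": best_sp,
                     "identity": best_ident})
    return pd.DataFrame(rows, columns=["species", "closest_species", "identity"])


def flag_confusable(report: pd.DataFrame, threshold: float = 97.0) -> pd.DataFrame:
    """Rows whose cross-species identity exceeds the clustering threshold.

    These are the species that cannot be told apart reliably over this
    marker and call for corroborating evidence from a second gene.
    """
    if report.empty:
        return report.copy()
    return report[report["identity"] > threshold].reset_index(drop=True)


def nj_tree(matrix: pd.DataFrame) -> str:
    """Neighbor-joining tree on d = 100 - identity, as a Newick string.

    A convenience topology for eyeballing dataset structure — no
    evolutionary-model correction is applied, so do not publish it as a
    phylogeny. Requires at least 3 taxa.
    """
    if len(matrix) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    dist = 100.0 - matrix.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dm = DistanceMatrix((dist + dist.T) / 2.0, ids=list(matrix.index))
    tree = nj(dm)
    return str(tree).strip()


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.4f")
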