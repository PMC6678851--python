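"""In-silico PCR: degenerate-primer site search and amplicon extraction.

Binding sites are located by exhaustive window scanning with an IUPAC-aware
mismatch count, a total-mismatch tolerance and a 3'-clamp (no mismatch in
the primer's 3'-terminal bases, where a real polymerase would fail to
extend). Amplicons are the template segments bounded by a forward site on
the plus strand and a reverse-primer site on the minus strand.

Coordinates are 0-based half-open throughout; the groEL literature's
1-based inclusive "340-824 bp" convention is converted only at the
reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .primers import IUPAC_CODES, PrimerPair, normalize, reverse_complement

__all__ = [
    "BindingSite",
    "Amplicon",
    "find_binding_sites",
    "amplify",
    "specificity_screen",
    "write_sites_bed",
    "read_templates_fasta",
]

#: Default product-length window: brackets the ~480 bp expected product
#: while tolerating synthetic variants.
DEFAULT_MIN_LEN = 100
DEFAULT_MAX_LEN = 2000


@dataclass(frozen=True)
class BindingSite:
    """A primer binding site on a template, 0-based half-open."""

    template_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """An in-silico PCR product.

    ``start`` is the first base of the forward-primer site; ``end`` is one
    past the last base of the reverse-primer site (0-based half-open on the
    plus strand of the template).
    """

    template_id: str
    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError("amplicon sequence length inconsistent with coordinates")


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    """Map a concrete DNA string to integer codes; non-ACGT -> 4 (never matches)."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return arr


def _allowed_matrix(primer: str) -> np.ndarray:
    """Boolean (len(primer), 5) matrix: allowed[i, code] for each window base."""
    allowed = np.zeros((len(primer), 5), dtype=bool)
    for i, sym in enumerate(primer):
        for base in IUPAC_CODES[sym]:
            allowed[i, _BASE_INDEX[base]] = True
    return allowed


def find_binding_sites(
    template: str,
    primer: str,
    max_mismatches: int = 2,
    clamp_len: int = 3,
    strand: str = "+",
    template_id: str = "",
) -> list[BindingSite]:
    """Locate all binding sites of a degenerate primer on one template strand.

    On the plus strand the primer is matched 5'→3' against template
    windows directly; on the minus strand its reverse complement is
    matched, so the primer's 3' end maps to the *left* edge of the reported
    window. A window qualifies when its total mismatch count is at most
    ``max_mismatches`` and no mismatch falls within ``clamp_len`` bases of
    the primer's 3' end. Sites are returned sorted by start coordinate.

    A template shorter than the primer yields an empty list.
    """
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    template = normalize(template)
    primer = normalize(primer)
    L = len(primer)
    if len(template) < L:
        return []

    pattern = primer if strand == "+" else reverse_complement(primer)
    allowed = _allowed_matrix(pattern)
    codes = _encode(template)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    match = allowed[np.arange(L)[None, :], windows]  # (n_windows, L) bool
    mm_total = (~match).sum(axis=1)
    # 3'-clamp: last clamp_len pattern positions on '+', first on '-'.
    clamp = min(clamp_len, L)
    if clamp > 0:
        clamp_slice = match[:, L - clamp:] if strand == "+" else match[:, :clamp]
        clamp_ok = clamp_slice.all(axis=1)
    else:
        clamp_ok = np.ones(len(windows), dtype=bool)
    hits = np.nonzero((mm_total <= max_mismatches) & clamp_ok)[0]
    return [
        BindingSite(template_id, int(s), int(s) + L, strand, int(mm_total[s]))
        for s in hits
    ]


def _paired_spans(
    template: str, pair: PrimerPair, min_len: int, max_len: int
) -> list[tuple[int, int]]:
    """(start, end) spans with the forward primer on the plus strand."""
    fwd = find_binding_sites(
        template, pair.forward, pair.max_mismatches, pair.clamp_len, "+"
    )
    rev = find_binding_sites(
        template, pair.reverse, pair.max_mismatches, pair.clamp_len, "-"
    )
    if not fwd or not rev:
        return []

    def nearest_downstream(f: BindingSite) -> BindingSite | None:
        cands = [r for r in rev if r.start >= f.end]
        return min(cands, key=lambda r: r.start) if cands else None

    def nearest_upstream(r: BindingSite) -> BindingSite | None:
        cands = [f for f in fwd if f.end <= r.start]
        return max(cands, key=lambda f: f.start) if cands else None

    spans = []
    for f in fwd:
        r = nearest_downstream(f)
        if r is None or nearest_upstream(r) != f:
            continue
        if min_len <= r.end - f.start <= max_len:
            spans.append((f.start, r.end))
    return spans


def amplify(
    template: str,
    pair: PrimerPair,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    template_id: str = "",
) -> list[Amplicon]:
    """Predict PCR products of a primer pair on one template.

    Both template orientations are examined (a PCR product forms whichever
    strand carries the forward site), so the product set is invariant under
    reverse-complementing the template up to mirrored coordinates. Within
    one orientation, sites are paired mutual-nearest: a product is emitted
    for a (forward, reverse) pair iff the reverse site is the forward
    site's nearest non-overlapping downstream reverse site *and* the
    forward site is that reverse site's nearest upstream forward site —
    the shortest product dominates when several primers could pair, as it
    does in a real reaction. Products outside [min_len, max_len] are
    discarded.

    Coordinates are reported on the input's plus strand; ``sequence`` is
    always given forward-primer-first (reverse-complemented relative to
    the input for minus-orientation products).
    """
    if min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    template = normalize(template)
    n = len(template)
    products: dict[tuple[int, int, str], Amplicon] = {}
    for start, end in _paired_spans(template, pair, min_len, max_len):
        seq = template[start:end]
        products[(start, end, seq)] = Amplicon(template_id, start, end, seq)
    rc = reverse_complement(template)
    for start, end in _paired_spans(rc, pair, min_len, max_len):
        key = (n - end, n - start, rc[start:end])
        products.setdefault(key, Amplicon(template_id, n - end, n - start,
                                          rc[start:end]))
    return [products[k] for k in sorted(products)]


def specificity_screen(
    templates: dict[str, str],
    pair: PrimerPair,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> pd.DataFrame:
    """Amplification screen across a named template set.

    Returns one row per template with its product count and product
    lengths; a count of 0 marks non-amplifying templates (e.g. taxa
    outside the Lactobacillus Genus Complex).
    """
    if not templates:
        raise ValueError("template set must be non-empty")
    ids = list(templates)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate template ids")
    rows = []
    for tid in ids:
        amps = amplify(templates[tid], pair, min_len, max_len, template_id=tid)
        rows.append(
            {
                "template_id": tid,
                "amplicon_count": len(amps),
                "lengths": ",".join(str(a.length) for a in amps),
            }
        )
    return pd.DataFrame(rows)


def read_templates_fasta(path) -> dict[str, str]:
    """Read templates from FASTA; duplicate ids are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate template id {rec.id!r}")
        out[rec.id] = normalize(str(rec.seq))
    return out


def write_sites_bed(sites: list[BindingSite], path) -> None:
    """BED-like TSV: template, start, end, strand, mismatches."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.template_id}\t{s.start}\t{s.end}\t{s.strand}\t{s.mismatches}\n")
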