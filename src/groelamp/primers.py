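"""Degenerate-primer algebra over the IUPAC nucleotide alphabet.

The Lactobacillus groEL profiling primers are written with IUPAC ambiguity
codes (Y = C/T, W = A/T, V = A/C/G, N = any base), each degenerate primer
standing for a pool of concrete oligonucleotides.  This module provides the
primitives the rest of the package builds on: expansion of a degenerate
sequence into its concrete pool, IUPAC-aware reverse complementation,
mismatch counting of a concrete window against a degenerate pattern, and
per-column conservation profiling (sequence-logo statistics) of an
alignment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "IUPAC_CODES",
    "IUPAC_COMPLEMENT",
    "AlphabetError",
    "PrimerPair",
    "LAC_GROEL",
    "normalize",
    "degeneracy",
    "expand_degenerate",
    "reverse_complement",
    "count_mismatches",
    "conservation_profile",
    "conservation_profile_from_fasta",
    "write_profile_tsv",
]

#: The 15 IUPAC nucleotide symbols and the concrete bases each stands for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Symbol-wise Watson-Crick complement; closed over the 15-symbol alphabet.
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

GAP_CHARS = frozenset("-.")


class AlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""


def normalize(seq: str) -> str:
    """Uppercase a sequence and convert RNA-style U to T.

    Public groEL records vary in case and occasionally use U; every entry
    point funnels input through this.
    """
    return seq.upper().replace("U", "T")


def _validate(seq: str, *, allow_gaps: bool = False) -> str:
    seq = normalize(seq)
    for i, ch in enumerate(seq):
        if ch in IUPAC_CODES:
            continue
        if allow_gaps and ch in GAP_CHARS:
            continue
        raise AlphabetError(
            f"invalid IUPAC symbol {ch!r} at position {i} (0-based)"
        )
    return seq


def degeneracy(seq: str) -> int:
    """Number of concrete sequences a degenerate sequence stands for."""
    seq = _validate(seq)
    n = 1
    for ch in seq:
        n *= len(IUPAC_CODES[ch])
    return n


def expand_degenerate(seq: str) -> set[str]:
    """Expand a degenerate IUPAC sequence into its set of concrete sequences.

    The result is the Cartesian product of the per-symbol base sets; its
    size equals :func:`degeneracy`.

    Raises
    ------
    AlphabetError
        If the sequence is empty or contains a non-IUPAC character.
    """
    seq = _validate(seq)
    if not seq:
        raise AlphabetError("cannot expand an empty sequence")
    pools = [sorted(IUPAC_CODES[ch]) for ch in seq]
    return {"".join(p) for p in itertools.product(*pools)}


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (an involution on valid input)."""
    seq = _validate(seq)
    return "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(seq))


def count_mismatches(primer: str, window: str) -> int:
    """Count positions where a concrete window is incompatible with a primer.

    A position matches when the window's base belongs to the primer
    symbol's IUPAC base set, so degenerate positions tolerate any of their
    encoded bases at zero cost.

    Raises
    ------
    ValueError
        If the two sequences differ in length.
    """
    primer = _validate(primer)
    window = _validate(window)
    if len(primer) != len(window):
        raise ValueError(
            f"primer length {len(primer)} != window length {len(window)}"
        )
    return sum(1 for p, w in zip(primer, window) if w not in IUPAC_CODES[p])


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate forward/reverse primer pair with matching parameters.

    Parameters
    ----------
    name : str
        Free-text identifier.
    forward, reverse : str
        Primer sequences, 5'→3', IUPAC alphabet.
    max_mismatches : int
        Total mismatches tolerated when locating a binding site.
    clamp_len : int
        Number of 3'-terminal primer bases in which no mismatch is allowed
        (a PRIMER-BLAST-style extension clamp).
    """

    name: str
    forward: str
    reverse: str
    max_mismatches: int = 2
    clamp_len: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward", _validate(self.forward))
        object.__setattr__(self, "reverse", _validate(self.reverse))
        if not self.forward or not self.reverse:
            raise AlphabetError("primer sequences must be non-empty")
        if self.max_mismatches < 0 or self.clamp_len < 0:
            raise ValueError("max_mismatches and clamp_len must be >= 0")


#: The Lactobacillus groEL profiling pair (Lac_groEL_F / Lac_groEL_R),
#: targeting the hypervariable 340-824 bp region of the groEL gene.
LAC_GROEL = PrimerPair(
    name="Lac_groEL",
    forward="GCYGGTGCWAACCCNGTTGG",
    reverse="AANGTNCCVCGVATCTTGTT",
)


@dataclass
class ConservationProfile:
    """Per-column base frequencies and information content of an alignment.

    ``table`` has one row per alignment column (1-based index ``column``)
    with columns A, C, G, T (frequencies over non-gap characters; NaN for
    all-gap columns) and ``bits`` (information content ``2 - H`` with
    Shannon entropy H in bits; NaN where undefined).
    """

    table: pd.DataFrame = field(repr=False)

    @property
    def n_columns(self) -> int:
        return len(self.table)


def conservation_profile(aligned_seqs: list[str]) -> ConservationProfile:
    """Column-wise conservation statistics of an aligned set of sequences.

    Gaps (``-`` or ``.``) are excluded from each column's denominator, as
    in a standard sequence logo; ambiguity codes other than A/C/G/T are
    likewise excluded from the counts. Zero frequencies contribute zero
    entropy (0·log0 := 0). An all-gap column has undefined frequencies and
    information, reported as NaN.
    """
    if len(aligned_seqs) < 2:
        raise ValueError("need at least 2 sequences for a profile")
    seqs = [_validate(s, allow_gaps=True) for s in aligned_seqs]
    ncol = len(seqs[0])
    for s in seqs:
        if len(s) != ncol:
            raise ValueError("aligned sequences must have equal lengths")

    rows = []
    for j in range(ncol):
        counts = {b: 0 for b in "ACGT"}
        for s in seqs:
            if s[j] in counts:
                counts[s[j]] += 1
        total = sum(counts.values())
        if total == 0:
            rows.append({"column": j + 1, "A": np.nan, "C": np.nan,
                         "G": np.nan, "T": np.nan, "bits": np.nan})
            continue
        freqs = {b: c / total for b, c in counts.items()}
        h = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        rows.append({"column": j + 1, **freqs, "bits": 2.0 - h})
    return ConservationProfile(pd.DataFrame(rows))


def conservation_profile_from_fasta(path) -> ConservationProfile:
    """Profile an aligned FASTA file (plain text)."""
    seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    return conservation_profile(seqs)


def write_profile_tsv(profile: ConservationProfile, path) -> None:
    profile.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
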