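"""Read processing: quality filtering, paired-end merging, primer trimming.

Implements the amplicon-sequencing read-processing rules used throughout
the package: reads are kept when their mean Phred quality exceeds 30, a
pair merges when its two reads share an exact suffix/prefix overlap longer
than 10 bp, and primer windows are removed from both ends of the merged
product before classification.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .primers import PrimerPair, count_mismatches, normalize, reverse_complement

__all__ = [
    "ReadRecord",
    "MergedRead",
    "Rejection",
    "quality_filter",
    "merge_pairs",
    "merge_all",
    "trim_primers",
    "trim_all",
    "read_fastq",
    "write_fastq",
    "write_rejection_log",
]

MAX_PHRED = 93


@dataclass
class ReadRecord:
    """A single read with per-base Phred scores (Sanger / Illumina 1.8+)."""

    id: str
    seq: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(f"{self.id}: sequence and quality lengths differ")
        if self.quals and not all(0 <= q <= MAX_PHRED for q in self.quals):
            raise ValueError(f"{self.id}: Phred scores must be in [0, {MAX_PHRED}]")

    @property
    def mean_quality(self) -> float:
        return sum(self.quals) / len(self.quals) if self.quals else 0.0


@dataclass
class MergedRead:
    id: str
    seq: str
    quals: list[int]
    overlap_len: int
    r1_id: str
    r2_id: str


@dataclass(frozen=True)
class Rejection:
    """One rejected read with the pipeline stage and reason."""

    id: str
    stage: str
    reason: str


def quality_filter(
    reads: list[ReadRecord], min_mean_q: float = 30.0
) -> tuple[list[ReadRecord], list[Rejection]]:
    """Keep reads whose mean Phred quality is strictly greater than the cutoff.

    The criterion is per-read mean quality, read strictly ("higher than
    30"), so a read at exactly the cutoff is rejected. Input order is
    preserved.
    """
    kept, rejects = [], []
    for r in reads:
        if r.mean_quality > min_mean_q:
            kept.append(r)
        else:
            rejects.append(
                Rejection(r.id, "quality_filter",
                          f"mean quality {r.mean_quality:.2f} <= {min_mean_q:g}")
            )
    return kept, rejects


def merge_pairs(
    r1: ReadRecord,
    r2: ReadRecord,
    min_overlap: int = 11,
    max_overlap_mismatch: int = 0,
) -> MergedRead | Rejection:
    """Merge a read pair by its suffix/prefix overlap.

    ``r2`` is supplied in raw (reverse-strand) orientation and is
    reverse-complemented internally. The longest overlap of length >=
    ``min_overlap`` between the 3' end of ``r1`` and the 5' end of the
    reverse-complemented ``r2`` with at most ``max_overlap_mismatch``
    mismatching bases determines the merge (the default of 0 enforces the
    ">10 bp overlap, no mismatch" splicing condition). Within the overlap
    the base with the higher Phred score is taken and the merged quality
    is the maximum of the two.
    """
    s1 = normalize(r1.seq)
    s2 = reverse_complement(normalize(r2.seq))
    q2 = list(reversed(r2.quals))
    max_ov = min(len(s1), len(s2))
    for ov in range(max_ov, min_overlap - 1, -1):
        tail, head = s1[len(s1) - ov:], s2[:ov]
        if max_overlap_mismatch == 0:
            if tail != head:
                continue
            n_mm = 0
        else:
            n_mm = sum(1 for a, b in zip(tail, head) if a != b)
            if n_mm > max_overlap_mismatch:
                continue
        # build the merged read over the overlap
        seq = list(s1[: len(s1) - ov])
        quals = list(r1.quals[: len(s1) - ov])
        for k in range(ov):
            i1 = len(s1) - ov + k
            b1, b2 = s1[i1], s2[k]
            qa, qb = r1.quals[i1], q2[k]
            seq.append(b1 if qa >= qb else b2)
            quals.append(max(qa, qb))
        seq.extend(s2[ov:])
        quals.extend(q2[ov:])
        return MergedRead(r1.id, "".join(seq), quals, ov, r1.id, r2.id)
    return Rejection(r1.id, "merge",
                     f"no overlap of >= {min_overlap} bases with <= "
                     f"{max_overlap_mismatch} mismatches")


def merge_all(
    pairs: list[tuple[ReadRecord, ReadRecord]],
    min_overlap: int = 11,
    max_overlap_mismatch: int = 0,
) -> tuple[list[MergedRead], list[Rejection]]:
    merged, rejects = [], []
    for r1, r2 in pairs:
        out = merge_pairs(r1, r2, min_overlap, max_overlap_mismatch)
        (merged if isinstance(out, MergedRead) else rejects).append(out)
    return merged, rejects


def trim_primers(
    merged: MergedRead | str,
    pair: PrimerPair,
    max_mismatches: int | None = None,
) -> str | Rejection:
    """Remove the primer windows from a merged amplicon sequence.

    The forward primer must match the sequence prefix and the reverse
    complement of the reverse primer the suffix, each within the pair's
    mismatch tolerance (no 3'-clamp here: the clamp models polymerase
    extension, not recognition of primer bases already sequenced). Returns
    the inner insert, or a :class:`Rejection` when either primer is
    absent. Trimming is idempotent in the sense that the insert of a
    trimmed read no longer carries primer hits.
    """
    if max_mismatches is None:
        max_mismatches = pair.max_mismatches
    seq = merged.seq if isinstance(merged, MergedRead) else normalize(merged)
    rid = merged.id if isinstance(merged, MergedRead) else "<seq>"
    f, r = pair.forward, reverse_complement(pair.reverse)
    if len(seq) < len(f) + len(r):
        return Rejection(rid, "trim_primers", "shorter than the two primers")
    if count_mismatches(f, seq[: len(f)]) > max_mismatches:
        return Rejection(rid, "trim_primers", "forward primer not found at 5' end")
    if count_mismatches(r, seq[len(seq) - len(r):]) > max_mismatches:
        return Rejection(rid, "trim_primers", "reverse primer not found at 3' end")
    return seq[len(f): len(seq) - len(r)]


def trim_all(
    merged: list[MergedRead], pair: PrimerPair
) -> tuple[list[tuple[str, str]], list[Rejection]]:
    """Trim a batch; returns (read id, insert) pairs plus the rejection log."""
    kept, rejects = [], []
    for m in merged:
        out = trim_primers(m, pair)
        if isinstance(out, Rejection):
            rejects.append(out)
        else:
            kept.append((m.id, out))
    return kept, rejects


def _open_maybe_gzip(path, mode="rt"):
    return gzip.open(path, mode) if str(path).endswith(".gz") else open(path, mode)


def read_fastq(path) -> list[ReadRecord]:
    """Read a (possibly gzipped) Sanger/Illumina-1.8+ FASTQ file."""
    with _open_maybe_gzip(path) as fh:
        return [
            ReadRecord(rec.id, str(rec.seq),
                       list(rec.letter_annotations["phred_quality"]))
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(reads: list[ReadRecord], path) -> None:
    with _open_maybe_gzip(path, "wt") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = list(r.quals)
            SeqIO.write(rec, fh, "fastq")


def write_rejection_log(rejects: list[Rejection], path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tstage\treason\n")
        for rj in rejects:
            fh.write(f"{rj.id}\t{rj.stage}\t{rj.reason}\n")
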