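"""OTU clustering at 97% identity and species-level assignment.

Merged, primer-trimmed reads are dereplicated into unique sequences with
counts, clustered by abundance-sorted greedy centroid clustering at 97%
global identity (the classic closed-reference-free OTU picking scheme),
and each OTU centroid is classified by best-hit global alignment against
the reference amplicon inserts. Identity between two sequences is defined
MatGAT-style: matches divided by aligned columns, terminal gaps excluded,
from a Needleman-Wunsch global alignment (match +1, mismatch -1, gap open
2 plus 1 per gapped column, end gaps free).

Reporting conventions follow the field's abundance-table layout: named
species below 1% relative abundance in a sample are pooled into
"other Lactobacillus <1%", and OTUs without a confident species hit are
reported as "unassigned".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from skbio.alignment import pair_align

from .refdb import ReferenceDB

__all__ = [
    "UNASSIGNED",
    "OTHER_LABEL",
    "DereplicatedSeq",
    "OTU",
    "TaxonomyAssignment",
    "global_identity",
    "dereplicate",
    "greedy_cluster",
    "assign_taxonomy",
    "abundance_table",
]

UNASSIGNED = "unassigned"
OTHER_LABEL = "other Lactobacillus <1%"

#: Unit-cost-style scoring used for all identity computations.
MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_OPEN = 2.0
GAP_EXTEND = 1.0


def _align(a: str, b: str) -> tuple[float, str, str]:
    """Global alignment (free end gaps); returns (score, aligned a, aligned b)."""
    res = pair_align(
        a, b,
        mode="global",
        sub_score=(MATCH_SCORE, MISMATCH_SCORE),
        gap_cost=(GAP_OPEN, GAP_EXTEND),
        free_ends=True,
        max_paths=1,
    )
    s1, s2 = res.paths[0].to_aligned((a, b))
    return float(res.score), s1, s2


def global_identity(a: str, b: str) -> float:
    """Percent identity of two sequences under global alignment.

    identity = 100 x matches / aligned columns, where terminal-gap columns
    (overhangs of either sequence) are excluded from the denominator so
    that length-truncated reads are not penalized. Symmetric in its
    arguments.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    _, s1, s2 = _align(a, b)
    # strip terminal gap columns: first/last column where both are residues
    n = len(s1)
    lo = 0
    while lo < n and (s1[lo] == "-" or s2[lo] == "-"):
        lo += 1
    hi = n
    while hi > lo and (s1[hi - 1] == "-" or s2[hi - 1] == "-"):
        hi -= 1
    if hi == lo:  # alignment is pure overhang (disjoint placement)
        return 0.0
    matches = sum(1 for i in range(lo, hi) if s1[i] == s2[i] and s1[i] != "-")
    return 100.0 * matches / (hi - lo)


@dataclass
class DereplicatedSeq:
    """A unique sequence with its read count and member read ids."""

    seq: str
    count: int
    member_ids: list[str] = field(default_factory=list)


@dataclass
class OTU:
    """An operational taxonomic unit: a centroid plus its members.

    The centroid is the founding (highest-count) unique sequence; every
    member joined with identity >= the clustering threshold to it.
    """

    otu_id: str
    centroid_seq: str
    members: list[DereplicatedSeq] = field(default_factory=list)
    member_identities: list[float] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(m.count for m in self.members)


@dataclass
class TaxonomyAssignment:
    otu_id: str
    label: str
    best_identity: float
    best_accession: str | None
    tie: bool = False


def dereplicate(reads: list[tuple[str, str]]) -> list[DereplicatedSeq]:
    """Collapse identical sequences into unique sequences with counts.

    ``reads`` are (read id, sequence) pairs. The result is sorted by
    decreasing count, ties broken by lexicographic sequence order — the
    deterministic insertion order used by greedy clustering.
    """
    by_seq: dict[str, DereplicatedSeq] = {}
    for rid, seq in reads:
        d = by_seq.get(seq)
        if d is None:
            by_seq[seq] = DereplicatedSeq(seq, 1, [rid])
        else:
            d.count += 1
            d.member_ids.append(rid)
    return sorted(by_seq.values(), key=lambda d: (-d.count, d.seq))


def greedy_cluster(
    dereps: list[DereplicatedSeq], threshold: float = 97.0
) -> list[OTU]:
    """Abundance-sorted greedy centroid clustering.

    Unique sequences are processed in decreasing count order (ties by
    lexicographic sequence order). Each joins the first existing centroid
    (in founding order) with global identity >= ``threshold``, otherwise
    it founds a new OTU — so all centroids are pairwise below the
    threshold at founding time. Read counts are conserved by construction.
    """
    if not dereps:
        raise ValueError("no sequences to cluster")
    order = sorted(dereps, key=lambda d: (-d.count, d.seq))
    otus: list[OTU] = []
    for d in order:
        placed = False
        for otu in otus:
            if d.seq == otu.centroid_seq:
                ident = 100.0
            else:
                ident = global_identity(d.seq, otu.centroid_seq)
            if ident >= threshold:
                otu.members.append(d)
                otu.member_identities.append(ident)
                placed = True
                break
        if not placed:
            otu = OTU(f"OTU_{len(otus) + 1}", d.seq)
            otu.members.append(d)
            otu.member_identities.append(100.0)
            otus.append(otu)
    return otus


def assign_taxonomy(
    otus: list[OTU], db: ReferenceDB, min_identity: float = 97.0
) -> list[TaxonomyAssignment]:
    """Best-hit species assignment of OTU centroids against the database.

    Each centroid is aligned to every usable reference insert (amplicon
    minus primer windows — centroids are primer-trimmed, so both sides are
    on the same footing). The best hit assigns its species label when its
    identity is >= ``min_identity``. When the best identity is shared by
    hits carrying different species labels, the OTU is reported
    "unassigned" with the tie flag set: several Lactobacillus species are
    literally identical over this marker region, and silently picking one
    would fabricate precision.
    """
    targets = db.ok_records()
    if not targets:
        raise ValueError("reference database has no usable (ok) records")
    inserts = [(r, db.insert_seq(r)) for r in targets]
    out: list[TaxonomyAssignment] = []
    for otu in otus:
        best = -1.0
        best_records: list = []
        for rec, ins in inserts:
            ident = 100.0 if otu.centroid_seq == ins else global_identity(
                otu.centroid_seq, ins)
            if ident > best:
                best, best_records = ident, [rec]
            elif ident == best:
                best_records.append(rec)
        labels = {r.species_label for r in best_records}
        acc = best_records[0].accession
        if best < min_identity:
            out.append(TaxonomyAssignment(otu.otu_id, UNASSIGNED, best, acc))
        elif len(labels) > 1:
            out.append(TaxonomyAssignment(otu.otu_id, UNASSIGNED, best, acc, tie=True))
        else:
            out.append(TaxonomyAssignment(otu.otu_id, labels.pop(), best, acc))
    return out


def abundance_table(
    assignments: list[TaxonomyAssignment],
    counts: dict[str, dict[str, int]],
    group_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-sample species-level relative abundance table.

    ``counts`` maps sample name → {otu_id: read count}. Per sample, the
    relative abundance of each species label is the summed count of its
    OTUs divided by the sample total. Named species below
    ``group_threshold`` in a sample are pooled into the reserved
    "other Lactobacillus <1%" column for that sample; "unassigned" is kept
    separate and never pooled. Rows sum to 1 by construction. Columns are
    ordered by decreasing mean abundance with the reserved labels last.
    """
    label_of = {a.otu_id: a.label for a in assignments}
    rows: dict[str, dict[str, float]] = {}
    for sample, otu_counts in counts.items():
        total = sum(otu_counts.values())
        if total <= 0:
            raise ValueError(f"sample {sample!r} has no reads")
        per_label: dict[str, float] = {}
        for otu_id, c in otu_counts.items():
            if c < 0:
                raise ValueError("counts must be positive")
            lbl = label_of.get(otu_id, UNASSIGNED)
            per_label[lbl] = per_label.get(lbl, 0.0) + c / total
        pooled: dict[str, float] = {}
        for lbl, frac in per_label.items():
            if lbl != UNASSIGNED and frac < group_threshold:
                pooled[OTHER_LABEL] = pooled.get(OTHER_LABEL, 0.0) + frac
            else:
                pooled[lbl] = pooled.get(lbl, 0.0) + frac
        rows[sample] = pooled
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    named = [c for c in df.columns if c not in (OTHER_LABEL, UNASSIGNED)]
    named.sort(key=lambda c: (-df[c].mean(), c))
    ordered = named + [c for c in (OTHER_LABEL, UNASSIGNED) if c in df.columns]
    df = df[ordered]
    df.index.name = "sample"
    return df
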