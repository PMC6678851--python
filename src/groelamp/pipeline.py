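"""End-to-end profiling pipeline: reads in, abundance table out.

Thin orchestration over the reads / cluster_assign modules with the
marker's standard parameters (mean Q > 30, overlap > 10 bp with no
mismatch, 97% OTU clustering and assignment identity, <1% grouping).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from . import cluster_assign, reads as reads_mod
from .cluster_assign import UNASSIGNED, TaxonomyAssignment, OTU
from .reads import ReadRecord, Rejection
from .refdb import ReferenceDB

__all__ = ["PipelineConfig", "ProfileResult", "profile_pairs"]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds of the profiling workflow (defaults = printed parameters)."""

    min_mean_q: float = 30.0
    min_overlap: int = 11
    max_overlap_mismatch: int = 0
    cluster_threshold: float = 97.0
    assign_min_identity: float = 97.0
    group_threshold: float = 0.01
    sample_name: str = "sample"

    def __post_init__(self) -> None:
        if not (0 <= self.min_mean_q <= 93):
            raise ValueError("min_mean_q must be in [0, 93]")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.max_overlap_mismatch < 0:
            raise ValueError("max_overlap_mismatch must be >= 0")
        for name in ("cluster_threshold", "assign_min_identity"):
            v = getattr(self, name)
            if not (0 < v <= 100):
                raise ValueError(f"{name} must be in (0, 100]")
        if not (0 <= self.group_threshold < 1):
            raise ValueError("group_threshold must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class ProfileResult:
    """Outputs and bookkeeping of one profiling run."""

    otus: list[OTU]
    assignments: list[TaxonomyAssignment]
    table: "object"  # pandas DataFrame: samples x labels, grouped
    species_fractions: dict[str, float]  # named species, ungrouped
    species_read_counts: dict[str, int]
    unassigned_reads: int
    merged_count: int
    input_pairs: int
    rejections: list[Rejection] = field(repr=False, default_factory=list)


def profile_pairs(
    r1: list[ReadRecord],
    r2: list[ReadRecord],
    db: ReferenceDB,
    cfg: PipelineConfig = PipelineConfig(),
) -> ProfileResult:
    """Run the full profiling workflow on one sample's read pairs.

    A pair is processed only when both mates pass the quality filter; the
    surviving pairs are merged, primer-trimmed, dereplicated, clustered
    into OTUs and classified against the database. Fractions in
    ``species_fractions`` are per named species over all clustered reads
    (no <1% pooling); the pooled presentation lives in ``table``.
    """
    if len(r1) != len(r2):
        raise ValueError("R1 and R2 read lists differ in length")
    rejections: list[Rejection] = []
    pairs = []
    for a, b in zip(r1, r2):
        _, rej_a = reads_mod.quality_filter([a], cfg.min_mean_q)
        _, rej_b = reads_mod.quality_filter([b], cfg.min_mean_q)
        if rej_a or rej_b:
            rejections.extend(rej_a + rej_b)
            continue
        pairs.append((a, b))

    merged, rej = reads_mod.merge_all(pairs, cfg.min_overlap,
                                      cfg.max_overlap_mismatch)
    rejections.extend(rej)
    trimmed, rej = reads_mod.trim_all(merged, db.primer_pair)
    rejections.extend(rej)
    if not trimmed:
        raise ValueError("no reads survived merging and primer trimming")

    dereps = cluster_assign.dereplicate(trimmed)
    otus = cluster_assign.greedy_cluster(dereps, cfg.cluster_threshold)
    assignments = cluster_assign.assign_taxonomy(otus, db,
                                                 cfg.assign_min_identity)
    counts = {cfg.sample_name: {o.otu_id: o.total_count for o in otus}}
    table = cluster_assign.abundance_table(assignments, counts,
                                           cfg.group_threshold)

    label_of = {a.otu_id: a.label for a in assignments}
    total = sum(o.total_count for o in otus)
    read_counts: dict[str, int] = {}
    for o in otus:
        lbl = label_of[o.otu_id]
        read_counts[lbl] = read_counts.get(lbl, 0) + o.total_count
    unassigned = read_counts.get(UNASSIGNED, 0)
    fractions = {lbl: c / total for lbl, c in read_counts.items()
                 if lbl != UNASSIGNED}
    return ProfileResult(
        otus=otus,
        assignments=assignments,
        table=table,
        species_fractions=fractions,
        species_read_counts=read_counts,
        unassigned_reads=unassigned,
        merged_count=len(merged),
        input_pairs=len(r1),
        rejections=rejections,
    )
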