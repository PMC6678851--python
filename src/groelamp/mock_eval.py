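"""Mock-community accuracy evaluation.

A mock community is a defined mixture of strains at known DNA masses. This
module converts masses to groEL gene copy numbers (the standard dsDNA
mass-to-copies formula, 650 g/mol per bp — groEL is single-copy in
Lactobacillus so copies stand in for cfu), derives the expected community
composition, regresses observed against expected relative abundances
(ordinary least squares of y on x, as in the accuracy benchmark of the
profiling method), and scans a dilution series for the detection limit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .refdb import ReferenceDB

__all__ = [
    "AVOGADRO",
    "BP_MASS_G_PER_MOL",
    "MockStrain",
    "MockSpec",
    "MockEvalResult",
    "copies_from_mass",
    "expected_composition",
    "regress_observed_expected",
    "run_mock_experiment",
    "detection_limit_scan",
]

AVOGADRO = 6.022e23
#: Average mass of one double-stranded base pair, g/mol.
BP_MASS_G_PER_MOL = 650.0


def copies_from_mass(mass_ng: float, length_bp: float) -> float:
    """Template copy number from DNA mass and template length.

    copies = mass_ng x 6.022e23 / (length_bp x 1e9 x 650)

    Linear in mass and inversely proportional to length. For genomic DNA,
    ``length_bp`` is the genome size and the result counts genome (hence
    single-copy-gene) copies.
    """
    if length_bp <= 0:
        raise ValueError("template length must be positive")
    if mass_ng < 0:
        raise ValueError("mass must be non-negative")
    return mass_ng * AVOGADRO / (length_bp * 1e9 * BP_MASS_G_PER_MOL)


@dataclass(frozen=True)
class MockStrain:
    accession: str
    species: str
    dna_mass_ng: float
    template_length_bp: float

    @property
    def copies(self) -> float:
        return copies_from_mass(self.dna_mass_ng, self.template_length_bp)


@dataclass
class MockSpec:
    """Per-strain DNA masses and template lengths defining a mock community."""

    strains: list[MockStrain] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.strains:
            if s.dna_mass_ng < 0:
                raise ValueError(f"{s.accession}: mass must be >= 0")
            if s.template_length_bp <= 0:
                raise ValueError(f"{s.accession}: template length must be > 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([s.__dict__ for s in self.strains], fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MockSpec":
        with open(path) as fh:
            return cls([MockStrain(**d) for d in json.load(fh)])


def expected_composition(spec: MockSpec) -> dict[str, float]:
    """Expected per-species fractions: copies_i / sum(copies), summing to 1."""
    if not spec.strains:
        raise ValueError("mock spec has no strains")
    copies: dict[str, float] = {}
    for s in spec.strains:
        copies[s.species] = copies.get(s.species, 0.0) + s.copies
    total = sum(copies.values())
    if total <= 0:
        raise ValueError("all strain masses are zero")
    return {sp: c / total for sp, c in copies.items()}


@dataclass
class MockEvalResult:
    """OLS fit of observed (y) on expected (x) relative abundances."""

    slope: float
    intercept: float
    r_squared: float
    table: pd.DataFrame = field(repr=False)

    def to_json(self, path) -> None:
        payload = {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "species": self.table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def regress_observed_expected(
    observed: dict[str, float], expected: dict[str, float]
) -> MockEvalResult:
    """Ordinary least squares of observed on expected fractions.

    Species are matched by label over the union of the two mappings
    (absent entries count as 0, e.g. a species sequenced below the
    detection limit). Requires at least two species and non-degenerate
    expected values.
    """
    labels = sorted(set(observed) | set(expected))
    if len(labels) < 2:
        raise ValueError("need at least 2 species for a regression")
    x = np.array([expected.get(l, 0.0) for l in labels])
    y = np.array([observed.get(l, 0.0) for l in labels])
    if np.allclose(x, x[0]):
        raise ValueError("expected fractions have zero variance")
    fit = stats.linregress(x, y)
    table = pd.DataFrame({"species": labels, "expected": x, "observed": y})
    return MockEvalResult(float(fit.slope), float(fit.intercept),
                          float(fit.rvalue) ** 2, table)


def run_mock_experiment(
    seed: int,
    depth: int = 20000,
    substitution_rate: float = 0.005,
    n_species: int = 9,
) -> MockEvalResult:
    """End-to-end accuracy benchmark on a synthetic mock community.

    Generates a seeded nine-species reference set and mock community
    (masses geometrically spaced over 0.01-50 ng), simulates ``depth``
    2x300 bp read pairs with the given substitution rate, runs the full
    pipeline (quality filter, merge, primer trim, dereplication, 97% OTU
    clustering, species assignment), and regresses the observed species
    fractions on the composition actually sequenced. Read allocation is
    deterministic (largest-remainder), so at substitution rate 0 the
    pipeline recovers the sequenced composition exactly and the fit is
    slope = 1, R^2 = 1.

    The result table carries three columns of fractions: ``expected`` (the
    regression x: sequenced composition), ``mass_expected`` (the
    mass-derived theoretical composition) and ``observed``.
    """
    from . import simulate  # deferred: simulate depends on this module
    from .pipeline import PipelineConfig, profile_pairs
    from .refdb import build_db_from_records

    fx = simulate.mock_fixture(seed, depth=depth,
                               substitution_rate=substitution_rate,
                               n_species=n_species)
    db = build_db_from_records(fx.ref_set.records, fx.ref_set.taxonomy)
    result = profile_pairs(fx.r1, fx.r2, db, PipelineConfig())
    res = regress_observed_expected(result.species_fractions, fx.realized_fractions)
    theo = fx.expected_fractions
    res.table["mass_expected"] = [theo.get(l, 0.0) for l in res.table["species"]]
    res.table.attrs["n_unassigned_reads"] = result.unassigned_reads
    res.table.attrs["n_merged_reads"] = result.merged_count
    return res


def detection_limit_scan(
    ref_set,
    db: ReferenceDB,
    spec_series: list[MockSpec],
    target_species: str,
    depth: int,
    seed: int,
    substitution_rate: float = 0.0,
    min_count: int = 1,
) -> pd.DataFrame:
    """Scan a dilution series of one target strain for its detection limit.

    ``spec_series`` must hold the target species at strictly decreasing
    masses. Each spec is simulated (depth read pairs, seeded), processed
    and classified; the target is "detected" when at least ``min_count``
    reads are assigned to it. Returns one row per spec with the target
    mass, its copy-count equivalent, its expected fraction, the assigned
    read count and the detection call. The smallest detected mass is the
    empirical detection limit under these conditions.
    """
    from . import simulate
    from .pipeline import PipelineConfig, profile_pairs

    masses = []
    for spec in spec_series:
        m = [s.dna_mass_ng for s in spec.strains if s.species == target_species]
        if len(m) != 1:
            raise ValueError(f"each spec must contain {target_species!r} exactly once")
        masses.append(m[0])
    if any(b >= a for a, b in zip(masses, masses[1:])):
        raise ValueError("target mass must be strictly decreasing across the series")

    acc_of = {label: acc for acc, label in ref_set.taxonomy.items()}
    rows = []
    for k, spec in enumerate(spec_series):
        expected = expected_composition(spec)
        proportions = {acc_of[sp]: frac for sp, frac in expected.items()}
        cfg = simulate.ReadSimConfig(depth=depth,
                                     substitution_rate=substitution_rate,
                                     seed=(seed + k) % (2**31))
        r1, r2, _ = simulate.simulate_reads(ref_set, proportions, cfg)
        result = profile_pairs(r1, r2, db, PipelineConfig())
        n_target = result.species_read_counts.get(target_species, 0)
        target = next(s for s in spec.strains if s.species == target_species)
        rows.append({
            "mass_ng": target.dna_mass_ng,
            "copies": target.copies,
            "expected_fraction": expected[target_species],
            "assigned_reads": n_target,
            "detected": n_target >= min_count,
        })
    return pd.DataFrame(rows)
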