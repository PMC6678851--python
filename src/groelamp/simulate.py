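"""Synthetic data generation for desk-scale pipeline testing.

Generates reference sets that emulate the structure of the Lactobacillus
groEL marker — a hypervariable insert flanked by conserved primer-binding
sites, high inter-species divergence (default 10% substitutions from a
common ancestor) and slight strain-level micro-variation (default 0.5%) —
plus seeded 2x300 bp paired-end reads with Phred qualities and
substitution errors, and a nine-strain mock-community bundle wired to the
copy-number calculator.

Every generator is fully deterministic under a fixed seed. The forward
primer site is planted as an exact expansion starting at 1-based position
340 of each template and the reverse site ends at position 824, so each
reference yields exactly one 485 bp in-silico product with a 445 bp
insert — the coordinate layout of the real marker region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import mock_eval
from .cluster_assign import global_identity
from .primers import LAC_GROEL, IUPAC_CODES, PrimerPair, reverse_complement
from .reads import ReadRecord

__all__ = [
    "FWD_SITE_START_1BASED",
    "SynthRefConfig",
    "SynthReferenceSet",
    "ReadSimConfig",
    "MockFixture",
    "synth_reference_set",
    "simulate_reads",
    "mock_fixture",
]

#: 1-based start of the planted forward-primer site (the marker's anchor).
FWD_SITE_START_1BASED = 340

BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass(frozen=True)
class SynthRefConfig:
    """Parameters of the synthetic reference generator.

    Divergences are substitution fractions applied as a fixed number of
    substitutions round(rate x insert length) at seeded positions, so the
    identity structure of the set is stable: inter-species divergence must
    land below the 97% clustering threshold and strain-level variation
    above it (verified post hoc by alignment).
    """

    n_species: int = 9
    strains_per_species: int = 1
    amplicon_insert_len: int = 445
    inter_species_divergence: float = 0.10
    intra_species_divergence: float = 0.005
    flank_len: int = 200
    seed: int = 0
    pair: PrimerPair = LAC_GROEL


@dataclass
class SynthReferenceSet:
    """In-memory synthetic reference set: templates plus taxonomy."""

    records: dict[str, str]  # accession -> full template
    taxonomy: dict[str, str]  # accession -> species label
    amplicons: dict[str, str]  # accession -> 485 bp amplicon
    config: SynthRefConfig

    def insert(self, accession: str) -> str:
        f = len(self.config.pair.forward)
        r = len(self.config.pair.reverse)
        return self.amplicons[accession][f:-r]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for acc, seq in self.records.items():
                fh.write(f">{acc}\n{seq}\n")

    def write_taxonomy(self, path) -> None:
        with open(path, "w") as fh:
            for acc, label in self.taxonomy.items():
                fh.write(f"{acc}\t{label}\n")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _random_expansion(rng: np.random.Generator, primer: str) -> str:
    return "".join(
        sorted(IUPAC_CODES[sym])[rng.integers(len(IUPAC_CODES[sym]))]
        for sym in primer
    )


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute exactly n_subs distinct positions with a different base."""
    out = list(seq)
    for pos in rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False):
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(3)]
    return "".join(out)


def synth_reference_set(cfg: SynthRefConfig) -> SynthReferenceSet:
    """Generate a multi-species reference set with planted primer sites.

    Each species' insert is mutated from a common random ancestor at the
    inter-species divergence; strains are mutated from their species
    insert at the intra-species divergence. Templates carry a random
    5' flank of 339 bp (placing the forward site at 1-based 340), an exact
    forward-primer expansion, the insert, the reverse complement of an
    exact reverse-primer expansion (ending at 1-based 824 for the default
    insert length) and a random 3' flank of ``flank_len`` bp.

    The inter/intra identity invariants are verified post hoc by global
    alignment of the inserts; a configuration that violates them is
    regenerated under a derived seed a few times before giving up with a
    diagnostic.
    """
    threshold = 97.0
    for attempt in range(5):
        rng = np.random.default_rng((cfg.seed + 7919 * attempt) % (2**31))
        refset = _generate(cfg, rng)
        if _invariants_hold(refset, cfg, threshold):
            return refset
    raise RuntimeError(
        "could not generate a reference set satisfying the identity "
        f"invariants (inter < {threshold}% <= intra) after 5 attempts; "
        "inter_species_divergence and intra_species_divergence are likely "
        "too close to the clustering threshold"
    )


def _generate(cfg: SynthRefConfig, rng: np.random.Generator) -> SynthReferenceSet:
    L = cfg.amplicon_insert_len
    ancestor = _random_seq(rng, L)
    n_inter = round(cfg.inter_species_divergence * L)
    n_intra = round(cfg.intra_species_divergence * L)
    flank5_len = FWD_SITE_START_1BASED - 1

    records: dict[str, str] = {}
    taxonomy: dict[str, str] = {}
    amplicons: dict[str, str] = {}
    k = 0
    for s in range(cfg.n_species):
        label = f"Lactobacillus synspecies{s + 1:02d}"
        species_insert = _mutate(rng, ancestor, n_inter)
        for t in range(cfg.strains_per_species):
            k += 1
            acc = f"SYN{k:06d}"
            insert = species_insert if t == 0 else _mutate(rng, species_insert, n_intra)
            fwd = _random_expansion(rng, cfg.pair.forward)
            rev = _random_expansion(rng, cfg.pair.reverse)
            amplicon = fwd + insert + reverse_complement(rev)
            template = (_random_seq(rng, flank5_len) + amplicon
                        + _random_seq(rng, cfg.flank_len))
            records[acc] = template
            taxonomy[acc] = label
            amplicons[acc] = amplicon
    return SynthReferenceSet(records, taxonomy, amplicons, cfg)


def _invariants_hold(refset: SynthReferenceSet, cfg: SynthRefConfig,
                     threshold: float) -> bool:
    accs = list(refset.records)
    for i, a in enumerate(accs):
        for b in accs[i + 1:]:
            ident = global_identity(refset.insert(a), refset.insert(b))
            same_species = refset.taxonomy[a] == refset.taxonomy[b]
            if same_species and ident < threshold:
                return False
            if not same_species and ident >= threshold:
                return False
    return True


@dataclass(frozen=True)
class ReadSimConfig:
    """Paired-end read-simulation parameters.

    The quality model is a linear per-position profile from ``mean_q`` at
    the 5' end to ``q_decay_to`` at the 3' end (representative MiSeq 2x300
    behaviour). Per-base substitution probabilities are proportional to
    the per-position error probability 10^(-Q/10), rescaled so that the
    read-average substitution probability equals ``substitution_rate``.
    ``allocation`` chooses how read pairs are divided among templates:
    "multinomial" draws, or "exact" deterministic largest-remainder
    rounding of the proportions.
    """

    read_len: int = 300
    depth: int = 1000
    substitution_rate: float = 0.0
    mean_q: float = 38.0
    q_decay_to: float = 25.0
    seed: int = 0
    allocation: str = "multinomial"


def _allocate(rng: np.random.Generator, probs: np.ndarray, depth: int,
              mode: str) -> np.ndarray:
    if mode == "multinomial":
        return rng.multinomial(depth, probs)
    if mode == "exact":
        ideal = probs * depth
        counts = np.floor(ideal).astype(int)
        rem = depth - counts.sum()
        order = np.argsort(-(ideal - counts), kind="stable")
        counts[order[:rem]] += 1
        return counts
    raise ValueError(f"unknown allocation mode {mode!r}")


def simulate_reads(
    refs: SynthReferenceSet | dict[str, str],
    proportions: dict[str, float],
    cfg: ReadSimConfig,
) -> tuple[list[ReadRecord], list[ReadRecord], dict[str, int]]:
    """Simulate paired 2x300 bp reads over the references' amplicons.

    ``refs`` is a synthetic reference set (its precomputed amplicons are
    used) or a plain accession → amplicon mapping. ``proportions`` maps
    accessions to fractions summing to 1. Each pair reads the amplicon
    from its two ends: R1 is the first ``read_len`` bases, R2 the reverse
    complement of the last ``read_len`` bases, so a 485 bp amplicon gives
    a 115 bp overlap. Substitution errors are i.i.d. per base at the
    quality-linked rates; qualities are the rounded profile. Returns
    (R1 reads, R2 reads, realized per-accession pair counts). Deterministic
    per seed.
    """
    amplicons = refs.amplicons if isinstance(refs, SynthReferenceSet) else refs
    accs = list(proportions)
    probs = np.array([proportions[a] for a in accs], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    for a in accs:
        if len(amplicons[a]) < cfg.read_len:
            raise ValueError(
                f"{a}: amplicon shorter than read_len {cfg.read_len}")
    rng = np.random.default_rng(cfg.seed)
    counts = _allocate(rng, probs, cfg.depth, cfg.allocation)

    # linear quality profile and quality-linked error rates
    q = np.linspace(cfg.mean_q, cfg.q_decay_to, cfg.read_len)
    quals = np.rint(q).astype(int).tolist()
    p = 10.0 ** (-q / 10.0)
    if cfg.substitution_rate > 0:
        err = np.minimum(cfg.substitution_rate * p / p.mean(), 0.75)
    else:
        err = np.zeros(cfg.read_len)

    r1_out: list[ReadRecord] = []
    r2_out: list[ReadRecord] = []
    realized: dict[str, int] = {}
    n = 0
    for acc, c in zip(accs, counts):
        realized[acc] = int(c)
        amp = amplicons[acc]
        fwd = amp[: cfg.read_len]
        rev = reverse_complement(amp)[: cfg.read_len]
        for _ in range(int(c)):
            n += 1
            rid = f"SIM{n:07d}"
            r1_out.append(ReadRecord(rid, _with_errors(rng, fwd, err), quals))
            r2_out.append(ReadRecord(rid, _with_errors(rng, rev, err), quals))
    return r1_out, r2_out, realized


def _with_errors(rng: np.random.Generator, seq: str, err: np.ndarray) -> str:
    if not err.any():
        return seq
    hits = np.nonzero(rng.random(len(seq)) < err)[0]
    if len(hits) == 0:
        return seq
    out = list(seq)
    for pos in hits:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(3)]
    return "".join(out)


@dataclass
class MockFixture:
    """Everything an end-to-end mock-community experiment needs."""

    ref_set: SynthReferenceSet
    mock_spec: mock_eval.MockSpec
    expected_fractions: dict[str, float]  # mass-derived (theoretical)
    realized_fractions: dict[str, float]  # composition actually sequenced
    r1: list[ReadRecord] = field(repr=False)
    r2: list[ReadRecord] = field(repr=False)
    read_cfg: ReadSimConfig = field(default_factory=ReadSimConfig)


def mock_fixture(
    seed: int,
    depth: int = 20000,
    substitution_rate: float = 0.005,
    n_species: int = 9,
) -> MockFixture:
    """A seeded nine-strain mock-community bundle.

    One strain per species; DNA masses geometrically spaced over
    [0.01, 50] ng (ascending with species index) and genome lengths drawn
    uniformly in [1.8, 3.4] Mb — the size range of typical Lactobacillus
    genomes. Expected fractions follow from the copy-number calculator;
    read pairs are allocated deterministically (largest remainder) so the
    sequenced composition is a fixed rounding of the expectation.
    """
    ref_cfg = SynthRefConfig(n_species=n_species, seed=seed % (2**31))
    ref_set = synth_reference_set(ref_cfg)
    rng = np.random.default_rng((seed + 104729) % (2**31))
    masses = np.geomspace(0.01, 50.0, n_species)
    genome_lengths = rng.uniform(1.8e6, 3.4e6, n_species)
    accs = list(ref_set.records)
    strains = [
        mock_eval.MockStrain(acc, ref_set.taxonomy[acc],
                             float(masses[i]), float(round(genome_lengths[i])))
        for i, acc in enumerate(accs)
    ]
    spec = mock_eval.MockSpec(strains)
    expected = mock_eval.expected_composition(spec)
    proportions = {acc: expected[ref_set.taxonomy[acc]] for acc in accs}
    cfg = ReadSimConfig(depth=depth, substitution_rate=substitution_rate,
                        seed=(seed + 15485863) % (2**31), allocation="exact")
    r1, r2, realized = simulate_reads(ref_set, proportions, cfg)
    realized_fracs = {
        ref_set.taxonomy[acc]: c / depth for acc, c in realized.items()
    }
    return MockFixture(ref_set, spec, expected, realized_fracs, r1, r2, cfg)
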