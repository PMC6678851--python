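"""Synthetic reference sets, seeded read simulation and the mock bundle."""

import numpy as np
import pytest

from groelamp import ispcr, refdb, simulate
from groelamp.cluster_assign import global_identity
from groelamp.pipeline import PipelineConfig, profile_pairs
from groelamp.primers import LAC_GROEL
from groelamp.reads import merge_pairs, MergedRead
from groelamp.simulate import ReadSimConfig, SynthRefConfig


class TestSynthReferenceSet:
    def test_nine_species_all_amplify_to_485(self):
        ref_set = simulate.synth_reference_set(SynthRefConfig(seed=101))
        assert len(ref_set.records) == 9
        for acc, template in ref_set.records.items():
            amps = ispcr.amplify(template, LAC_GROEL, template_id=acc)
            assert len(amps) == 1
            assert amps[0].length == 485
            assert amps[0].start == 339  # forward site at 1-based 340
            assert amps[0].sequence == ref_set.amplicons[acc]

    def test_same_seed_identical_output(self):
        a = simulate.synth_reference_set(SynthRefConfig(seed=102))
        b = simulate.synth_reference_set(SynthRefConfig(seed=102))
        assert a.records == b.records and a.taxonomy == b.taxonomy

    def test_different_seed_different_output(self):
        a = simulate.synth_reference_set(SynthRefConfig(seed=103))
        b = simulate.synth_reference_set(SynthRefConfig(seed=104))
        assert a.records != b.records

    def test_inter_species_identities_below_threshold(self):
        ref_set = simulate.synth_reference_set(
            SynthRefConfig(n_species=5, seed=105))
        accs = list(ref_set.records)
        for i, a in enumerate(accs):
            for b in accs[i + 1:]:
                assert global_identity(ref_set.insert(a),
                                       ref_set.insert(b)) < 97.0

    def test_strain_variation_stays_within_species(self, small_refset):
        accs = list(small_refset.records)
        for a in accs:
            for b in accs:
                if a >= b:
                    continue
                ident = global_identity(small_refset.insert(a),
                                        small_refset.insert(b))
                same = small_refset.taxonomy[a] == small_refset.taxonomy[b]
                assert (ident >= 97.0) == same

    def test_impossible_divergence_config_raises(self):
        cfg = SynthRefConfig(n_species=3, inter_species_divergence=0.001,
                             seed=106)
        with pytest.raises(RuntimeError, match="identity"):
            simulate.synth_reference_set(cfg)


@pytest.fixture(scope="module")
def two_species():
    return simulate.synth_reference_set(SynthRefConfig(n_species=2, seed=107))


@pytest.fixture(scope="module")
def mock_bundle():
    return simulate.mock_fixture(31, depth=400, substitution_rate=0.0)


class TestSimulateReads:
    def test_same_seed_identical_reads(self, two_species):
        accs = list(two_species.records)
        props = {accs[0]: 0.7, accs[1]: 0.3}
        cfg = ReadSimConfig(depth=50, substitution_rate=0.01, seed=7)
        out1 = simulate.simulate_reads(two_species, props, cfg)
        out2 = simulate.simulate_reads(two_species, props, cfg)
        assert out1 == out2

    def test_species_counts_within_binomial_bounds(self, two_species):
        accs = list(two_species.records)
        props = {accs[0]: 0.7, accs[1]: 0.3}
        cfg = ReadSimConfig(depth=1000, seed=13)
        _, _, realized = simulate.simulate_reads(two_species, props, cfg)
        # 3 sigma of Binomial(1000, 0.7)
        sigma = np.sqrt(1000 * 0.7 * 0.3)
        assert abs(realized[accs[0]] - 700) <= 3 * sigma
        assert sum(realized.values()) == 1000

    def test_exact_allocation_is_largest_remainder(self, two_species):
        accs = list(two_species.records)
        props = {accs[0]: 0.7005, accs[1]: 0.2995}
        cfg = ReadSimConfig(depth=10, seed=1, allocation="exact")
        _, _, realized = simulate.simulate_reads(two_species, props, cfg)
        assert realized == {accs[0]: 7, accs[1]: 3}

    def test_error_free_pairs_merge_to_the_amplicon(self, two_species):
        accs = list(two_species.records)
        cfg = ReadSimConfig(depth=20, substitution_rate=0.0, seed=17,
                            allocation="exact")
        r1, r2, _ = simulate.simulate_reads(two_species, {accs[0]: 1.0}, cfg)
        amp = two_species.amplicons[accs[0]]
        for a, b in zip(r1, r2):
            m = merge_pairs(a, b)
            assert isinstance(m, MergedRead)
            assert m.seq == amp
            assert m.overlap_len == 2 * 300 - 485 == 115

    def test_substitution_rate_perturbs_reads(self, two_species):
        accs = list(two_species.records)
        cfg = ReadSimConfig(depth=30, substitution_rate=0.02, seed=19,
                            allocation="exact")
        r1, _, _ = simulate.simulate_reads(two_species, {accs[0]: 1.0}, cfg)
        amp = two_species.amplicons[accs[0]]
        diffs = sum(a != b for rec in r1 for a, b in zip(rec.seq, amp[:300]))
        # 30 reads x 300 bp x 2% = 180 expected substitutions
        assert 90 < diffs < 300

    def test_zero_depth_is_valid_and_empty(self, two_species):
        accs = list(two_species.records)
        cfg = ReadSimConfig(depth=0, seed=3)
        r1, r2, realized = simulate.simulate_reads(
            two_species, {accs[0]: 1.0}, cfg)
        assert r1 == [] and r2 == []

    def test_proportions_must_sum_to_one(self, two_species):
        accs = list(two_species.records)
        with pytest.raises(ValueError, match="sum to 1"):
            simulate.simulate_reads(two_species, {accs[0]: 0.5},
                                    ReadSimConfig(depth=10, seed=1))


class TestMockFixture:
    def test_masses_span_the_printed_range(self, mock_bundle):
        masses = [s.dna_mass_ng for s in mock_bundle.mock_spec.strains]
        assert min(masses) == pytest.approx(0.01)
        assert max(masses) == pytest.approx(50.0)
        assert len(masses) == 9

    def test_expected_fractions_sum_to_one(self, mock_bundle):
        assert sum(mock_bundle.expected_fractions.values()) == pytest.approx(1.0)
        assert sum(mock_bundle.realized_fractions.values()) == pytest.approx(1.0)

    def test_error_free_pipeline_recovers_generating_species(self, mock_bundle):
        """Round trip: synth refs -> db -> reads -> merge/trim -> cluster ->
        assign recovers exactly the sequenced species with read-count
        conservation and no unassigned reads."""
        db = refdb.build_db_from_records(mock_bundle.ref_set.records,
                                         mock_bundle.ref_set.taxonomy)
        result = profile_pairs(mock_bundle.r1, mock_bundle.r2, db, PipelineConfig())
        assert result.unassigned_reads == 0
        assert sum(o.total_count for o in result.otus) == 400
        sequenced = {sp for sp, f in mock_bundle.realized_fractions.items() if f > 0}
        assert set(result.species_fractions) == sequenced
        for sp, frac in result.species_fractions.items():
            assert frac == pytest.approx(mock_bundle.realized_fractions[sp])
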