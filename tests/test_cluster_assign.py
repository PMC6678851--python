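"""Global identity (against an exhaustive alignment-enumeration oracle),
dereplication, greedy OTU clustering, taxonomy assignment and abundance
tables."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from groelamp import refdb
from groelamp.cluster_assign import (
    OTHER_LABEL,
    UNASSIGNED,
    DereplicatedSeq,
    _align,
    abundance_table,
    assign_taxonomy,
    dereplicate,
    global_identity,
    greedy_cluster,
)
from conftest import random_dna

MATCH, MISMATCH, OPEN, EXT = 1.0, -1.0, 2.0, 1.0


def enumerate_alignments(a: str, b: str):
    """Yield every monotone global alignment of a and b as (row_a, row_b)."""
    if not a and not b:
        yield ("", "")
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield (a[0] + ra, "-" + rb)
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield ("-" + ra, b[0] + rb)
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield (a[0] + ra, b[0] + rb)


def score_alignment(ra: str, rb: str) -> float:
    """Score with affine gaps (open + len*extend) and free terminal gaps.

    A terminal gap run is the maximal leading (or trailing) run of gap
    columns of one kind, matching a DP whose first row/column costs zero.
    """
    cols = list(zip(ra, rb))
    lo, hi = 0, len(cols)
    if cols and "-" in cols[0]:
        which = 0 if ra[0] == "-" else 1
        while lo < hi and cols[lo][which] == "-":
            lo += 1
    if hi > lo and "-" in cols[hi - 1]:
        which = 0 if ra[-1] == "-" else 1
        while hi > lo and cols[hi - 1][which] == "-":
            hi -= 1
    score = 0.0
    in_gap = None
    for x, y in cols[lo:hi]:
        if x == "-" or y == "-":
            kind = 0 if x == "-" else 1
            score -= EXT + (OPEN if in_gap != kind else 0.0)
            in_gap = kind
        else:
            score += MATCH if x == y else MISMATCH
            in_gap = None
    return score


def identity_of(ra: str, rb: str) -> float:
    cols = [(x, y) for x, y in zip(ra, rb)]
    lo = 0
    while lo < len(cols) and "-" in cols[lo]:
        lo += 1
    hi = len(cols)
    while hi > lo and "-" in cols[hi - 1]:
        hi -= 1
    if hi == lo:
        return 0.0
    matches = sum(1 for x, y in cols[lo:hi] if x == y and x != "-")
    return 100.0 * matches / (hi - lo)


class TestGlobalIdentity:
    def test_identical_sequences(self):
        s = random_dna(random.Random(0), 100)
        assert global_identity(s, s) == 100.0

    def test_one_substitution_in_100mer_is_99(self):
        rng = random.Random(1)
        a = random_dna(rng, 100)
        b = list(a)
        b[40] = "A" if b[40] != "A" else "C"
        assert global_identity(a, "".join(b)) == pytest.approx(99.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=40),
           st.text(alphabet="ACGT", min_size=1, max_size=40))
    def test_symmetry(self, a, b):
        assert global_identity(a, b) == pytest.approx(global_identity(b, a))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=5),
           st.text(alphabet="ACGT", min_size=1, max_size=5))
    def test_matches_exhaustive_enumeration_oracle(self, a, b):
        """The alignment engine must return an optimal-score alignment and
        the identity of one of the optimal alignments."""
        scored = [(score_alignment(ra, rb), identity_of(ra, rb))
                  for ra, rb in enumerate_alignments(a, b)]
        best = max(s for s, _ in scored)
        optimal_identities = {i for s, i in scored if s == best}
        score, ra, rb = _align(a, b)
        assert score == pytest.approx(best)
        got = global_identity(a, b)
        assert any(got == pytest.approx(i) for i in optimal_identities)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_identity("", "ACGT")


class TestDereplicate:
    def test_counts_conserved(self):
        reads = [("r1", "AAAA"), ("r2", "CCCC"), ("r3", "AAAA"), ("r4", "AAAA")]
        dereps = dereplicate(reads)
        assert sum(d.count for d in dereps) == 4
        assert dereps[0].seq == "AAAA" and dereps[0].count == 3
        assert dereps[0].member_ids == ["r1", "r3", "r4"]

    def test_ties_broken_lexicographically(self):
        dereps = dereplicate([("a", "TTTT"), ("b", "AAAA")])
        assert [d.seq for d in dereps] == ["AAAA", "TTTT"]


def mutate(rng, seq, n):
    out = list(seq)
    for pos in rng.sample(range(len(seq)), n):
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)


class TestGreedyCluster:
    def test_single_sequence_single_otu(self):
        otus = greedy_cluster([DereplicatedSeq("ACGT" * 30, 5, ["r"])])
        assert len(otus) == 1 and otus[0].total_count == 5

    def test_similar_sequences_join_the_abundant_centroid(self):
        rng = random.Random(81)
        a = random_dna(rng, 200)
        b = mutate(rng, a, 2)  # 99% identity
        otus = greedy_cluster([DereplicatedSeq(a, 10), DereplicatedSeq(b, 1)])
        assert len(otus) == 1
        assert otus[0].centroid_seq == a

    def test_divergent_sequences_found_separate_otus(self):
        rng = random.Random(82)
        a = random_dna(rng, 200)
        b = mutate(rng, a, 20)  # ~90% identity
        otus = greedy_cluster([DereplicatedSeq(a, 10), DereplicatedSeq(b, 1)])
        assert len(otus) == 2

    def test_members_within_threshold_and_counts_conserved(self):
        rng = random.Random(83)
        bases = [random_dna(rng, 300) for _ in range(4)]
        dereps = [
            DereplicatedSeq(mutate(rng, base, rng.randint(0, 4)),
                            rng.randint(1, 50))
            for base in bases for _ in range(8)
        ]
        otus = greedy_cluster(dereps, 97.0)
        assert sum(o.total_count for o in otus) == sum(d.count for d in dereps)
        for otu in otus:
            for m in otu.members:
                assert global_identity(m.seq, otu.centroid_seq) >= 97.0

    def test_equals_brute_force_reimplementation(self):
        """Greedy clustering must equal an independent naive implementation
        of the same insertion-order rule on 50 unique sequences."""
        rng = random.Random(84)
        bases = [random_dna(rng, 250) for _ in range(5)]
        dereps = [
            DereplicatedSeq(mutate(rng, rng.choice(bases), rng.randint(0, 8)),
                            rng.randint(1, 30))
            for _ in range(50)
        ]
        dereps = dereplicate([
            (f"r{i}", d.seq) for i, d in enumerate(dereps) for _ in range(d.count)
        ])
        assert len(dereps) <= 50

        # naive reimplementation: ordered list scan, no shortcuts
        order = sorted(dereps, key=lambda d: (-d.count, d.seq))
        naive: list[list[DereplicatedSeq]] = []
        for d in order:
            for cluster in naive:
                if global_identity(d.seq, cluster[0].seq) >= 97.0:
                    cluster.append(d)
                    break
            else:
                naive.append([d])

        otus = greedy_cluster(dereps, 97.0)
        assert len(otus) == len(naive)
        for otu, cluster in zip(otus, naive):
            assert otu.centroid_seq == cluster[0].seq
            assert [m.seq for m in otu.members] == [m.seq for m in cluster]


class TestAssignTaxonomy:
    def test_exact_centroid_assigned_at_100(self, small_db):
        rec = small_db.ok_records()[0]
        otu = greedy_cluster([DereplicatedSeq(small_db.insert_seq(rec), 3)])
        (a,) = assign_taxonomy(otu, small_db)
        assert a.label == rec.species_label
        assert a.best_identity == 100.0
        assert not a.tie

    def test_divergent_centroid_unassigned(self, small_db):
        rng = random.Random(85)
        rec = small_db.ok_records()[0]
        far = mutate(rng, small_db.insert_seq(rec), 45)  # ~90% identity
        (a,) = assign_taxonomy(greedy_cluster([DereplicatedSeq(far, 1)]),
                               small_db, min_identity=97.0)
        assert a.label == UNASSIGNED and a.best_identity < 97.0

    def test_identical_amplicons_in_two_species_tie_flagged(self, small_refset):
        # two species sharing one amplicon cannot be told apart: report
        # unassigned with the tie flag rather than fabricating precision
        recs = dict(small_refset.records)
        tax = dict(small_refset.taxonomy)
        first = list(recs)[0]
        recs["DUP001"] = recs[first]
        tax["DUP001"] = "Lactobacillus doppelganger"
        db = refdb.build_db_from_records(recs, tax)
        rec = next(r for r in db.ok_records() if r.accession == first)
        (a,) = assign_taxonomy(greedy_cluster(
            [DereplicatedSeq(db.insert_seq(rec), 2)]), db)
        assert a.label == UNASSIGNED and a.tie
        assert a.best_identity == 100.0

    def test_empty_db_rejected(self, small_db):
        empty = refdb.ReferenceDB(records=[], primer_pair=small_db.primer_pair)
        with pytest.raises(ValueError):
            assign_taxonomy([], empty)


class TestAbundanceTable:
    def _assign(self, labels):
        from groelamp.cluster_assign import TaxonomyAssignment

        return [TaxonomyAssignment(f"OTU_{i+1}", lbl, 100.0, "X")
                for i, lbl in enumerate(labels)]

    def test_single_species_is_unity(self):
        table = abundance_table(self._assign(["L. a"]),
                                {"s1": {"OTU_1": 50}})
        assert table.loc["s1", "L. a"] == 1.0

    def test_rare_species_pooled_into_other(self):
        assigns = self._assign(["L. a", "L. b"])
        table = abundance_table(assigns, {"s1": {"OTU_1": 995, "OTU_2": 5}})
        assert OTHER_LABEL in table.columns
        assert table.loc["s1", OTHER_LABEL] == pytest.approx(0.005)
        assert "L. b" not in table.columns  # pooled away in its only sample

    def test_species_kept_where_abundant_zeroed_where_pooled(self):
        assigns = self._assign(["L. a", "L. b"])
        table = abundance_table(assigns, {
            "s1": {"OTU_1": 995, "OTU_2": 5},
            "s2": {"OTU_1": 500, "OTU_2": 500},
        })
        assert table.loc["s2", "L. b"] == pytest.approx(0.5)
        assert table.loc["s1", "L. b"] == 0.0
        assert table.loc["s1", OTHER_LABEL] == pytest.approx(0.005)
        assert table.sum(axis=1).tolist() == pytest.approx([1.0, 1.0])

    def test_unassigned_kept_separate_never_pooled(self):
        assigns = self._assign(["L. a", UNASSIGNED])
        table = abundance_table(assigns, {"s1": {"OTU_1": 999, "OTU_2": 1}})
        assert table.loc["s1", UNASSIGNED] == pytest.approx(0.001)
        assert OTHER_LABEL not in table.columns

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.integers(min_value=1, max_value=1000), min_size=1,
                    max_size=8))
    def test_rows_sum_to_one(self, counts):
        labels = [f"L. sp{i}" for i in range(len(counts))]
        assigns = self._assign(labels)
        table = abundance_table(
            assigns, {"s": {f"OTU_{i+1}": c for i, c in enumerate(counts)}})
        assert table.sum(axis=1).iloc[0] == pytest.approx(1.0)
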