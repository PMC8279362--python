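import pytest
from Bio import Align

from ssp_homlab.homology import (
    IdentityCache,
    max_cross_identity,
    max_inner_identity,
    pairwise_identity,
    reduce_between,
    reduce_two_way,
    reduce_within,
)
from ssp_homlab.seq import LabeledSequence, SequenceDataset

from _oracles import alignment_oracle, oracle_identity

AA = "ACDEFGHIKLMNPQRSTVWY"


def seq(residues: str, seq_id: str = "s", family: str = "") -> LabeledSequence:
    return LabeledSequence(
        id=seq_id, residues=residues, ss8="C" * len(residues), family_id=family
    )


def random_seq(rng, n, seq_id="s"):
    return seq("".join(rng.choice(list(AA), size=n)), seq_id)


def dataset(records, name="d"):
    return SequenceDataset(name=name, role="universe", records=records)


class TestPairwiseIdentity:
    def test_self_identity_is_one(self, rng):
        for i in range(10):
            s = random_seq(rng, int(rng.integers(1, 80)), f"s{i}")
            assert pairwise_identity(s, s).identity == 1.0

    def test_disjoint_alphabets_score_zero(self):
        assert pairwise_identity(seq("AAAA"), seq("CCCC")).identity == 0.0

    def test_single_mismatch(self):
        res = pairwise_identity(seq("ACDEF"), seq("ACDFF"))
        assert res.identity == pytest.approx(0.8)
        assert res.n_matches == 4
        assert res.denominator == 5

    def test_symmetry(self, rng):
        for _ in range(30):
            a = random_seq(rng, int(rng.integers(3, 50)), "a")
            b = random_seq(rng, int(rng.integers(3, 50)), "b")
            assert (
                pairwise_identity(a, b).identity
                == pairwise_identity(b, a).identity
            )

    def test_against_recursive_oracle(self, rng):
        """Match count agrees with an independent lexicographic DP."""
        for _ in range(40):
            a = random_seq(rng, int(rng.integers(1, 14)), "a")
            b = random_seq(rng, int(rng.integers(1, 14)), "b")
            assert pairwise_identity(a, b).identity == pytest.approx(
                oracle_identity(a.residues, b.residues)
            )

    def test_score_matches_biopython(self, rng):
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = 0
        aligner.open_gap_score = -1
        aligner.extend_gap_score = -1
        for _ in range(30):
            a = random_seq(rng, int(rng.integers(2, 60)), "a")
            b = random_seq(rng, int(rng.integers(2, 60)), "b")
            score, _ = alignment_oracle(a.residues, b.residues)
            assert score == aligner.score(a.residues, b.residues)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            LabeledSequence(id="x", residues="", ss8="")

    def test_cache_returns_same_values(self, rng):
        cache = IdentityCache()
        a = random_seq(rng, 30, "a")
        b = random_seq(rng, 25, "b")
        direct = pairwise_identity(a, b).identity
        assert cache.identity(a, b) == direct
        assert cache.identity(b, a) == direct
        assert len(cache) == 1


class TestReduceWithin:
    def test_duplicates_collapse(self, rng):
        a = random_seq(rng, 40, "a")
        b = seq(a.residues, "b")
        reduced = reduce_within(dataset([a, b]), 0.9)
        assert len(reduced) == 1

    def test_fixed_point_when_already_nonredundant(self, rng):
        records = [random_seq(rng, 60, f"s{i}") for i in range(6)]
        ds = dataset(records)
        assert max_inner_identity(ds) < 0.6
        reduced = reduce_within(ds, 0.6)
        assert reduced.ids == sorted(ds.ids, key=lambda i: i)  # same records
        assert set(reduced.ids) == set(ds.ids)

    def test_greedy_chain_keeps_distant_member(self, rng):
        # A contains the shared block; B is the block itself; C shares the
        # block with 6 substitutions but is otherwise unrelated to A.
        block = "".join(rng.choice(list(AA), size=60))
        junk_a = "".join(rng.choice(list(AA), size=140))
        junk_c = "".join(rng.choice(list(AA), size=140))
        mutated = list(block)
        for pos in rng.choice(60, size=6, replace=False):
            mutated[pos] = AA[(AA.index(mutated[pos]) + 1) % 20]
        a = seq(block + junk_a, "a")
        b = seq(block, "b")
        c = seq("".join(mutated) + junk_c, "c")
        assert pairwise_identity(a, b).identity >= 0.9
        assert pairwise_identity(b, c).identity >= 0.9
        assert pairwise_identity(a, c).identity < 0.9
        reduced = reduce_within(dataset([a, b, c]), 0.9)
        assert set(reduced.ids) == {"a", "c"}
        assert max_inner_identity(reduced) < 0.9

    def test_postcondition_oracle(self, mini_universe, mini_pools):
        for cutoff in (0.9, 0.5, 0.3):
            reduced = reduce_within(
                mini_universe, cutoff, cache=mini_pools.identity_cache
            )
            assert max_inner_identity(
                reduced, mini_pools.identity_cache
            ) < cutoff
            assert reduced.declared_inner_cutoff == cutoff

    def test_monotone_in_cutoff(self, mini_universe, mini_pools):
        sizes = [
            len(reduce_within(mini_universe, c, cache=mini_pools.identity_cache))
            for c in (0.9, 0.6, 0.4)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_cutoff_rejected(self, mini_universe):
        with pytest.raises(ValueError):
            reduce_within(mini_universe, 0.0)


class TestReduceBetween:
    def test_empty_reference_keeps_everything(self, rng):
        b = dataset([random_seq(rng, 30, f"b{i}") for i in range(4)], "B")
        a = dataset([], "A")
        assert reduce_between(b, a, 0.5).ids == b.ids

    def test_self_reduction_removes_all(self, rng):
        records = [random_seq(rng, 30, f"s{i}") for i in range(4)]
        a, b = dataset(records, "A"), dataset(list(records), "B")
        assert len(reduce_between(b, a, 1.0)) == 0

    def test_postcondition_oracle(self, mini_universe, mini_pools, rng):
        ids = list(mini_universe.ids)
        rng.shuffle(ids)
        a = mini_universe.subset(ids[:40], name="A")
        b = mini_universe.subset(ids[40:80], name="B")
        b_prime = reduce_between(b, a, 0.4, cache=mini_pools.identity_cache)
        assert max_cross_identity(b_prime, a, mini_pools.identity_cache) < 0.4


class TestReduceTwoWay:
    def test_unrelated_datasets_untouched(self, rng):
        a = dataset([random_seq(rng, 50, f"a{i}") for i in range(4)], "A")
        b = dataset([random_seq(rng, 50, f"b{i}") for i in range(4)], "B")
        assert max_cross_identity(a, b) < 0.5
        a2, b2 = reduce_two_way(a, b, 0.5)
        assert a2.ids == a.ids and b2.ids == b.ids

    def test_identical_datasets(self, rng):
        records = [random_seq(rng, 30, f"s{i}") for i in range(4)]
        a, b = dataset(records, "A"), dataset(list(records), "B")
        a2, b2 = reduce_two_way(a, b, 0.9)
        assert len(b2) == 0
        assert a2.ids == a.ids

    def test_idempotent_and_cross_clean(self, mini_universe, mini_pools, rng):
        ids = list(mini_universe.ids)
        for trial in range(5):
            rng.shuffle(ids)
            a = mini_universe.subset(ids[:25], name="A")
            b = mini_universe.subset(ids[25:50], name="B")
            cache = mini_pools.identity_cache
            a1, b1 = reduce_two_way(a, b, 0.4, cache)
            assert max_cross_identity(a1, b1, cache) < 0.4
            a2, b2 = reduce_two_way(a1, b1, 0.4, cache)
            assert a2.ids == a1.ids and b2.ids == b1.ids
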