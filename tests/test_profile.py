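import numpy as np
import pytest

from ssp_homlab.profile import (
    Hit,
    build_pssm,
    entropy,
    hmm_to_prob,
    search_homologs,
    weighted_mean_entropy,
    write_pssm_csv,
)
from ssp_homlab.seq import LabeledSequence, SequenceDataset
from ssp_homlab.synthetic import UniverseConfig, mutate_homolog, sample_ancestor

LOG2_20 = np.log2(20)


def seq(residues, seq_id="q"):
    return LabeledSequence(id=seq_id, residues=residues, ss8="C" * len(residues))


class TestEntropy:
    def test_uniform_is_maximal(self):
        assert entropy(np.full(20, 0.05)) == pytest.approx(LOG2_20)

    def test_one_hot_is_zero(self):
        p = np.zeros(20)
        p[3] = 1.0
        assert entropy(p) == 0.0

    def test_closed_form_mixture(self):
        p = np.zeros(20)
        p[:3] = [0.5, 0.25, 0.25]
        assert entropy(p) == pytest.approx(1.5)

    def test_non_normalised_rejected(self):
        with pytest.raises(ValueError):
            entropy(np.full(20, 0.06))


class TestHmmTransform:
    @pytest.mark.parametrize("h, p", [(0, 1.0), (1000, 0.5), (3000, 0.125)])
    def test_score_to_probability(self, h, p):
        assert hmm_to_prob(h) == pytest.approx(p)

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            hmm_to_prob(-1)


class TestSearchHomologs:
    def test_exact_copy_is_top_hit(self, rng):
        config = UniverseConfig(length_range=(60, 80))
        query = sample_ancestor(config, rng, seq_id="q")
        copy = LabeledSequence(id="copy", residues=query.residues, ss8=query.ss8)
        decoy = sample_ancestor(config, rng, seq_id="decoy")
        reference = SequenceDataset(
            name="ref", role="reference", records=[decoy, copy]
        )
        hits = search_homologs(query, reference)
        assert hits and hits[0].record.id == "copy"
        assert hits[0].identity == 1.0

    def test_no_qualifying_hits_is_empty(self, rng):
        config = UniverseConfig(length_range=(60, 80))
        query = sample_ancestor(config, rng, seq_id="q")
        reference = SequenceDataset(
            name="ref", role="reference",
            records=[sample_ancestor(config, rng, seq_id=f"d{i}") for i in range(5)],
        )
        hits = search_homologs(query, reference, min_identity=0.6)
        assert hits == []

    def test_hit_list_truncated_to_closest(self, rng):
        config = UniverseConfig(length_range=(60, 80))
        query = sample_ancestor(config, rng, seq_id="q")
        homologs = [
            mutate_homolog(query, t, config, rng, seq_id=f"h{i}")
            for i, t in enumerate(np.linspace(0.5, 0.95, 12))
        ]
        reference = SequenceDataset(name="ref", role="reference", records=homologs)
        hits = search_homologs(query, reference, max_hits=5, min_identity=0.3)
        assert len(hits) == 5
        identities = [h.identity for h in hits]
        assert identities == sorted(identities, reverse=True)
        all_idents = sorted(
            (h.identity for h in search_homologs(query, reference, min_identity=0.3)),
            reverse=True,
        )
        assert identities == all_idents[:5]


class TestBuildPssm:
    def test_no_hits_no_pseudocounts_is_one_hot(self, rng):
        config = UniverseConfig(length_range=(40, 50))
        query = sample_ancestor(config, rng, seq_id="q")
        profile = build_pssm(query, [], pseudocount_weight=0.0)
        assert np.allclose(profile.probs.sum(axis=1), 1.0)
        assert np.all(profile.position_entropy == 0.0)
        assert np.all(profile.probs.max(axis=1) == 1.0)

    def test_large_pseudocount_approaches_background(self, rng):
        config = UniverseConfig(length_range=(40, 50))
        query = sample_ancestor(config, rng, seq_id="q")
        profile = build_pssm(query, [], pseudocount_weight=1e7)
        assert np.allclose(profile.probs, 0.05, atol=1e-5)
        assert profile.mean_entropy == pytest.approx(LOG2_20, abs=1e-4)

    def test_single_mismatched_hit_splits_column(self):
        query = seq("A", "q")
        hit_rec = seq("C", "h")
        hit = Hit(record=hit_rec, identity=0.0, query_to_hit=np.array([0]))
        profile = build_pssm(query, [hit], pseudocount_weight=0.0)
        assert profile.probs[0, 0] == pytest.approx(0.5)  # A
        assert profile.probs[0, 1] == pytest.approx(0.5)  # C
        assert profile.position_entropy[0] == pytest.approx(1.0)

    def test_gapped_hit_positions_contribute_nothing(self):
        query = seq("ACD", "q")
        hit_rec = seq("AD", "h")
        hit = Hit(
            record=hit_rec, identity=0.5, query_to_hit=np.array([0, -1, 1])
        )
        profile = build_pssm(query, [hit], pseudocount_weight=0.0)
        assert profile.position_entropy[1] == 0.0  # only the query residue

    def test_invalid_background_rejected(self, rng):
        config = UniverseConfig(length_range=(40, 50))
        query = sample_ancestor(config, rng, seq_id="q")
        with pytest.raises(ValueError):
            build_pssm(query, [], background=np.full(20, 0.06))


class TestEntropyDiversity:
    def _profile_from(self, query, targets, config, rng, beta=0.1):
        hits = []
        for i, t in enumerate(targets):
            rec = mutate_homolog(query, t, config, rng, seq_id=f"h{i}")
            hits.append(
                Hit(
                    record=rec,
                    identity=t,
                    query_to_hit=np.arange(query.length),
                )
            )
        return build_pssm(query, hits, pseudocount_weight=beta)

    def test_diverse_hits_raise_entropy(self, rng):
        """A diverse hit set encodes more column-level variation."""
        config = UniverseConfig(length_range=(120, 140))
        query = sample_ancestor(config, rng, seq_id="q")
        redundant = self._profile_from(query, [0.95, 0.95, 0.95], config, rng)
        diverse = self._profile_from(query, [0.9, 0.6, 0.4], config, rng)
        assert diverse.mean_entropy > redundant.mean_entropy

    def test_truncation_bound_replacing_duplicates_raises_entropy(self, rng):
        """With the hit cap binding, near-duplicates crowd out diversity."""
        config = UniverseConfig(length_range=(120, 140))
        query = sample_ancestor(config, rng, seq_id="q")
        crowded = self._profile_from(query, [0.98, 0.96, 0.94], config, rng)
        opened = self._profile_from(query, [0.98, 0.5, 0.35], config, rng)
        assert opened.mean_entropy > crowded.mean_entropy


class TestAggregation:
    def _dummy_profile(self, length, mean_entropy):
        probs = np.full((length, 20), 0.05)
        # Constant-entropy columns scaled artificially via position_entropy.
        from ssp_homlab.profile import ProfileMatrix

        return ProfileMatrix(
            query_id="d",
            probs=probs,
            log_odds=np.zeros((length, 20)),
            position_entropy=np.full(length, mean_entropy),
            n_hits=0,
        )

    def test_single_profile_returns_own_entropy(self):
        p = self._dummy_profile(50, 1.25)
        assert weighted_mean_entropy([p]) == pytest.approx(1.25)

    def test_equal_lengths_average(self):
        ps = [self._dummy_profile(100, 1.0), self._dummy_profile(100, 3.0)]
        assert weighted_mean_entropy(ps) == pytest.approx(2.0)

    def test_length_weighting(self):
        ps = [self._dummy_profile(100, 1.0), self._dummy_profile(300, 3.0)]
        assert weighted_mean_entropy(ps) == pytest.approx(2.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean_entropy([])


def test_pssm_csv_export(tmp_path, rng):
    config = UniverseConfig(length_range=(30, 40))
    query = sample_ancestor(config, rng, seq_id="q")
    profile = build_pssm(query, [])
    out = tmp_path / "profile.csv"
    write_pssm_csv(profile, out)
    import csv

    with open(out) as fh:
        rows = list(csv.reader(fh))
    assert len(rows) == profile.length + 1
    assert len(rows[0]) == 2 + 40
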