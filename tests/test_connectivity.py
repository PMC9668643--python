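"""KS connectivity scoring, tau normalization, permutation p, ranking."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigreverse import (
    ConfigurationError,
    DiseaseSignature,
    InputError,
    PerturbagenCompendium,
    ks_enrichment,
    permutation_pvalue,
    raw_connectivity,
    score_compendium,
    tau_normalize,
    truncate_candidates,
)
from sigreverse.connectivity import PerturbagenProfile, _es_from_sorted_positions

from conftest import profile_from_positions
from oracles import ks_walk_oracle


@st.composite
def random_instances(draw):
    n = draw(st.integers(min_value=2, max_value=200))
    t = draw(st.integers(min_value=1, max_value=n))
    positions = draw(st.permutations(range(1, n + 1)))
    return n, sorted(positions[:t])


class TestKSEnrichment:
    @pytest.mark.parametrize(
        "n, positions, expected",
        [
            (100, range(1, 11), 0.9),  # tags at the very top
            (100, range(91, 101), -0.91),  # tags at the very bottom
            (10, [2, 5, 9], -7.0 / 30.0),  # both maxima evaluated by hand
        ],
    )
    def test_hand_computed_scores(self, n, positions, expected):
        tags = [f"T{i}" for i in range(len(list(positions)))]
        profile = profile_from_positions(n, tags, positions)
        assert ks_enrichment(tags, profile) == pytest.approx(expected, abs=1e-12)

    def test_missing_tags_dropped_with_warning(self, caplog):
        profile = profile_from_positions(50, [f"T{i}" for i in range(12)],
                                         range(1, 13))
        tags = [f"T{i}" for i in range(12)] + ["ABSENT"]
        with caplog.at_level("WARNING"):
            es = ks_enrichment(tags, profile)
        assert es > 0.7
        assert any("not in universe" in m for m in caplog.messages)

    def test_fully_missing_tags_error_lists_genes(self):
        profile = profile_from_positions(20, ["T0"], [1])
        with pytest.raises(InputError, match="NOPE"):
            ks_enrichment(["NOPE"], profile)

    @settings(max_examples=300, derandomize=True)
    @given(random_instances())
    def test_matches_running_sum_oracle(self, instance):
        n, positions = instance
        es = float(_es_from_sorted_positions(np.array(positions, float), n))
        assert es == pytest.approx(ks_walk_oracle(positions, n), abs=1e-12)

    @settings(max_examples=300, derandomize=True)
    @given(random_instances())
    def test_bounded_by_unit_interval(self, instance):
        n, positions = instance
        es = float(_es_from_sorted_positions(np.array(positions, float), n))
        assert -1.0 <= es <= 1.0


class TestRawConnectivity:
    def _profile_and_signature(self, up_positions, down_positions, n=100):
        up = [f"U{i}" for i in range(len(list(up_positions)))]
        down = [f"D{i}" for i in range(len(list(down_positions)))]
        profile = profile_from_positions(
            n, up + down, list(up_positions) + list(down_positions)
        )
        return DiseaseSignature(up_tags=up, down_tags=down), profile

    def test_mimic_profile_scores_high(self):
        """Up-tags at ranks 1..10 and down-tags at 91..100 combine to
        (0.9 − (−0.91))/2 = 0.905."""
        sig, profile = self._profile_and_signature(range(1, 11), range(91, 101))
        es_up, es_down, raw = raw_connectivity(sig, profile)
        assert es_up == pytest.approx(0.9)
        assert es_down == pytest.approx(-0.91)
        assert raw == pytest.approx(0.905)

    def test_same_sign_enrichments_give_zero(self):
        sig, profile = self._profile_and_signature(range(1, 11), range(11, 21))
        es_up, es_down, raw = raw_connectivity(sig, profile)
        assert es_up > 0 and es_down > 0
        assert raw == 0.0

    def test_swapping_tag_directions_negates_score(self):
        sig, profile = self._profile_and_signature(range(1, 11), range(91, 101))
        swapped = DiseaseSignature(up_tags=sig.down_tags, down_tags=sig.up_tags)
        _, _, raw = raw_connectivity(sig, profile)
        _, _, raw_swapped = raw_connectivity(swapped, profile)
        assert raw_swapped == -raw


class TestTauNormalize:
    def test_dominating_scores_reach_bounds(self):
        refs = np.linspace(-0.5, 0.5, 100)
        assert tau_normalize(0.9, refs) == 100.0
        assert tau_normalize(-0.9, refs) == -100.0

    def test_zero_score_maps_to_zero(self):
        assert tau_normalize(0.0, np.linspace(-1, 1, 50)) == 0.0

    def test_percentile_counted_with_strict_inequality(self):
        """75 of 100 references below |raw|=0.5 gives tau -75."""
        refs = np.concatenate([np.linspace(0.0, 0.49, 75), np.linspace(0.5, 1.0, 25)])
        assert tau_normalize(-0.5, refs) == -75.0

    def test_too_few_references_rejected(self):
        with pytest.raises(ConfigurationError, match=">= 20"):
            tau_normalize(0.5, np.zeros(19))

    def test_magnitude_monotone_in_raw_score(self):
        rng = np.random.default_rng(7)
        refs = rng.uniform(-1, 1, 100)
        taus = [abs(tau_normalize(r, refs)) for r in np.linspace(0.01, 1, 50)]
        assert (np.diff(taus) >= 0).all()


class TestPermutationPvalue:
    def _signature_profile(self, n=500, t=20, seed=0):
        rng = np.random.default_rng(seed)
        genes = np.array([f"F{j:05d}" for j in range(n)], dtype=object)
        profile = PerturbagenProfile("p", rng.permutation(genes))
        picks = rng.choice(genes, 2 * t, replace=False)
        return (
            DiseaseSignature(up_tags=list(picks[:t]), down_tags=list(picks[t:])),
            profile,
        )

    def test_minimum_achievable_p_for_perfect_reverser(self):
        n, t = 200, 10
        up = [f"U{i}" for i in range(t)]
        down = [f"D{i}" for i in range(t)]
        profile = profile_from_positions(
            n, down + up, list(range(1, t + 1)) + list(range(n - t + 1, n + 1))
        )
        sig = DiseaseSignature(up_tags=up, down_tags=down)
        p = permutation_pvalue(sig, profile, n_perm=1000, seed=3)
        assert p == pytest.approx(1.0 / 1001.0)

    def test_p_bounded_below_by_estimator_floor(self):
        sig, profile = self._signature_profile()
        p = permutation_pvalue(sig, profile, n_perm=150, seed=1)
        assert 1.0 / 151.0 <= p <= 1.0

    def test_reproducible_under_fixed_seed(self):
        sig, profile = self._signature_profile()
        assert permutation_pvalue(sig, profile, 200, seed=5) == permutation_pvalue(
            sig, profile, 200, seed=5
        )

    def test_small_n_perm_rejected(self):
        sig, profile = self._signature_profile()
        with pytest.raises(InputError, match="n_perm"):
            permutation_pvalue(sig, profile, n_perm=50)


class TestScoreCompendium:
    def test_noiseless_reversers_and_mimics_at_extremes(
        self, small_compendium, small_signature
    ):
        compendium, truth = small_compendium
        records = score_compendium(small_signature, compendium, n_perm=300, seed=8)
        merged = records.merge(truth, on="perturbagen_id")
        k = (truth["role"] == "reverser").sum()
        assert (merged.head(k)["role"] == "reverser").all()
        assert (merged.head(k)["tau"] == -100.0).all()
        m = (truth["role"] == "mimic").sum()
        assert (merged.tail(m)["role"] == "mimic").all()
        assert (merged.tail(m)["tau"] == 100.0).all()

    def test_rank_column_follows_tau_order(self, small_compendium, small_signature):
        compendium, _ = small_compendium
        records = score_compendium(small_signature, compendium, n_perm=300, seed=8)
        assert (records["rank"].to_numpy() == np.arange(1, len(records) + 1)).all()
        assert (np.diff(records["tau"].to_numpy()) >= 0).all()

    def test_null_scores_symmetric_about_zero(self, small_signature):
        """Over random profiles mean raw score is ~0 and tau signs balance
        (two-sided sign test)."""
        from scipy import stats

        from sigreverse import SimulationConfig, generate_compendium

        cfg = SimulationConfig(
            n_genes=2000, n_perturbagens=200, n_reversers=0, n_mimics=0,
            profile_noise=0.0, seed=33,
        )
        compendium, _ = generate_compendium(cfg, small_signature, n_ref=40)
        records = score_compendium(small_signature, compendium, n_perm=300, seed=9)
        raw = records["raw_score"].to_numpy()
        assert abs(raw.mean()) < 3 * raw.std() / np.sqrt(len(raw))
        nonzero = records["tau"][records["tau"] != 0]
        n_pos = int((nonzero > 0).sum())
        assert stats.binomtest(n_pos, len(nonzero)).pvalue > 0.01

    def test_empty_compendium_rejected(self, small_signature):
        universe = np.array(["G1", "G2"])
        compendium = PerturbagenCompendium(
            universe=universe, perturbagen_ids=[],
            rankings=np.empty((0, 2), dtype=np.int64),
            reference_scores=np.empty((0, 30)),
        )
        with pytest.raises(InputError, match="empty"):
            score_compendium(small_signature, compendium)


class TestTruncateCandidates:
    @pytest.mark.parametrize("n_records, k, expected", [(500, 150, 150), (40, 150, 40), (10, 1, 1)])
    def test_keeps_first_min_k(self, n_records, k, expected):
        records = pd.DataFrame(
            {"perturbagen_id": [f"D{i}" for i in range(n_records)],
             "tau": np.linspace(-100, 100, n_records)}
        )
        out = truncate_candidates(records, k)
        assert len(out) == expected
        assert out["perturbagen_id"].tolist() == records["perturbagen_id"][:expected].tolist()

    def test_invalid_k_rejected(self):
        with pytest.raises(InputError):
            truncate_candidates(pd.DataFrame({"tau": [1.0]}), 0)
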