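"""The noisy minimal-complexity predictor: selection, noise, resources."""

from collections import Counter

import numpy as np
import pytest
from scipy import stats

from geomlang.language import LanguageError
from geomlang.predictor import (
    FULL_RESOURCES,
    PRESETS,
    CandidateSet,
    PredictorParams,
    RunResources,
    draw_run_resources,
    predict_next,
)
from geomlang.stimuli import StimulusSpec, make_sequence

NOISELESS = PredictorParams(sigma=0.0)


class TestSelection:
    def test_simplest_completion_wins_without_noise(self, atlas, rng):
        # (0,1): the clockwise progression (K=5) is the unique minimum
        assert predict_next((0, 1), atlas, NOISELESS, rng=rng) == 2
        # rotation equivariance: prefixes are matched up to rotation
        assert predict_next((3, 4), atlas, NOISELESS, rng=rng) == 5

    def test_unique_completion_predicted_when_within_capacity(self, atlas, rng):
        seq = make_sequence(StimulusSpec("2squares", 0, 1)).locations  # K=8
        assert predict_next(seq[:7], atlas, NOISELESS, rng=rng) == seq[7]

    def test_over_capacity_prefix_elicits_chance(self, atlas, rng):
        seq = make_sequence(StimulusSpec("irregular", 0, 1, seed=3)).locations
        responses = Counter(
            predict_next(seq[:7], atlas, NOISELESS, rng=rng) for _ in range(700)
        )
        assert set(responses) == set(range(8)) - {seq[6]}  # never the current
        assert min(responses.values()) > 50  # roughly uniform over the 7

    def test_cyclic_continuation_past_eight(self, atlas, rng):
        seq = make_sequence(StimulusSpec("2squares", 2, -1)).locations
        pres = seq * 2
        for pos in (9, 12, 16):
            assert predict_next(pres[: pos - 1], atlas, NOISELESS, rng=rng) == (
                pres[pos - 1]
            )

    def test_equal_minima_break_uniformly(self, atlas, rng):
        # (0,4) at sigma=0: the four K=7 point-symmetry figures tie
        responses = Counter(
            predict_next((0, 4), atlas, NOISELESS, rng=rng) for _ in range(800)
        )
        assert set(responses) == {1, 3, 5, 7}
        assert min(responses.values()) > 120

    def test_inconsistent_prefix(self, atlas, rng):
        with pytest.raises(LanguageError):
            predict_next((0, 2, 0), atlas, NOISELESS, rng=rng)
        r = predict_next((0, 2, 0), atlas, NOISELESS, rng=rng, on_empty="chance")
        assert r != 0

    def test_huge_noise_selects_candidates_uniformly(self, atlas):
        """As sigma grows the argmin over noisy complexities tends to a
        uniform draw from the candidate set."""
        rng = np.random.default_rng(7)
        params = PredictorParams(sigma=1e6, k_max=10**9)
        prefix = (0, 1, 2, 3, 4)  # 6 candidates (3! completions)
        cs = CandidateSet(atlas, prefix, params)
        assert len(cs) == 6
        counts = Counter(
            predict_next(prefix, atlas, params, rng=rng) for _ in range(1200)
        )
        # 3 possible next locations, weighted 2:2:2 by completions
        chi = stats.chisquare(list(counts.values()))
        assert len(counts) == 3
        assert chi.pvalue > 1e-4


class TestNoiseAndResources:
    def test_execution_noise_saturates(self, atlas, rng):
        params = PredictorParams(sigma=0.0, sigma2=1.0)
        responses = Counter(
            predict_next((0, 1), atlas, params, rng=rng) for _ in range(700)
        )
        assert set(responses) == set(range(8)) - {1}

    def test_resource_draws_are_bernoulli(self):
        rng = np.random.default_rng(0)
        assert draw_run_resources(PRESETS["adult"], rng) == RunResources(True, True)
        p = PredictorParams(p_nest=0.0, p_p=1.0)
        assert all(
            draw_run_resources(p, rng).can_nest is False for _ in range(20)
        )
        child = PRESETS["child"]
        draws = [draw_run_resources(child, rng) for _ in range(10_000)]
        f_nest = np.mean([d.can_nest for d in draws])
        f_p = np.mean([d.can_use_p for d in draws])
        assert abs(f_nest - child.p_nest) < 3.5 * np.sqrt(0.14 * 0.86 / 10_000)
        assert abs(f_p - child.p_p) < 3.5 * np.sqrt(0.18 * 0.82 / 10_000)

    def test_missing_P_caps_point_symmetry_sequences(self, atlas):
        params = NOISELESS
        no_p = RunResources(can_nest=True, can_use_p=False)
        cs = CandidateSet(atlas, (0, 4), params, no_p)
        # every sequence opening with a half-turn needs P somewhere
        assert (cs.effective_K == params.k_max).all()
        full = CandidateSet(atlas, (0, 4), params, FULL_RESOURCES)
        assert full.effective_K.min() == 7

    def test_restricted_k_mode_uses_true_restricted_complexity(self, atlas):
        params = PredictorParams(sigma=0.0, restricted_k=True)
        no_nest = RunResources(can_nest=False, can_use_p=True)
        cs = CandidateSet(atlas, (0, 2, 4, 6, 1, 3, 5), params, no_nest)
        assert len(cs) == 1  # the 2squares completion
        i = cs.indices[0]
        assert cs.effective_K[0] == atlas.K_no_nesting[i] > atlas.K[i]

    def test_seed_determinism(self, atlas):
        seq = make_sequence(StimulusSpec("2crosses", 1, -1)).locations
        params = PRESETS["child"]

        def stream(seed):
            rng = np.random.default_rng(seed)
            res = draw_run_resources(params, rng)
            return [
                predict_next(seq[: t - 1], atlas, params, res, rng)
                for t in range(3, 9)
            ]

        assert stream(42) == stream(42)
        assert stream(42) != stream(43) or stream(1) != stream(2)
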