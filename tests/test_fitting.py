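"""Curves, MSE fits, baselines, correlations and the ideal observer."""

import numpy as np
import pandas as pd
import pytest

from geomlang.fitting import (
    accuracy_curves,
    constant_baseline,
    curves_mse,
    fit_sigma,
    ideal_observer_chance,
    mean_spearman,
    model_curves,
    spearman_error_vs_K,
)
from geomlang.language import LanguageError
from geomlang.predictor import PredictorParams
from geomlang.cohort import simulate_cohort


def _toy_table(rows):
    df = pd.DataFrame(
        rows,
        columns=["subject_id", "sequence_family", "ordinal_position", "correct"],
    )
    return df


class TestAccuracyCurves:
    def test_all_correct_gives_ones(self):
        tab = _toy_table([(0, "repeat", p, True) for p in range(3, 9)])
        cur = accuracy_curves(tab)
        assert (cur["accuracy"] == 1.0).all()

    def test_split_outcomes_average(self):
        tab = _toy_table(
            [(0, "2arcs", 5, True), (1, "2arcs", 5, False)]
        )
        cur = accuracy_curves(tab)
        assert cur["accuracy"].item() == 0.5
        assert cur["n"].item() == 2

    def test_empty_table_rejected(self):
        with pytest.raises(LanguageError):
            accuracy_curves(_toy_table([]))
        with pytest.raises(LanguageError):
            accuracy_curves(
                _toy_table([(0, "repeat", 3, True)]), families=["2arcs"]
            )

    def test_mse_invariant_to_row_order(self, rng):
        rows = [
            (s, f, p, bool(rng.integers(2)))
            for s in range(4)
            for f in ("repeat", "2arcs")
            for p in range(3, 9)
        ]
        a = accuracy_curves(_toy_table(rows))
        b = accuracy_curves(_toy_table(list(reversed(rows))))
        assert curves_mse(a, b) == 0.0


class TestBaselinesAndCorrelation:
    def test_constant_baseline_of_flat_curves_is_zero(self):
        cur = pd.DataFrame(
            {
                "sequence_family": ["repeat"] * 3 + ["2arcs"] * 3,
                "ordinal_position": [3, 4, 5] * 2,
                "accuracy": [0.9] * 3 + [0.4] * 3,
                "n": [10] * 6,
            }
        )
        consts, mse = constant_baseline(cur)
        assert consts == pytest.approx({"repeat": 0.9, "2arcs": 0.4})
        assert mse == pytest.approx(0.0, abs=1e-12)

    def test_single_position_curves_have_zero_variance(self):
        cur = pd.DataFrame(
            {
                "sequence_family": ["repeat", "2arcs"],
                "ordinal_position": [3, 3],
                "accuracy": [1.0, 0.2],
                "n": [5, 5],
            }
        )
        _, mse = constant_baseline(cur)
        assert mse == 0.0

    def test_spearman_signs(self):
        # errors perfectly ordered by K -> rho = 1; anti-ordered -> -1
        ks = {"repeat": 5, "2squares": 8, "2rectangles": 10, "irregular": 16}
        rows = []
        for i, fam in enumerate(ks):
            n_err = i  # increasing error with K
            rows += [(0, fam, 3 + j, j >= n_err) for j in range(4)]
            rows += [(1, fam, 3 + j, j < n_err) for j in range(4)]
        tab = _toy_table(rows)
        per = spearman_error_vs_K(tab, k_by_family=ks, families=list(ks))
        assert per.loc[per.subject_id == 0, "rho"].item() == pytest.approx(1.0)
        assert per.loc[per.subject_id == 1, "rho"].item() == pytest.approx(-1.0)

    def test_constant_errors_flagged_undefined(self):
        rows = [(0, f, p, True) for f in ("repeat", "2arcs") for p in (3, 4)]
        per = spearman_error_vs_K(_toy_table(rows))
        assert not per["defined"].item()
        assert np.isnan(per["rho"].item())


class TestIdealObserver:
    @pytest.mark.parametrize("pos,err", [(7, 0.5), (8, 0.0), (3, 5 / 6)])
    def test_closed_form(self, pos, err):
        assert ideal_observer_chance(pos) == pytest.approx(err)

    def test_against_simulated_guesser(self, rng):
        """Monte-carlo check: a guesser avoiding visited locations."""
        for pos in (4, 6, 8):
            errs = 0
            n = 4000
            for _ in range(n):
                perm = rng.permutation(8)
                unvisited = perm[pos - 1 :]
                errs += int(unvisited[rng.integers(len(unvisited))] != perm[pos - 1])
            assert errs / n == pytest.approx(
                ideal_observer_chance(pos), abs=4 * np.sqrt(0.25 / n)
            )

    def test_out_of_range(self):
        for pos in (2, 9):
            with pytest.raises(LanguageError):
                ideal_observer_chance(pos)


class TestFits:
    def test_single_point_grid_returns_it(self, atlas):
        obs = model_curves(PredictorParams(sigma=0), n_runs=10, seed=3, atlas=atlas)
        fit = fit_sigma(obs, grid=[1.5], n_runs=10, seed=4, atlas=atlas)
        assert fit.best == (1.5,)
        assert fit.best_mse >= 0

    def test_noiseless_self_fit_prefers_zero(self, atlas):
        tab = simulate_cohort(
            "adult", 40, PredictorParams(sigma=0), seed=6, atlas=atlas,
            battery="shared",
        )
        obs = accuracy_curves(tab)
        fit = fit_sigma(obs, grid=[0.0, 2.0, 4.0], n_runs=40, seed=7, atlas=atlas)
        assert fit.best == (0.0,)

    def test_model_beats_flat_baseline_on_structured_curves(self, atlas):
        tab = simulate_cohort(
            "adult", 60, PredictorParams(sigma=2), seed=8, atlas=atlas,
            battery="shared",
        )
        obs = accuracy_curves(tab)
        fit = fit_sigma(obs, grid=[2.0], n_runs=60, seed=9, atlas=atlas)
        _, base_mse = constant_baseline(obs)
        assert fit.best_mse < base_mse

    def test_positive_complexity_correlation_under_noise(self, atlas):
        tab = simulate_cohort(
            "adult", 40, PredictorParams(sigma=2), seed=10, atlas=atlas,
            battery="shared",
        )
        assert mean_spearman(tab) > 0
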