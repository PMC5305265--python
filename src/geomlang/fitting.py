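"""Accuracy curves, grid-search fits, baselines and control predictors.

The fitting pipeline mirrors how the model is confronted with behavior:
per-family per-position correct-rate curves are computed from a behavioral
table, a parameter grid is scanned by simulating a fresh cohort of model
runs at every grid point, and the mean squared error between model and
observed curves (equal weight on every family x position cell, over the 8
shared families) selects the fit.  An 8-parameter constant-per-family fit
serves as the reference baseline, and the closed-form ideal observer (a
guesser who avoids previously visited locations) gives the chance curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import ComplexityAtlas, default_atlas
from .cohort import simulate_cohort
from .language import LanguageError
from .predictor import PredictorParams
from .stimuli import FAMILY_K, SHARED_FAMILIES

#: Default scoring window: ordinal positions of the first presentation,
#: starting at the first guessable position.
FIRST_PRESENTATION = (3, 8)
ALL_POSITIONS = (3, 16)


def accuracy_curves(
    table: pd.DataFrame,
    window: tuple[int, int] = ALL_POSITIONS,
    families: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Mean accuracy per (family, ordinal position).

    Returns a tidy frame with columns ``sequence_family``,
    ``ordinal_position``, ``accuracy`` and ``n``.
    """
    if len(table) == 0:
        raise LanguageError("empty behavioral table")
    t = table
    lo, hi = window
    t = t[(t["ordinal_position"] >= lo) & (t["ordinal_position"] <= hi)]
    if families is not None:
        t = t[t["sequence_family"].isin(families)]
    if len(t) == 0:
        raise LanguageError(f"no rows in window {window} / families {families}")
    g = (
        t.groupby(["sequence_family", "ordinal_position"])["correct"]
        .agg(accuracy="mean", n="size")
        .reset_index()
    )
    return g


def curves_mse(model: pd.DataFrame, observed: pd.DataFrame) -> float:
    """MSE between two accuracy-curve frames over their shared cells."""
    m = model.merge(
        observed,
        on=["sequence_family", "ordinal_position"],
        suffixes=("_model", "_obs"),
    )
    if len(m) == 0:
        raise LanguageError("model and observed curves share no cells")
    return float(((m["accuracy_model"] - m["accuracy_obs"]) ** 2).mean())


def model_curves(
    params: PredictorParams,
    group: str = "adult",
    n_runs: int = 300,
    seed: int = 0,
    atlas: Optional[ComplexityAtlas] = None,
    window: tuple[int, int] = ALL_POSITIONS,
) -> pd.DataFrame:
    """Average model performance per position over ``n_runs`` runs of the
    shared-family battery."""
    table = simulate_cohort(
        group, n_runs, params, seed=seed, atlas=atlas, battery="shared"
    )
    return accuracy_curves(table, window=window, families=SHARED_FAMILIES)


@dataclass
class FitResult:
    """A scanned grid with its MSE profile."""

    param_names: tuple[str, ...]
    grid: list[tuple]
    mse: np.ndarray
    n_runs: int
    meta: dict = field(default_factory=dict)

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.mse))

    @property
    def best(self) -> tuple:
        return self.grid[self.best_index]

    @property
    def best_mse(self) -> float:
        return float(self.mse[self.best_index])

    @property
    def ties(self) -> list[tuple]:
        """Every grid point attaining the minimum (reported, never hidden)."""
        m = self.mse.min()
        return [g for g, v in zip(self.grid, self.mse) if v == m]

    def as_dict(self) -> dict:
        return {
            "param_names": list(self.param_names),
            "grid": [list(g) for g in self.grid],
            "mse": [float(v) for v in self.mse],
            "best": list(self.best),
            "best_mse": self.best_mse,
            "ties": [list(t) for t in self.ties],
            "n_runs": self.n_runs,
            "meta": self.meta,
        }


DEFAULT_SIGMA_GRID = tuple(np.arange(0.0, 6.01, 0.5))
DEFAULT_P_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))


def fit_sigma(
    observed: pd.DataFrame,
    grid: Iterable[float] = DEFAULT_SIGMA_GRID,
    n_runs: int = 300,
    seed: int = 0,
    group: str = "adult",
    window: tuple[int, int] = ALL_POSITIONS,
    atlas: Optional[ComplexityAtlas] = None,
    sigma2: float = 0.0,
) -> FitResult:
    """Scan the encoding-noise grid against observed curves (full-resource
    model, no execution noise unless given)."""
    grid = [float(s) for s in grid]
    if not grid:
        raise LanguageError("empty sigma grid")
    atlas = default_atlas() if atlas is None else atlas
    # common random numbers: every grid point reuses the same simulation
    # seed, so grid comparisons are not blurred by independent Monte-Carlo
    # noise (resource draws couple monotonically in the probabilities)
    mses = []
    for sigma in grid:
        params = PredictorParams(sigma=sigma, sigma2=sigma2)
        curves = model_curves(params, group, n_runs, seed, atlas, window)
        mses.append(curves_mse(curves, observed))
    return FitResult(
        ("sigma",),
        [(s,) for s in grid],
        np.array(mses),
        n_runs,
        {"group": group, "window": list(window), "sigma2": sigma2, "seed": seed},
    )


def fit_resources(
    observed: pd.DataFrame,
    p_nest_grid: Iterable[float] = DEFAULT_P_GRID,
    p_p_grid: Iterable[float] = DEFAULT_P_GRID,
    sigma: float = 3.0,
    n_runs: int = 300,
    seed: int = 0,
    group: str = "child",
    window: tuple[int, int] = ALL_POSITIONS,
    atlas: Optional[ComplexityAtlas] = None,
) -> FitResult:
    """Scan the (p_nest, p_p) probability grid at fixed encoding noise and
    no execution noise (the resource-restriction fit)."""
    pn = [float(p) for p in p_nest_grid]
    pp = [float(p) for p in p_p_grid]
    if not pn or not pp:
        raise LanguageError("empty probability grid")
    if any(not 0 <= p <= 1 for p in pn + pp):
        raise LanguageError("probability grids must lie in [0, 1]")
    atlas = default_atlas() if atlas is None else atlas
    grid, mses = [], []
    for a in pn:
        for b in pp:
            params = PredictorParams(sigma=sigma, sigma2=0.0, p_nest=a, p_p=b)
            curves = model_curves(params, group, n_runs, seed, atlas, window)
            grid.append((a, b))
            mses.append(curves_mse(curves, observed))
    return FitResult(
        ("p_nest", "p_p"),
        grid,
        np.array(mses),
        n_runs,
        {
            "group": group,
            "window": list(window),
            "sigma": sigma,
            "seed": seed,
            "shape": [len(pn), len(pp)],
        },
    )


def flat_region(fit: FitResult, tolerance: float = 0.005) -> list[tuple]:
    """Grid points whose MSE is within ``tolerance`` of the minimum (the
    fit surface can be nearly flat over a broad region)."""
    return [g for g, v in zip(fit.grid, fit.mse) if v <= fit.best_mse + tolerance]


def constant_baseline(observed: pd.DataFrame) -> tuple[dict, float]:
    """The simplest reference fit: one constant accuracy per family (8
    parameters over the shared families).  Returns the constants and the
    MSE of that fit to the observed curves."""
    fams = observed["sequence_family"].unique()
    constants = {}
    sq = 0.0
    n = 0
    for fam in fams:
        sub = observed[observed["sequence_family"] == fam]
        c = float(sub["accuracy"].mean())
        constants[fam] = c
        sq += float(((sub["accuracy"] - c) ** 2).sum())
        n += len(sub)
    return constants, sq / n


def spearman_error_vs_K(
    table: pd.DataFrame,
    k_by_family: Optional[dict] = None,
    families: Sequence[str] = SHARED_FAMILIES,
) -> pd.DataFrame:
    """Per-subject Spearman rank correlation between family error rate and
    family complexity K.

    Returns one row per subject with ``rho`` and ``defined`` (False when
    the subject's error rates are constant, leaving the correlation
    undefined rather than silently zero).
    """
    k_by_family = dict(FAMILY_K) if k_by_family is None else k_by_family
    t = table[table["sequence_family"].isin(families)]
    if t["sequence_family"].nunique() < 2:
        raise LanguageError("need at least 2 families for a rank correlation")
    rows = []
    for subject, sub in t.groupby("subject_id"):
        err = 1.0 - sub.groupby("sequence_family")["correct"].mean()
        ks = np.array([k_by_family[f] for f in err.index])
        if err.nunique() <= 1 or len(err) < 2:
            rows.append({"subject_id": subject, "rho": np.nan, "defined": False})
            continue
        rho = stats.spearmanr(ks, err.to_numpy()).statistic
        rows.append({"subject_id": subject, "rho": float(rho), "defined": True})
    return pd.DataFrame(rows)


def mean_spearman(table: pd.DataFrame, **kw) -> float:
    per = spearman_error_vs_K(table, **kw)
    return float(per.loc[per["defined"], "rho"].mean())


def ideal_observer_chance(position: int) -> float:
    """Expected error rate (fraction) at an ordinal position for a guesser
    who knows locations never repeat and chooses uniformly among unvisited
    vertices: ``1 - 1/(9 - position)`` for positions 3-8."""
    if not 3 <= position <= 8:
        raise LanguageError(f"position must be in 3..8, got {position}")
    return 1.0 - 1.0 / (9 - position)
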