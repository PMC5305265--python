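"""The noisy minimal-complexity sequence predictor.

Given the prefix of an unfolding sequence, the model considers every
complete 8-location sequence consistent with it (atlas rows, matched up to
rotation; positions past 8 continue the sequence cyclically, since a trial
shows the sequence twice), perturbs each candidate's complexity with
additive Gaussian noise of standard deviation ``sigma``, and bets on the
least (noisy) complex completion.  If even that winning complexity exceeds
the capacity limit ``K_max`` the response is a guess among the 7 vertices
other than the current one.  A second noise source, ``sigma2``, overwrites
the response with a random guess (an execution error) with fixed
probability.

Limited-language subjects are modeled probabilistically: each simulated run
draws two resources -- whether nested repetitions are available
(``p_nest``) and whether the point symmetry P is available (``p_p``).  A
sequence whose minimal programs require a missing resource has its
complexity capped at ``K_max``, rendering it useless for extracting
regularity (the exact restricted-language complexity, where it exists, is
available as an alternative mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .atlas import ComplexityAtlas, UNREACHABLE
from .language import LanguageError


@dataclass(frozen=True)
class PredictorParams:
    """One record fully determines a simulated population."""

    sigma: float = 2.0  # sd of Gaussian noise on complexity estimates
    sigma2: float = 0.0  # probability of a random execution error
    k_max: int = 12  # capacity limit on usable complexity
    p_nest: float = 1.0  # probability a run can use nested repetitions
    p_p: float = 1.0  # probability a run can use the point symmetry
    restricted_k: bool = False  # use true restricted-language K when finite

    def __post_init__(self):
        if self.sigma < 0:
            raise LanguageError("sigma must be >= 0")
        for name in ("sigma2", "p_nest", "p_p"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise LanguageError(f"{name} must be in [0, 1], got {v}")
        if self.k_max <= 0:
            raise LanguageError("k_max must be positive")


#: Fitted presets for the three populations.
PRESETS: dict[str, PredictorParams] = {
    "adult": PredictorParams(sigma=2.0, sigma2=0.0, p_nest=1.0, p_p=1.0),
    "child": PredictorParams(sigma=3.0, sigma2=0.0, p_nest=0.14, p_p=0.18),
    "munduruku": PredictorParams(sigma=3.0, sigma2=0.0, p_nest=0.54, p_p=0.26),
}


@dataclass(frozen=True)
class RunResources:
    """Per-run language resources (drawn once per simulated subject)."""

    can_nest: bool = True
    can_use_p: bool = True


FULL_RESOURCES = RunResources(True, True)


def draw_run_resources(params: PredictorParams, rng: np.random.Generator) -> RunResources:
    """Independent Bernoulli draws of the two resources."""
    return RunResources(
        can_nest=bool(rng.random() < params.p_nest),
        can_use_p=bool(rng.random() < params.p_p),
    )


class CandidateSet:
    """Atlas rows consistent with an observed prefix, with their effective
    complexities under the run's resources."""

    def __init__(
        self,
        atlas: ComplexityAtlas,
        prefix,
        params: PredictorParams,
        resources: RunResources = FULL_RESOURCES,
    ):
        p = tuple(int(x) for x in prefix)
        if len(p) < 2:
            raise LanguageError("prefix must have at least 2 locations")
        self.prefix = p
        self.rotation = p[0] % 8  # atlas rows start at the origin 0
        rp = tuple((x - self.rotation) % 8 for x in p)
        lo, hi = atlas.prefix_range(rp[:8])
        idx = np.arange(lo, hi)
        if len(p) > 8:
            # cyclic continuation: the 16-item trial is the sequence twice
            keep = [
                i
                for i in idx
                if all(
                    atlas.seqs[i][j % 8] == rp[j] for j in range(8, len(rp))
                )
            ]
            idx = np.array(keep, dtype=int)
        self.indices = idx
        self.atlas = atlas
        self.effective_K = self._effective_k(params, resources)

    def __len__(self) -> int:
        return len(self.indices)

    def _effective_k(self, params: PredictorParams, res: RunResources) -> np.ndarray:
        a, idx = self.atlas, self.indices
        k = a.K[idx].astype(float)
        if params.restricted_k:
            if not res.can_use_p:
                kp = a.K_no_p[idx].astype(float)
                kp[a.K_no_p[idx] == UNREACHABLE] = np.inf
                k = np.maximum(k, kp)
            if not res.can_nest:
                kn = a.K_no_nesting[idx].astype(float)
                kn[a.K_no_nesting[idx] == UNREACHABLE] = np.inf
                k = np.maximum(k, kn)
            np.minimum(k, max(params.k_max, 16), out=k)
            k[np.isinf(k)] = params.k_max
            return k
        if not res.can_use_p:
            k[a.uses_P[idx]] = params.k_max
        if not res.can_nest:
            k[a.uses_nesting[idx]] = params.k_max
        return k

    def next_location(self, i: int) -> int:
        """The continuation the i-th candidate predicts, in trial frame."""
        row = self.atlas.seqs[self.indices[i]]
        return (int(row[len(self.prefix) % 8]) + self.rotation) % 8


def _random_other(current: int, rng: np.random.Generator) -> int:
    """Uniform guess among the 7 vertices other than the current one."""
    return int((current + 1 + rng.integers(7)) % 8)


def predict_next(
    prefix,
    atlas: ComplexityAtlas,
    params: PredictorParams,
    resources: RunResources = FULL_RESOURCES,
    rng: Optional[np.random.Generator] = None,
    on_empty: str = "error",
) -> int:
    """One response of the noisy minimal-complexity predictor.

    ``on_empty`` controls what happens when no complete sequence in the
    hypothesis space matches the prefix (possible only for stimuli outside
    the no-revisit space, e.g. the short span controls): ``"error"`` raises,
    ``"chance"`` answers like an over-capacity guess.
    """
    rng = np.random.default_rng() if rng is None else rng
    current = int(prefix[-1])
    cs = CandidateSet(atlas, prefix, params, resources)
    if len(cs) == 0:
        if on_empty == "chance":
            return _random_other(current, rng)
        raise LanguageError(f"prefix {tuple(prefix)} matches no candidate sequence")
    noisy = cs.effective_K + rng.normal(0.0, params.sigma, size=len(cs))
    winners = np.flatnonzero(noisy == noisy.min())
    pick = int(winners[rng.integers(len(winners))]) if len(winners) > 1 else int(winners[0])
    if noisy[pick] <= params.k_max:
        response = cs.next_location(pick)
    else:
        response = _random_other(current, rng)
    if params.sigma2 > 0 and rng.random() < params.sigma2:
        response = _random_other(current, rng)
    return response
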