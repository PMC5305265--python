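"""Stimulus sequences and experimental batteries.

Each named family is a construction over the octagon: a progression
(``repeat``), a two-instruction zigzag (``alternate``), a shape redrawn
under a transform (``2squares``, ``2arcs``, ``4segments``, ``4diagonals``),
doubly nested shapes (``2rectangles``, ``2crosses``), incompressible
sequences (``irregular``), and the short memory-span controls (``2points``,
``4points``, scored on their 8-emission cyclic trial encoding).

Every generated instance is checked against the family's nominal complexity
at construction time, so randomization (starts, directions, axes) can never
silently change what the stimulus measures.

A :class:`Trial` wraps a sequence in a presentation protocol: adults see a
16-location stream (the sequence twice) and guess from the 3rd location
onward; children answer in two phases (view 5 / guess 3, then view 3 /
guess 5, i.e. ordinals 6-8 and 12-16 of the same 16-location stream).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .complexity import minimal_description
from .language import (
    Atom,
    LanguageError,
    MOVES,
    Program,
    Repeat,
    RepeatVar,
    emit,
)

AXES = ("H", "V", "A", "B")

#: Nominal complexity of each family's instances (2/4-location families are
#: scored on their 8-emission cyclic trial encoding).
FAMILY_K = {
    "repeat": 5,
    "repeat+2": 5,
    "alternate": 7,
    "2arcs": 8,
    "2squares": 8,
    "4segments": 7,
    "4diagonals": 7,
    "2rectangles": 10,
    "2crosses": 7,
    "irregular": 16,
    "2points": 6,
    "4points": 9,
}

FAMILIES = tuple(FAMILY_K)

#: The eight families shared by every experimental group and spanning all 8
#: locations without revisits -- the set over which models are fitted.
SHARED_FAMILIES = (
    "repeat",
    "2arcs",
    "2squares",
    "4segments",
    "4diagonals",
    "2rectangles",
    "2crosses",
    "irregular",
)

_AXIS_BY_C = {7: "H", 3: "V", 1: "A", 5: "B"}


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of one stimulus instance."""

    name: str
    start: int = 0
    direction: int = 1  # +1 clockwise, -1 counterclockwise
    axis: Optional[str] = None  # for 4segments / 2rectangles
    seed: int = 0  # for the sampled families (irregular, 4points)


@dataclass(frozen=True)
class Stimulus:
    spec: StimulusSpec
    locations: tuple[int, ...]
    K: int
    program: Optional[Program] = None  # constructive witness, when one exists

    @property
    def name(self) -> str:
        return self.spec.name


def _from_program(spec: StimulusSpec, program: Program, anchor: int) -> Stimulus:
    locs = tuple(emit(program, anchor))
    return Stimulus(spec, locs, FAMILY_K[spec.name], program)


#: Verified instances: locations -> K (every generated instance is searched
#: once; repeated randomizations hit the cache).
_K_CACHE: dict[tuple[int, ...], int] = {}


def _verified_k(locations: tuple[int, ...]) -> int:
    k = _K_CACHE.get(locations)
    if k is None:
        k = minimal_description(locations, max_witnesses=0).K
        _K_CACHE[locations] = k
    return k


def make_sequence(spec: StimulusSpec, atlas=None) -> Stimulus:
    """Construct one stimulus instance; its complexity is verified against
    the family's nominal K.  Passing a prebuilt atlas lets the sampled
    families draw directly from its maximal-complexity rows."""
    name, s0, d = spec.name, spec.start % 8, spec.direction
    if d not in (+1, -1):
        raise LanguageError(f"direction must be +1 or -1, got {spec.direction}")
    if spec.axis is not None and name not in ("4segments", "2rectangles"):
        raise LanguageError(f"family {name!r} takes no axis parameter")
    if spec.axis is not None and spec.axis not in AXES:
        raise LanguageError(f"unknown axis {spec.axis!r}")
    rng = np.random.default_rng(spec.seed)

    if name == "repeat":
        step = "+1" if d > 0 else "-1"
        stim = _from_program(spec, Repeat(Atom(step), 8), (s0 - d) % 8)
    elif name == "repeat+2":
        step = "+2" if d > 0 else "-2"
        stim = _from_program(spec, Repeat(Atom(step), 8), (s0 - 2 * d) % 8)
    elif name == "alternate":
        back = "-1" if d > 0 else "+1"
        shift = "+2" if d > 0 else "-2"
        stim = _from_program(spec, RepeatVar(Atom(back), 4, shift), s0)
    elif name == "2squares":
        step = "+2" if d > 0 else "-2"
        shift = "+1" if d > 0 else "-1"
        stim = _from_program(spec, RepeatVar(Repeat(Atom(step), 3), 2, shift), s0)
    elif name == "2arcs":
        step = "+1" if d > 0 else "-1"
        c = (2 * s0 + 7 * d) % 8  # the unique axis flipping this arc onto
        axis = _AXIS_BY_C[c]  # the four remaining locations
        stim = _from_program(spec, RepeatVar(Repeat(Atom(step), 3), 2, axis), s0)
    elif name == "4segments":
        axis = spec.axis or AXES[rng.integers(4)]
        shift = "+2" if d > 0 else "-2"
        stim = _from_program(spec, RepeatVar(Atom(axis), 4, shift), s0)
        if _verified_k(stim.locations) != FAMILY_K[name]:
            # a distance-1 segment shifted along its own direction degenerates
            # into the plain progression; the opposite shift preserves the
            # four-parallel-segments shape
            shift = "-2" if d > 0 else "+2"
            stim = _from_program(spec, RepeatVar(Atom(axis), 4, shift), s0)
    elif name == "4diagonals":
        shift = "+1" if d > 0 else "-1"
        stim = _from_program(spec, RepeatVar(Atom("P"), 4, shift), s0)
    elif name == "2rectangles":
        axis = spec.axis or AXES[rng.integers(4)]
        partner = _AXIS_BY_C[(MOVES[axis] - 8 + 4) % 8]  # the parallel axis
        shift = "+2" if d > 0 else "-2"
        inner = RepeatVar(Atom(axis), 2, partner)
        stim = _from_program(spec, RepeatVar(inner, 2, shift), s0)
    elif name == "2crosses":
        shift = "+3" if d > 0 else "-3"
        stim = _from_program(spec, RepeatVar(Atom("P"), 4, shift), s0)
    elif name == "irregular":
        stim = _sample_irregular(spec, rng, atlas)
    elif name == "2points":
        pair = (s0, (s0 + 2 * d) % 8)
        stim = Stimulus(spec, pair * 4, FAMILY_K[name])
    elif name == "4points":
        stim = _sample_4points(spec, rng)
    else:
        raise LanguageError(f"unknown stimulus family: {name!r}")

    actual = _verified_k(stim.locations)
    if actual != FAMILY_K[name]:
        raise LanguageError(
            f"{name} instance {stim.locations} has K={actual}, "
            f"expected {FAMILY_K[name]}"
        )
    return stim


def _sample_irregular(spec: StimulusSpec, rng, atlas=None) -> Stimulus:
    """Uniform draw from the maximal-complexity class (768 of the 5040
    no-revisit sequences are incompressible).  With an atlas the draw is a
    direct row pick (rotated to the requested start; K is invariant under
    rotation); otherwise rejection sampling against the searcher."""
    s0 = spec.start % 8
    if atlas is not None:
        rows = getattr(atlas, "_max_k_rows", None)
        if rows is None:
            rows = np.flatnonzero(atlas.K == atlas.K.max())
            atlas._max_k_rows = rows
        row = atlas.seqs[rows[rng.integers(len(rows))]]
        seq = tuple((int(x) + s0) % 8 for x in row)
        _K_CACHE.setdefault(seq, 16)
        return Stimulus(spec, seq, 16)
    others = [v for v in range(8) if v != s0]
    for _ in range(1000):
        perm = list(others)
        rng.shuffle(perm)
        seq = (s0, *perm)
        if _verified_k(seq) == 16:
            return Stimulus(spec, seq, 16)
    raise LanguageError("failed to sample an incompressible sequence")


def _sample_4points(spec: StimulusSpec, rng) -> Stimulus:
    """A 4-location loop whose cyclic 8-emission encoding attains the
    maximal 4-loop complexity (K = 9), verified by search at generation."""
    s0 = spec.start % 8
    others = [v for v in range(8) if v != s0]
    for _ in range(1000):
        pick = list(rng.choice(others, size=3, replace=False))
        loop = (s0, *[int(x) for x in pick])
        seq = loop * 2
        if _verified_k(seq) == 9:
            return Stimulus(spec, seq, 9)
    raise LanguageError("failed to sample an incompressible 4-point loop")


# ---------------------------------------------------------------------------
# Trials and batteries
# ---------------------------------------------------------------------------

ADULT_RESPONSE_POSITIONS = tuple(range(3, 17))
#: Children answer ordinals 6-8 (after viewing 5) and 12-16 (after
#: re-viewing the first 3 of the sequence).
CHILD_RESPONSE_POSITIONS = (6, 7, 8, 12, 13, 14, 15, 16)


@dataclass(frozen=True)
class Trial:
    stimulus: Stimulus
    protocol: str  # "adult" | "child"
    index: int = 0
    n_previews: int = 0  # passive full viewings before responding

    @property
    def presentation(self) -> tuple[int, ...]:
        """The 16-location stream: the 8-emission encoding shown twice."""
        return self.stimulus.locations * 2

    @property
    def response_positions(self) -> tuple[int, ...]:
        if self.protocol == "adult":
            return ADULT_RESPONSE_POSITIONS
        return CHILD_RESPONSE_POSITIONS

    def phase(self, position: int) -> int:
        """1 for the first presentation of the sequence, 2 for the second."""
        return 1 if position <= 8 else 2

    def prefix(self, position: int) -> tuple[int, ...]:
        """What the subject has veridically seen before guessing at
        ``position`` (errors are corrected, so the prefix is the truth).
        In the child protocol the second phase restarts the sequence, so its
        guesses condition only on the re-shown opening."""
        if self.protocol == "child" and position > 8:
            return self.stimulus.locations[: position - 9]
        return self.presentation[: position - 1]

    def target(self, position: int) -> int:
        if self.protocol == "child" and position > 8:
            return self.stimulus.locations[position - 9]
        return self.presentation[position - 1]


def preview_mode(trial: Trial, n_previews: int) -> Trial:
    """Annotate a trial with passive full viewings (protocol fidelity only:
    the memoryless predictor is unaffected, mirroring the finding that
    previews did not change performance)."""
    if n_previews < 0:
        raise LanguageError(f"n_previews must be >= 0, got {n_previews}")
    if n_previews == 0:
        return trial
    return replace(trial, n_previews=n_previews)


def _make(rng, name, atlas=None, **fixed) -> Stimulus:
    return make_sequence(_spec(rng, name, **fixed), atlas=atlas)


def _spec(rng, name, **fixed) -> StimulusSpec:
    kw = dict(
        start=int(rng.integers(8)),
        direction=int(rng.choice([-1, 1])),
        seed=int(rng.integers(2**31 - 1)),
    )
    kw.update(fixed)
    return StimulusSpec(name, **kw)


def make_battery(
    group: str, seed: int = 0, n_previews: int = 0, atlas=None
) -> list[Trial]:
    """The trial list of one experimental session.

    Adults: 2 repeat + 2 alternate + 2 2squares + 2 2arcs + 4 4segments
    (one per axis) + 1 4diagonals + 1 2rectangles + 1 2crosses + 2 irregular
    = 16 trials.  Children: a single exemplar per family except 4segments
    (4, one per axis), with alternate replaced by repeat+2 and the 2- and
    4-location span controls added = 14 trials.  A repeat trial always
    comes first; the rest are shuffled.  Starts, directions and sampled
    instances are randomized per battery.
    """
    rng = np.random.default_rng(seed)
    stims: list[Stimulus] = []
    if group == "adult":
        for d in (1, -1):
            stims.append(_make(rng, "repeat", atlas, direction=d))
        for d in (1, -1):
            stims.append(_make(rng, "alternate", atlas, direction=d))
        for d in (1, -1):
            stims.append(_make(rng, "2squares", atlas, direction=d))
        for _ in range(2):
            stims.append(_make(rng, "2arcs", atlas))
        for axis in AXES:
            stims.append(_make(rng, "4segments", atlas, axis=axis))
        stims.append(_make(rng, "4diagonals", atlas))
        stims.append(_make(rng, "2rectangles", atlas))
        stims.append(_make(rng, "2crosses", atlas))
        for _ in range(2):
            stims.append(_make(rng, "irregular", atlas))
        protocol = "adult"
    elif group == "child":
        stims.append(_make(rng, "repeat", atlas))
        stims.append(_make(rng, "repeat+2", atlas))
        stims.append(_make(rng, "2arcs", atlas))
        stims.append(_make(rng, "2squares", atlas))
        for axis in AXES:
            stims.append(_make(rng, "4segments", atlas, axis=axis))
        stims.append(_make(rng, "4diagonals", atlas))
        stims.append(_make(rng, "2rectangles", atlas))
        stims.append(_make(rng, "2crosses", atlas))
        stims.append(_make(rng, "irregular", atlas))
        stims.append(_make(rng, "2points", atlas))
        stims.append(_make(rng, "4points", atlas))
        protocol = "child"
    else:
        raise LanguageError(f"unknown group: {group!r} (adult or child)")

    first = next(i for i, s in enumerate(stims) if s.name == "repeat")
    rest = [s for i, s in enumerate(stims) if i != first]
    order = rng.permutation(len(rest))
    ordered = [stims[first]] + [rest[i] for i in order]
    return [
        Trial(s, protocol, index=i, n_previews=n_previews)
        for i, s in enumerate(ordered)
    ]


def fitting_battery(group: str, seed: int = 0, atlas=None) -> list[Trial]:
    """One trial per shared family (the 8 sequences used in all groups with
    no location revisits): the stimulus set over which model curves are
    computed and parameters fitted."""
    rng = np.random.default_rng(seed)
    protocol = "adult" if group == "adult" else "child"
    stims = []
    for name in SHARED_FAMILIES:
        if name == "4segments":
            stims.append(_make(rng, name, atlas, axis=AXES[rng.integers(4)]))
        else:
            stims.append(_make(rng, name, atlas))
    return [Trial(s, protocol, index=i) for i, s in enumerate(stims)]
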