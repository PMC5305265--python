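"""A minimal language of geometry on the regular octagon.

The eight vertices of a regular octagon are labeled 0-7 clockwise (flat-top
convention).  A *program* describes a trajectory over those vertices as a
sequence of primitive transitions -- rotations, axial reflections and the
point symmetry -- optionally compressed by repetition (``[x]^n``) and by
repetition-with-variation (``[x]^n<v>``), in which a whole sub-figure is
redrawn under a global transform at each repetition.

Every primitive and every variation acts on a vertex as an affine map
``x -> x + a (mod 8)`` (rotations) or ``x -> c - x (mod 8)`` (reflections
about the axis parameterized by ``c``).  The four named axial symmetries use
the edge-bisector axes ``c in {7, 3, 1, 5}`` (H, V, A, B respectively), the
unique convention under which every one of the 7 displacements between
distinct vertices is realizable by a single primitive.

Plain repetition ``[x]^n`` continues from the current position, and an
*executed* repetition must trace a closed tour: after its ``n`` iterations
it returns to where it started (the full-circle progression ``[+1]^8``, a
two-point alternation ``[A]^8``, a repeated closed loop of four points),
and a block drawing more than one location must already close on every
iteration.  Inside the figure of a repetition-with-variation the rule
relaxes for single instructions: there ``[+2]^3`` abbreviates an open
stroke (the three sides of a square completed by the variation).  Without
the closed-tour rule, repetition of open strokes would compress sequences
that the calibration defines as incompressible (e.g. the zigzag of
parallel segments would collapse to a two-instruction loop even in the
rotations-only control language, where its complexity must stay maximal).

The description length (cost) of a program is the package's operational
proxy for Kolmogorov complexity: each primitive instruction costs a fixed
amount (2 units), repeating a block ``n`` times adds ``ceil(log2 n)`` units,
and a variation adds the transform's own cost plus a one-unit flag, so that
even a single repetition shortens a description (2 + 1 < 2 + 2).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Union

N_VERTICES = 8

# ---------------------------------------------------------------------------
# Affine maps on Z/8: encoded as an integer 0..15.
#   idx = a          -> x |-> x + a  (rotation by a)
#   idx = 8 + c      -> x |-> c - x  (reflection about axis c)
# ---------------------------------------------------------------------------

IDENTITY = 0


def affine_apply(m: int, x: int) -> int:
    if m < 8:
        return (x + m) % 8
    return (m - 8 - x) % 8


def affine_compose(m2: int, m1: int) -> int:
    """The map ``x -> m2(m1(x))``."""
    if m1 < 8:
        if m2 < 8:
            return (m1 + m2) % 8
        return 8 + (m2 - 8 - m1) % 8
    if m2 < 8:
        return 8 + (m1 - 8 + m2) % 8
    return (m2 - m1) % 8


APPLY = [[affine_apply(m, x) for x in range(8)] for m in range(16)]
COMPOSE = [[affine_compose(m2, m1) for m1 in range(16)] for m2 in range(16)]


def affine_pow(m: int, i: int) -> int:
    out = IDENTITY
    for _ in range(i):
        out = COMPOSE[m][out]
    return out


# ---------------------------------------------------------------------------
# Primitive movements and variation transforms
# ---------------------------------------------------------------------------

#: Movement primitives of the full language (plus the rotations +-3 and +4
#: that only the degraded control language uses as primitives).  P is the
#: point (rotational) symmetry, equivalent to the rotation +4.
MOVES: dict[str, int] = {
    "0": 0,
    "+1": 1,
    "-1": 7,
    "+2": 2,
    "-2": 6,
    "+3": 3,
    "-3": 5,
    "+4": 4,
    "P": 4,
    "H": 8 + 7,
    "V": 8 + 3,
    "A": 8 + 1,
    "B": 8 + 5,
}

#: The ten primitives of the full language.
FULL_MOVES = ("0", "+1", "-1", "+2", "-2", "H", "V", "A", "B", "P")

#: Transforms admissible in a repetition-with-variation: any nonzero start
#: offset, or a global symmetry.  "P" is accepted as an alias of "+4".
VARIATIONS: dict[str, int] = {
    "+1": 1,
    "+2": 2,
    "+3": 3,
    "+4": 4,
    "-1": 7,
    "-2": 6,
    "-3": 5,
    "P": 4,
    "H": 8 + 7,
    "V": 8 + 3,
    "A": 8 + 1,
    "B": 8 + 5,
}

FULL_VARIATIONS = ("+1", "+2", "+3", "+4", "-1", "-2", "-3", "H", "V", "A", "B")


class LanguageError(ValueError):
    """Unknown primitive, malformed program, or invalid parameter."""


def apply_movement(move: str, x: int) -> int:
    """Apply a single movement primitive to a vertex.

    >>> apply_movement("+1", 0)
    1
    >>> apply_movement("P", 6)
    2
    """
    if move not in MOVES:
        raise LanguageError(f"unknown movement primitive: {move!r}")
    if not 0 <= x < 8:
        raise LanguageError(f"vertex index out of range: {x}")
    return APPLY[MOVES[move]][x]


def apply_variation(var: str, x: int, power: int = 1) -> int:
    if var not in VARIATIONS:
        raise LanguageError(f"unknown variation transform: {var!r}")
    return APPLY[affine_pow(VARIATIONS[var], power)][x]


# ---------------------------------------------------------------------------
# Program syntax
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class Atom:
    move: str

    def __post_init__(self):
        if self.move not in MOVES:
            raise LanguageError(f"unknown movement primitive: {self.move!r}")


@dataclass(frozen=True, slots=True)
class Concat:
    parts: tuple["Program", ...]

    def __post_init__(self):
        if len(self.parts) < 1:
            raise LanguageError("empty concatenation")
        if any(isinstance(p, Concat) for p in self.parts):
            raise LanguageError("concatenation must be flat")


@dataclass(frozen=True, slots=True)
class Repeat:
    block: "Program"
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise LanguageError(f"repetition count must be >= 2, got {self.n}")


@dataclass(frozen=True, slots=True)
class RepeatVar:
    block: "Program"
    n: int
    var: str

    def __post_init__(self):
        if self.n < 2:
            raise LanguageError(f"repetition count must be >= 2, got {self.n}")
        if self.var not in VARIATIONS:
            raise LanguageError(f"unknown variation transform: {self.var!r}")


Program = Union[Atom, Concat, Repeat, RepeatVar]


def concat(*parts: Program) -> Program:
    """Flattening concatenation; a single part is returned unwrapped."""
    flat: list[Program] = []
    for p in parts:
        if isinstance(p, Concat):
            flat.extend(p.parts)
        else:
            flat.append(p)
    if len(flat) == 1:
        return flat[0]
    return Concat(tuple(flat))


# ---------------------------------------------------------------------------
# Execution (emission) semantics
# ---------------------------------------------------------------------------


def _emit(
    node: Program, pos: int, nonempty: bool, in_figure: bool = False
) -> tuple[list[int], int]:
    """Emit ``node`` from current position ``pos``.

    ``nonempty`` is True when at least one location has already been shown
    on screen; a repetition-with-variation physically shows its entry
    location only when the screen is still blank (otherwise the entry is the
    location already on display).  ``in_figure`` is True inside the block of
    a repetition-with-variation, where single-instruction repetitions may
    trace open strokes.
    """
    if isinstance(node, Atom):
        y = APPLY[MOVES[node.move]][pos]
        return [y], y
    if isinstance(node, Concat):
        acc: list[int] = []
        for part in node.parts:
            out, pos = _emit(part, pos, nonempty or bool(acc), in_figure)
            acc.extend(out)
        return acc, pos
    if isinstance(node, Repeat):
        # Closed-tour rule: a block drawing more than one location must
        # return to its entry on every iteration; an executed (non-figure)
        # repetition must close over its n iterations as a whole.
        entry = pos
        acc = []
        for _ in range(node.n):
            start = pos
            out, pos = _emit(node.block, pos, nonempty or bool(acc), in_figure)
            if len(out) > 1 and pos != start:
                raise LanguageError(
                    "invalid repetition: a block drawing more than one "
                    "location must return to its starting location"
                )
            acc.extend(out)
        if not in_figure and pos != entry:
            raise LanguageError(
                "invalid repetition: an executed repetition must trace a "
                "closed tour (return to its starting location); open "
                "strokes may only be repeated inside a variation figure"
            )
        return acc, pos
    if isinstance(node, RepeatVar):
        body, _ = _emit(node.block, pos, True, True)
        figure = [pos] + body
        v = VARIATIONS[node.var]
        acc = []
        vpow = IDENTITY
        for i in range(node.n):
            image = [APPLY[vpow][x] for x in figure]
            if i == 0 and nonempty:
                acc.extend(image[1:])
            else:
                acc.extend(image)
            vpow = COMPOSE[v][vpow]
        return acc, acc[-1]
    raise LanguageError(f"not a program node: {node!r}")


def emit(program: Program, anchor: int) -> list[int]:
    """The stream of displayed vertices when ``program`` runs from ``anchor``.

    The anchor itself is never displayed (and never costed): a program's
    first emission is produced by its first instruction.

    >>> emit(Repeat(Atom("+1"), 8), 7)
    [0, 1, 2, 3, 4, 5, 6, 7]
    >>> emit(RepeatVar(Atom("P"), 4, "+1"), 0)
    [0, 4, 1, 5, 2, 6, 3, 7]
    """
    if not 0 <= anchor < 8:
        raise LanguageError(f"anchor out of range: {anchor}")
    out, _ = _emit(program, anchor, False)
    return out


def leads_with_variation(node: Program) -> bool:
    """True when the program's first instruction is a repetition-with-
    variation, i.e. when its first emission at the start of a blank screen
    is the construct's own entry location."""
    if isinstance(node, RepeatVar):
        return True
    if isinstance(node, Concat):
        return leads_with_variation(node.parts[0])
    if isinstance(node, Repeat):
        return leads_with_variation(node.block)
    return False


def emission_length(node: Program, sequence_initial: bool = True) -> int:
    """Number of locations :func:`emit` would display, computed structurally."""
    n = _emission_length_noninitial(node)
    if sequence_initial and leads_with_variation(node):
        n += 1
    return n


def _emission_length_noninitial(node: Program) -> int:
    if isinstance(node, Atom):
        return 1
    if isinstance(node, Concat):
        return sum(_emission_length_noninitial(p) for p in node.parts)
    if isinstance(node, Repeat):
        return node.n * _emission_length_noninitial(node.block)
    if isinstance(node, RepeatVar):
        return node.n * (1 + _emission_length_noninitial(node.block)) - 1
    raise LanguageError(f"not a program node: {node!r}")


# ---------------------------------------------------------------------------
# Description length
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CostModel:
    """Calibrated description-length constants.

    ``atom_cost`` units per primitive instruction; repeating ``n`` times adds
    ``ceil(log2 n)``; a variation adds the transform's atom cost plus a
    one-unit flag.  These are the unique small integers under which a single
    repetition of an atom is cheaper than writing the atom twice
    (2 + 1 < 4) and all the printed stimulus complexities are attained
    simultaneously.
    """

    atom_cost: int = 2
    variation_overhead: int = 1

    def rep_cost(self, n: int) -> int:
        if n < 2:
            raise LanguageError(f"repetition count must be >= 2, got {n}")
        return math.ceil(math.log2(n))

    def variation_cost(self, n: int) -> int:
        return self.rep_cost(n) + self.atom_cost + self.variation_overhead


DEFAULT_COST_MODEL = CostModel()


def program_cost(node: Program, cm: CostModel = DEFAULT_COST_MODEL) -> int:
    """Description length of a program (not of the sequence it emits)."""
    if isinstance(node, Atom):
        return cm.atom_cost
    if isinstance(node, Concat):
        return sum(program_cost(p, cm) for p in node.parts)
    if isinstance(node, Repeat):
        return program_cost(node.block, cm) + cm.rep_cost(node.n)
    if isinstance(node, RepeatVar):
        return program_cost(node.block, cm) + cm.variation_cost(node.n)
    raise LanguageError(f"not a program node: {node!r}")


# ---------------------------------------------------------------------------
# Canonical text notation:  atoms by name, concatenation by spaces,
# "[x]^n" for repetition, "[x]^n<v>" for repetition with variation.
# ---------------------------------------------------------------------------


def to_text(node: Program) -> str:
    if isinstance(node, Atom):
        return node.move
    if isinstance(node, Concat):
        return " ".join(to_text(p) for p in node.parts)
    if isinstance(node, Repeat):
        return f"[{to_text(node.block)}]^{node.n}"
    if isinstance(node, RepeatVar):
        return f"[{to_text(node.block)}]^{node.n}<{node.var}>"
    raise LanguageError(f"not a program node: {node!r}")


_TOKEN = re.compile(r"\s*(\[|\]\^\d+(?:<[+\-]?\w+>)?|[+\-]?\w+)")


def _tokenize(text: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise LanguageError(f"cannot parse program text at: {text[pos:]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def from_text(text: str) -> Program:
    """Parse the canonical notation back into a program (inverse of
    :func:`to_text`)."""
    tokens = _tokenize(text)
    if not tokens:
        raise LanguageError("empty program text")
    pos = 0

    def parse_parts(depth: int) -> tuple[list[Program], int]:
        nonlocal pos
        parts: list[Program] = []
        while pos < len(tokens):
            tok = tokens[pos]
            if tok == "[":
                pos += 1
                inner, _ = parse_parts(depth + 1)
                if pos >= len(tokens) or not tokens[pos].startswith("]^"):
                    raise LanguageError("unclosed '[' in program text")
                closer = tokens[pos]
                pos += 1
                m = re.fullmatch(r"\]\^(\d+)(?:<([+\-]?\w+)>)?", closer)
                assert m is not None
                n = int(m.group(1))
                block = concat(*inner)
                if m.group(2) is not None:
                    parts.append(RepeatVar(block, n, m.group(2)))
                else:
                    parts.append(Repeat(block, n))
            elif tok.startswith("]^"):
                if depth == 0:
                    raise LanguageError("unmatched ']' in program text")
                return parts, pos
            else:
                parts.append(Atom(tok))
                pos += 1
        if depth != 0:
            raise LanguageError("unclosed '[' in program text")
        return parts, pos

    parts, _ = parse_parts(0)
    if not parts:
        raise LanguageError("empty program text")
    return concat(*parts)


# ---------------------------------------------------------------------------
# Random programs (used by property tests and sanity checks)
# ---------------------------------------------------------------------------


def random_program(
    rng,
    max_cost: int = 16,
    max_emissions: int = 8,
    moves: tuple[str, ...] = tuple(m for m in FULL_MOVES if m != "0"),
    variations: tuple[str, ...] = FULL_VARIATIONS,
    _depth: int = 0,
    _in_figure: bool = False,
) -> Program:
    """Draw a random syntactically valid program within a cost budget."""
    choices = ["atom"]
    if max_emissions >= 2 and max_cost >= 3 and _depth < 3:
        choices.append("repeat")
        choices.append("concat")
    if max_emissions >= 4 and max_cost >= 6 and _depth < 3 and variations:
        choices.append("repvar")
    kind = choices[rng.integers(len(choices))]
    if kind == "atom":
        return Atom(moves[rng.integers(len(moves))])
    if kind == "concat":
        k = int(rng.integers(2, 4))
        parts = []
        budget, room = max_cost, max_emissions
        for _ in range(k):
            if budget < 2 or room < 1:
                break
            p = random_program(rng, budget, room, moves, variations, _depth, _in_figure)
            if program_cost(p) > budget or emission_length(p, False) > room:
                p = Atom(moves[rng.integers(len(moves))])
            budget -= program_cost(p)
            room -= emission_length(p, False)
            parts.append(p)
        if not parts:
            return Atom(moves[rng.integers(len(moves))])
        return concat(*parts)
    if kind == "repeat":
        # the generator sticks to single-instruction blocks (closed
        # multi-step loops need anchor coordination); at execution level the
        # repetition must close its orbit, so n is drawn from the orbit
        move = moves[rng.integers(len(moves))]
        m = MOVES[move]
        if not _in_figure:
            period = 2 if m >= 8 else 8 // math.gcd(m, 8) if m else 1
            ns = [n for n in range(period, max_emissions + 1, period) if n >= 2]
            if not ns:
                return Atom(move)
            n = ns[rng.integers(len(ns))]
        else:
            n = int(rng.integers(2, max(3, max_emissions) + 1))
        return Repeat(Atom(move), n)
    n = 2 if max_emissions < 6 else int(rng.integers(2, 5))
    block = random_program(
        rng,
        max_cost - 6,
        max(1, max_emissions // n - 1),
        moves,
        variations,
        _depth + 1,
        True,
    )
    f = 1 + emission_length(block, False)
    while n * f > max_emissions + 1 and n > 2:
        n -= 1
    if n * f > max_emissions + 1:
        return block
    return RepeatVar(block, n, variations[rng.integers(len(variations))])
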