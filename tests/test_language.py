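"""Primitive actions, emission semantics, costs and the program notation."""

import pytest

from geomlang.language import (
    Atom,
    CostModel,
    LanguageError,
    Repeat,
    RepeatVar,
    apply_movement,
    concat,
    emission_length,
    emit,
    from_text,
    program_cost,
    random_program,
    to_text,
)

SYMMETRIES = ("H", "V", "A", "B", "P")
FULL_PRIMITIVES = ("0", "+1", "-1", "+2", "-2") + SYMMETRIES


class TestMovements:
    @pytest.mark.parametrize(
        "move,x,expected",
        [("+1", 0, 1), ("P", 6, 2), ("0", 3, 3), ("H", 0, 7), ("-2", 1, 7)],
    )
    def test_examples(self, move, x, expected):
        assert apply_movement(move, x) == expected

    def test_unknown_primitive_rejected(self):
        with pytest.raises(LanguageError):
            apply_movement("+5", 0)
        with pytest.raises(LanguageError):
            apply_movement("+1", 9)

    @pytest.mark.parametrize("sym", SYMMETRIES)
    def test_symmetries_are_involutions(self, sym):
        for x in range(8):
            assert apply_movement(sym, apply_movement(sym, x)) == x

    def test_every_transition_has_a_primitive(self):
        """Coverage: each of the 56 ordered vertex pairs is one instruction
        away under the edge-bisector axis convention."""
        for x in range(8):
            reached = {apply_movement(m, x) for m in FULL_PRIMITIVES if m != "0"}
            assert reached == set(range(8)) - {x} | reached  # no self-moves
            assert set(range(8)) - {x} <= reached


class TestEmission:
    @pytest.mark.parametrize(
        "program,anchor,expected",
        [
            (Repeat(Atom("+1"), 8), 7, [0, 1, 2, 3, 4, 5, 6, 7]),
            (
                RepeatVar(Repeat(Atom("+2"), 3), 2, "+1"),
                0,
                [0, 2, 4, 6, 1, 3, 5, 7],
            ),
            (RepeatVar(Atom("P"), 4, "+1"), 0, [0, 4, 1, 5, 2, 6, 3, 7]),
            (RepeatVar(Atom("P"), 4, "+3"), 0, [0, 4, 3, 7, 6, 2, 1, 5]),
            (
                RepeatVar(RepeatVar(Atom("H"), 2, "V"), 2, "+2"),
                0,
                [0, 7, 3, 4, 2, 1, 5, 6],
            ),
        ],
    )
    def test_examples(self, program, anchor, expected):
        assert emit(program, anchor) == expected

    def test_entry_shown_only_on_blank_screen(self):
        """Mid-sequence, a variation construct's first figure starts at the
        location already on display, so the entry is not re-shown."""
        p = concat(Atom("+1"), RepeatVar(Atom("P"), 2, "+1"))
        # from anchor 7: +1 shows 0; figure (0,4), second copy (1,5)
        assert emit(p, 7) == [0, 4, 1, 5]

    def test_open_multistep_repetition_rejected(self):
        with pytest.raises(LanguageError, match="return to its starting"):
            emit(Repeat(concat(Atom("+1"), Atom("+1")), 2), 0)

    def test_executed_repetition_must_close_its_tour(self):
        with pytest.raises(LanguageError, match="closed tour"):
            emit(Repeat(Atom("+2"), 3), 0)  # open arc at execution level
        # the same open stroke is fine inside a variation figure
        emit(RepeatVar(Repeat(Atom("+2"), 3), 2, "+1"), 0)

    def test_closed_loops_may_repeat(self):
        assert emit(Repeat(concat(Atom("-2"), Atom("+2")), 4), 2) == [0, 2] * 4

    def test_emission_length_examples(self):
        assert emission_length(Atom("H")) == 1
        two_atoms = concat(Atom("+1"), Atom("-1"))
        assert emission_length(Repeat(two_atoms, 4)) == 8
        assert emission_length(RepeatVar(Atom("H"), 4, "+1")) == 8
        assert emission_length(RepeatVar(Atom("H"), 4, "+1"), sequence_initial=False) == 7

    def test_emit_length_matches_structural_length(self, rng):
        checked = 0
        for _ in range(300):
            p = random_program(rng)
            for anchor in range(8):
                try:
                    out = emit(p, anchor)
                except LanguageError:
                    continue
                assert len(out) == emission_length(p)
                checked += 1
                break
        assert checked > 100


class TestCost:
    @pytest.mark.parametrize(
        "program,expected",
        [
            (Repeat(Atom("+1"), 8), 5),
            (concat(*[Atom("+1")] * 8), 16),
            (RepeatVar(Atom("H"), 4, "+1"), 7),
            (RepeatVar(RepeatVar(Atom("H"), 2, "V"), 2, "+2"), 10),
        ],
    )
    def test_examples(self, program, expected):
        assert program_cost(program) == expected

    def test_single_repetition_beats_writing_twice(self):
        cm = CostModel()
        assert cm.atom_cost + cm.rep_cost(2) < 2 * cm.atom_cost

    def test_cost_strictly_grows_with_concat_parts(self, rng):
        for _ in range(50):
            p = random_program(rng)
            q = concat(p, Atom("+1"))
            assert program_cost(q) > program_cost(p)

    def test_invalid_repetition_count(self):
        with pytest.raises(LanguageError):
            Repeat(Atom("+1"), 1)
        with pytest.raises(LanguageError):
            RepeatVar(Atom("+1"), 0, "+1")


class TestNotation:
    @pytest.mark.parametrize(
        "text",
        [
            "[+1]^8",
            "[[+2]^3]^2<+1>",
            "[[H]^2<V>]^2<+2>",
            "+1 -1 H V A B P 0",
            "[P]^4<+3> +1 [-2 +2]^4",
        ],
    )
    def test_round_trip_from_text(self, text):
        assert to_text(from_text(text)) == text

    def test_round_trip_random_programs(self, rng):
        for _ in range(300):
            p = random_program(rng)
            assert from_text(to_text(p)) == p

    def test_malformed_text_rejected(self):
        for bad in ("", "[+1", "]^2", "[+1]^x"):
            with pytest.raises(LanguageError):
                from_text(bad)
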