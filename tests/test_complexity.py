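"""The minimal-description search: calibration, controls, invariances."""

import pytest

from geomlang.complexity import (
    DEGRADED,
    INF,
    NO_NESTING,
    NO_P,
    complexity,
    degraded_complexity,
    minimal_description,
    normalized_jump_length,
    resource_flags,
)
from geomlang.language import (
    LanguageError,
    emit,
    program_cost,
    random_program,
)

from _oracle import oracle_min_cost

# the printed complexities of the named constructions
CALIBRATION = [
    ("repeat", (0, 1, 2, 3, 4, 5, 6, 7), 5),
    ("repeat-ccw", (0, 7, 6, 5, 4, 3, 2, 1), 5),
    ("alternate", (0, 7, 2, 1, 4, 3, 6, 5), 7),
    ("2squares", (0, 2, 4, 6, 1, 3, 5, 7), 8),
    ("2arcs", (0, 1, 2, 3, 7, 6, 5, 4), 8),
    ("4segments-V", (0, 3, 2, 5, 4, 7, 6, 1), 7),
    ("4diagonals", (0, 4, 1, 5, 2, 6, 3, 7), 7),
    ("2rectangles", (0, 7, 3, 4, 2, 1, 5, 6), 10),
    ("2crosses", (0, 4, 3, 7, 6, 2, 1, 5), 7),
    ("2points", (0, 2, 0, 2, 0, 2, 0, 2), 6),
    ("4points", (0, 7, 6, 5, 0, 7, 6, 5), 9),
]


class TestMinimalDescription:
    @pytest.mark.parametrize("name,seq,k", CALIBRATION, ids=[c[0] for c in CALIBRATION])
    def test_calibration(self, name, seq, k):
        rec = minimal_description(seq)
        assert rec.K == k

    def test_witnesses_emit_the_sequence_at_cost_K(self):
        for _, seq, k in CALIBRATION:
            rec = minimal_description(seq, max_witnesses=10)
            assert rec.witnesses
            for w in rec.witnesses:
                assert program_cost(w) == k
                emitted = []
                for a in range(8):
                    try:
                        emitted.append(emit(w, a))
                    except LanguageError:
                        continue  # this anchor does not close the tour
                assert list(seq) in emitted

    def test_incompressible_sequence_is_a_plain_list(self):
        rec = minimal_description((0, 2, 5, 1, 7, 4, 6, 3), max_witnesses=5)
        assert rec.K <= 16

    def test_sequence_validation(self):
        with pytest.raises(LanguageError):
            minimal_description((0, 1, 2, 3, 4, 5, 6, 7, 0))  # longer than 8
        with pytest.raises(LanguageError):
            minimal_description((0, 0, 1))  # consecutive duplicate
        with pytest.raises(LanguageError):
            minimal_description((3,))  # too short

    def test_cost_soundness_on_random_programs(self, rng):
        """K of an emitted sequence never exceeds the emitting program's
        cost (catches program shapes the search might miss)."""
        checked = 0
        for _ in range(400):
            p = random_program(rng)
            try:
                out = emit(p, int(rng.integers(8)))
            except LanguageError:
                continue
            if not (2 <= len(out) <= 8):
                continue
            if any(a == b for a, b in zip(out, out[1:])):
                continue
            assert minimal_description(out, max_witnesses=0).K <= program_cost(p)
            checked += 1
        assert checked > 150

    def test_matches_bruteforce_oracle_on_random_sequences(self, rng):
        for _ in range(12):
            perm = tuple(int(x) for x in rng.permutation(8))
            assert minimal_description(perm, max_witnesses=0).K == oracle_min_cost(perm)

    def test_dihedral_invariance(self, rng):
        """K is unchanged by rotating or reflecting the whole display."""
        for _ in range(10):
            perm = tuple(int(x) for x in rng.permutation(8))
            k = complexity(perm)
            r = int(rng.integers(1, 8))
            assert complexity(tuple((x + r) % 8 for x in perm)) == k
            c = 1 + 2 * int(rng.integers(4))
            assert complexity(tuple((c - x) % 8 for x in perm)) == k


class TestRestrictedLanguages:
    def test_degraded_control_values(self):
        assert degraded_complexity((0, 1, 2, 3, 4, 5, 6, 7)) == 5
        assert degraded_complexity((0, 7, 2, 1, 4, 3, 6, 5)) == 16  # 4segments
        assert degraded_complexity((0, 3, 2, 5, 4, 7, 6, 1)) == 16

    def test_degraded_matches_bruteforce(self, rng):
        seq = (0, 2, 4, 6, 1, 3, 5, 7)  # 2squares
        assert degraded_complexity(seq) == oracle_min_cost(seq, DEGRADED)
        for _ in range(5):
            perm = tuple(int(x) for x in rng.permutation(8))
            assert complexity(perm, DEGRADED) == oracle_min_cost(perm, DEGRADED)

    def test_half_turn_transitions_need_P(self):
        assert complexity((0, 4, 1, 5, 2, 6, 3, 7), NO_P) is None

    def test_resource_flags_examples(self):
        assert resource_flags((0, 1, 2, 3, 4, 5, 6, 7)) == (False, False)
        assert resource_flags((0, 4, 1, 5, 2, 6, 3, 7)) == (True, False)
        assert resource_flags((0, 2, 4, 6, 1, 3, 5, 7)) == (False, True)

    def test_restricted_searches_match_bruteforce(self, rng):
        for lang in (NO_P, NO_NESTING):
            for _ in range(4):
                perm = tuple(int(x) for x in rng.permutation(8))
                k = complexity(perm, lang)
                o = oracle_min_cost(perm, lang)
                assert (k is None and o >= INF) or k == o


class TestControls:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ((0, 1, 2, 3, 4, 5, 6, 7), 1.0),
            ((0, 4, 1, 5, 2, 6, 3, 7), 25 / 7),
            ((0, 2, 0, 2, 0, 2, 0, 2), 2.0),
        ],
    )
    def test_normalized_jump_length(self, seq, expected):
        assert normalized_jump_length(seq) == pytest.approx(expected)

    def test_jump_length_needs_two_points(self):
        with pytest.raises(LanguageError):
            normalized_jump_length((3,))
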