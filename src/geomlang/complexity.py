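"""Minimal description length of octagon sequences.

The complexity ``K`` of a displayed sequence is the cost of the shortest
program in the geometric language that emits it from some (free, undisplayed)
anchor.  The search is exact: it is organized as an interval dynamic program
over the sequence, where every sub-program is summarized by its *affine
signature* -- the tuple of maps ``x -> +-x + a (mod 8)`` sending the entry
position to each emitted position.  Because every primitive and every
variation transform is such an affine map, a program's emissions are affine
in its entry, and for a concrete target subsequence at most two signatures
per position are feasible.  The signature is what makes plain repetition
decidable locally: a block re-executed from a new entry must reproduce the
next stretch of the sequence through the *same* maps.

Sub-results are memoized by ``(entry, targets)`` (not by interval indices),
so enumerating all 5040 permutation sequences shares almost all of the work
across sequences.

Restricted languages (no point symmetry P; no nested repetitions; the
degraded rotations-only control) run through the same search with a
different :class:`LanguageConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Optional

from .language import (
    APPLY,
    COMPOSE,
    DEFAULT_COST_MODEL,
    FULL_MOVES,
    FULL_VARIATIONS,
    IDENTITY,
    MOVES,
    VARIATIONS,
    Atom,
    CostModel,
    LanguageError,
    Program,
    Repeat,
    RepeatVar,
    affine_pow,
    concat,
    emit,
    to_text,
)

INF = 10**9

#: Longest block interval for which full signature dictionaries are kept.
#: Plain-repetition blocks never exceed half of an 8-item sequence.
_SIG_CAP = 4


@dataclass(frozen=True)
class LanguageConfig:
    """The instruction set available to the search."""

    name: str
    atoms: tuple[str, ...]
    variations: tuple[str, ...]
    allow_nesting: bool = True


FULL_LANGUAGE = LanguageConfig(
    "full", tuple(m for m in FULL_MOVES if m != "0"), FULL_VARIATIONS
)

#: Language without the point symmetry: neither the primitive P nor the
#: global +4 transform.  Sequences containing a +-4 transition become
#: inexpressible (no single primitive realizes a half-turn displacement).
NO_P = LanguageConfig(
    "no_p",
    tuple(m for m in FULL_MOVES if m not in ("0", "P")),
    tuple(v for v in FULL_VARIATIONS if v != "+4"),
)

#: Language restricted to a single level of repetition: repetition blocks
#: may contain only primitive instructions.
NO_NESTING = LanguageConfig(
    "no_nesting", FULL_LANGUAGE.atoms, FULL_LANGUAGE.variations, allow_nesting=False
)

#: Degraded control language: rotations only (including the +-3 and +4 steps
#: that the full language lacks as primitives) and plain repetition; no
#: symmetries, no repetition-with-variation.
DEGRADED = LanguageConfig("degraded", ("+1", "-1", "+2", "-2", "+3", "-3", "+4"), ())


@dataclass
class SequenceRecord:
    """A sequence with its complexity and (optionally) witnesses and flags."""

    locations: tuple[int, ...]
    K: int
    witnesses: list[Program] = field(default_factory=list)
    uses_P: Optional[bool] = None
    uses_nesting: Optional[bool] = None
    K_no_p: Optional[int] = None
    K_no_nesting: Optional[int] = None

    def witness_texts(self) -> list[str]:
        return [to_text(w) for w in self.witnesses]


def validate_sequence(seq: Iterable[int]) -> tuple[int, ...]:
    s = tuple(int(x) for x in seq)
    if len(s) > 8:
        raise LanguageError(f"sequences longer than 8 are unsupported (got {len(s)})")
    if len(s) < 2:
        raise LanguageError(f"need at least 2 emissions (got {len(s)})")
    if any(not 0 <= x < 8 for x in s):
        raise LanguageError(f"vertex labels must be 0-7: {s}")
    for a, b in zip(s, s[1:]):
        if a == b:
            raise LanguageError(f"consecutive duplicate location in {s}")
    return s


# ---------------------------------------------------------------------------
# The search engine
# ---------------------------------------------------------------------------

# Signature-table variant keys: (leads_var, bare_repeat, flat)
#   leads_var   -- program's first instruction is a repetition-with-variation
#                  (its emission stream grows by one entry on a blank screen)
#   bare_repeat -- program is exactly one plain-Repeat item (such a program
#                  may not itself be the block of a plain Repeat)
#   flat        -- program contains no repetition construct at all (the only
#                  admissible block shape when nesting is disallowed)


def _feasible_maps(p: int, y: int) -> tuple[int, int]:
    """The two affine maps sending vertex p to vertex y."""
    return ((y - p) % 8, 8 + (y + p) % 8)


class ComplexitySearcher:
    """Exact minimal-description search for one language configuration.

    Instances cache sub-interval solutions keyed by concrete
    ``(entry, targets)`` content, so repeated queries (and the full atlas
    enumeration) are fast.  ``witness_cap`` bounds how many equal-cost
    minimal programs are retained per record (0 disables witness tracking).
    """

    def __init__(
        self,
        language: LanguageConfig = FULL_LANGUAGE,
        cost_model: CostModel = DEFAULT_COST_MODEL,
        witness_cap: int = 3,
    ):
        self.language = language
        self.cm = cost_model
        self.cap = witness_cap
        self._atoms_by_map: dict[int, list[str]] = {}
        for name in language.atoms:
            self._atoms_by_map.setdefault(MOVES[name], []).append(name)
        self._vars: list[tuple[int, str]] = []
        seen = set()
        for v in language.variations:
            m = VARIATIONS[v]
            if m not in seen:
                seen.add(m)
                self._vars.append((m, v))
        self._sig: dict = {}
        self._best: dict = {}

    # -- witness bookkeeping -------------------------------------------------

    def _merge(self, slot: list, cost: int, wits: Optional[list]) -> None:
        """slot = [cost, wits]; keep the minimum, pooling equal-cost wits."""
        if cost > slot[0]:
            return
        if cost < slot[0]:
            slot[0] = cost
            slot[1] = list(wits or [])[: self.cap]
            return
        if self.cap and wits:
            have = {to_text(w) for w in slot[1]}
            for w in wits:
                if len(slot[1]) >= self.cap:
                    break
                t = to_text(w)
                if t not in have:
                    have.add(t)
                    slot[1].append(w)

    def _pair_wits(self, lw: Optional[list], rw: Optional[list]) -> Optional[list]:
        if not self.cap:
            return None
        out = []
        for a in lw or []:
            for b in rw or []:
                out.append(concat(a, b))
                if len(out) >= self.cap:
                    return out
        return out

    # -- signature tables ----------------------------------------------------

    def sig_table(self, p: int, T: tuple[int, ...], figure: bool = False) -> dict:
        """All programs emitting the concrete targets ``T`` from entry ``p``
        (non-initial semantics), grouped by affine signature.

        ``figure`` is True inside the block of a repetition-with-variation,
        where a single-instruction repetition may trace an open stroke;
        outside, every repetition must close its tour.

        Returns ``{signature: {(leads_var, bare_repeat, flat): [cost, wits]}}``.
        """
        key = (p, T, figure)
        hit = self._sig.get(key)
        if hit is not None:
            return hit
        L = len(T)
        d: dict = {}

        def add(sig, variant, cost, wits):
            slot = d.setdefault(sig, {}).setdefault(variant, [INF, []])
            self._merge(slot, cost, wits)

        if L == 1:
            for m in _feasible_maps(p, T[0]):
                names = self._atoms_by_map.get(m)
                if names:
                    add(
                        (m,),
                        (False, False, True),
                        self.cm.atom_cost,
                        [Atom(nm) for nm in names] if self.cap else None,
                    )
        else:
            self._add_repeat_items(p, T, add, sig_mode=True, figure=figure)
            self._add_repvar_items_sig(p, T, add)
            for k in range(1, L):
                left = self.sig_table(p, T[:k], figure)
                right = self.sig_table(T[k - 1], T[k:], figure)
                for lsig, lvars in left.items():
                    mu = lsig[-1]
                    for rsig, rvars in right.items():
                        csig = lsig + tuple(COMPOSE[r][mu] for r in rsig)
                        for (llv, _lsr, lfl), (lc, lw) in lvars.items():
                            for (_rlv, _rsr, rfl), (rc, rw) in rvars.items():
                                add(
                                    csig,
                                    (llv, False, lfl and rfl),
                                    lc + rc,
                                    self._pair_wits(lw, rw),
                                )
        self._sig[key] = d
        return d

    def _add_repeat_items(self, p, T, add, sig_mode, figure):
        L = len(T)
        for n in range(2, L + 1):
            if L % n:
                continue
            b = L // n
            if b > _SIG_CAP:
                continue
            if b > 1 and T[b - 1] != p:
                continue  # multi-step blocks may only repeat closed figures
            rep = self.cm.rep_cost(n)
            for sig, variants in self.sig_table(p, T[:b], figure).items():
                if not self._check_repeat(sig, T, b, n):
                    continue
                if b == 1 and not figure and affine_pow(sig[0], n) != IDENTITY:
                    continue  # executed repetitions close their tour
                fullsig = None
                if sig_mode:
                    fullsig = list(sig)
                    mu = sig[b - 1]
                    mu_c = IDENTITY
                    for _ in range(1, n):
                        mu_c = COMPOSE[mu][mu_c]
                        fullsig.extend(COMPOSE[s][mu_c] for s in sig)
                    fullsig = tuple(fullsig)
                for (lv, sr, fl), (c, w) in variants.items():
                    if sr:
                        continue  # canonical: no Repeat directly inside Repeat
                    if not self.language.allow_nesting and not fl:
                        continue
                    wits = [Repeat(a, n) for a in w] if self.cap and w else None
                    add(
                        fullsig if sig_mode else None,
                        (lv, True, False),
                        c + rep,
                        wits,
                    )

    def _check_repeat(self, sig, T, b, n) -> bool:
        for c in range(1, n):
            e = T[c * b - 1]
            base = c * b
            for t in range(b):
                if APPLY[sig[t]][e] != T[base + t]:
                    return False
        return True

    def _check_repvar(self, F, T, f, n, vmap) -> bool:
        vp = IDENTITY
        for c in range(1, n):
            vp = COMPOSE[vmap][vp]
            base = c * f - 1
            for t in range(f):
                if APPLY[vp][F[t]] != T[base + t]:
                    return False
        return True

    def _repvar_shapes(self, L: int):
        for f in range(2, L + 2):
            n, r = divmod(L + 1, f)
            if r == 0 and n >= 2:
                yield f, n

    def _add_repvar_items_sig(self, p, T, add):
        """Repetition-with-variation items, with full signatures (short
        intervals only)."""
        L = len(T)
        for f, n in self._repvar_shapes(L):
            F = (p,) + T[: f - 1]
            cost_extra = self.cm.variation_cost(n)
            for vmap, vname in self._vars:
                if not self._check_repvar(F, T, f, n, vmap):
                    continue
                for bsig, bvars in self.sig_table(p, T[: f - 1], True).items():
                    figmaps = (IDENTITY,) + bsig
                    itemsig = list(bsig)
                    vp = IDENTITY
                    for _ in range(1, n):
                        vp = COMPOSE[vmap][vp]
                        itemsig.extend(COMPOSE[vp][g] for g in figmaps)
                    itemsig = tuple(itemsig)
                    for (_lv, _sr, fl), (c, w) in bvars.items():
                        if not self.language.allow_nesting and not fl:
                            continue
                        wits = (
                            [RepeatVar(a, n, vname) for a in w]
                            if self.cap and w
                            else None
                        )
                        add(itemsig, (True, False, False), c + cost_extra, wits)

    # -- aggregated best cost ------------------------------------------------

    def best(self, p: int, T: tuple[int, ...], figure: bool = False) -> list:
        """``[cost, wits, flat_cost, flat_wits]`` for emitting ``T`` from
        entry ``p`` (non-initial semantics), minimized over all programs."""
        key = (p, T, figure)
        hit = self._best.get(key)
        if hit is not None:
            return hit
        L = len(T)
        any_slot = [INF, []]
        flat_slot = [INF, []]
        if L <= _SIG_CAP:
            for variants in self.sig_table(p, T, figure).values():
                for (_lv, _sr, fl), (c, w) in variants.items():
                    self._merge(any_slot, c, w)
                    if fl:
                        self._merge(flat_slot, c, w)
        else:
            def add(_sig, variant, cost, wits):
                self._merge(any_slot, cost, wits)
                if variant[2]:
                    self._merge(flat_slot, cost, wits)

            self._add_repeat_items(p, T, add, sig_mode=False, figure=figure)
            for f, n in self._repvar_shapes(L):
                F = (p,) + T[: f - 1]
                cost_extra = self.cm.variation_cost(n)
                for vmap, vname in self._vars:
                    if not self._check_repvar(F, T, f, n, vmap):
                        continue
                    sub = self.best(p, T[: f - 1], True)
                    c, w = (
                        (sub[2], sub[3])
                        if not self.language.allow_nesting
                        else (sub[0], sub[1])
                    )
                    if c >= INF:
                        continue
                    wits = (
                        [RepeatVar(a, n, vname) for a in w] if self.cap and w else None
                    )
                    self._merge(any_slot, c + cost_extra, wits)
            for k in range(1, L):
                lft = self.best(p, T[:k], figure)
                rgt = self.best(T[k - 1], T[k:], figure)
                if lft[0] + rgt[0] < INF:
                    self._merge(
                        any_slot, lft[0] + rgt[0], self._pair_wits(lft[1], rgt[1])
                    )
                if lft[2] + rgt[2] < INF:
                    self._merge(
                        flat_slot, lft[2] + rgt[2], self._pair_wits(lft[3], rgt[3])
                    )
        out = [any_slot[0], any_slot[1], flat_slot[0], flat_slot[1]]
        self._best[key] = out
        return out

    # -- whole-sequence search ----------------------------------------------

    def search(self, seq) -> SequenceRecord:
        """Minimal description of a displayed sequence (anchor free)."""
        s = validate_sequence(seq)
        L = len(s)
        slot = [INF, []]

        def tail(e: int) -> list:
            if e == L:
                return [0, [None], 0, [None]]
            return self.best(s[e - 1], s[e:])

        # first instruction is a plain primitive
        rest = self.best(s[0], s[1:]) if L > 1 else [0, [None], 0, [None]]
        if rest[0] < INF:
            lead = [Atom(nm) for nm in self.language.atoms] if self.cap else None
            wits = None
            if self.cap and lead:
                wits = [
                    concat(a, w) if w is not None else a
                    for a in lead
                    for w in (rest[1] or [None])
                ]
            self._merge(slot, self.cm.atom_cost + rest[0], wits)

        # sequence-initial repetition-with-variation covering s[0:e]
        for f in range(2, L + 1):
            for n in range(2, L // f + 1):
                e = n * f
                F = s[:f]
                for vmap, vname in self._vars:
                    ok = True
                    vp = IDENTITY
                    for c in range(1, n):
                        vp = COMPOSE[vmap][vp]
                        base = c * f
                        for t in range(f):
                            if APPLY[vp][F[t]] != s[base + t]:
                                ok = False
                                break
                        if not ok:
                            break
                    if not ok:
                        continue
                    blk = self.best(s[0], s[1:f], True)
                    bc, bw = (
                        (blk[2], blk[3])
                        if not self.language.allow_nesting
                        else (blk[0], blk[1])
                    )
                    rst = tail(e)
                    if bc >= INF or rst[0] >= INF:
                        continue
                    cost = bc + self.cm.variation_cost(n) + rst[0]
                    wits = None
                    if self.cap:
                        item_w = [RepeatVar(a, n, vname) for a in bw or []]
                        wits = [
                            concat(iw, rw) if rw is not None else iw
                            for iw in item_w
                            for rw in (rst[1] or [None])
                        ]
                    self._merge(slot, cost, wits)

        # sequence-initial plain repetition, uniform copies (block does not
        # lead with a variation construct); the anchor is free
        for b in range(1, min(_SIG_CAP, L // 2) + 1):
            for n in range(2, L // b + 1):
                e = n * b
                rep = self.cm.rep_cost(n)
                rst = tail(e)
                if rst[0] >= INF:
                    continue
                # a multi-step block must close, pinning the anchor to the
                # block's last emission; a single instruction iterates freely
                anchors = range(8) if b == 1 else (s[b - 1],)
                for x0 in anchors:
                    for sig, variants in self.sig_table(x0, s[:b]).items():
                        if not self._check_repeat(sig, s[:e], b, n):
                            continue
                        if b == 1 and affine_pow(sig[0], n) != IDENTITY:
                            continue  # executed repetitions close their tour
                        for (lv, sr, fl), (c, w) in variants.items():
                            if lv or sr:
                                continue
                            if not self.language.allow_nesting and not fl:
                                continue
                            cost = c + rep + rst[0]
                            wits = None
                            if self.cap and w:
                                wits = [
                                    concat(Repeat(a, n), rw)
                                    if rw is not None
                                    else Repeat(a, n)
                                    for a in w
                                    for rw in (rst[1] or [None])
                                ]
                            self._merge(slot, cost, wits)

        # sequence-initial plain repetition whose block leads with a
        # variation construct: the first copy additionally shows its entry,
        # which must be s[0] (= the free anchor)
        for b in range(1, _SIG_CAP):
            if b < L and s[b] != s[0]:
                continue  # the leading-variation block must also close
            for n in range(2, (L - 1) // b + 1):
                e = n * b + 1
                if e > L:
                    continue
                rep = self.cm.rep_cost(n)
                rst = tail(e)
                if rst[0] >= INF:
                    continue
                for sig, variants in self.sig_table(s[0], s[1 : 1 + b]).items():
                    ok = True
                    for c in range(1, n):
                        ent = s[c * b]
                        base = c * b + 1
                        for t in range(b):
                            if APPLY[sig[t]][ent] != s[base + t]:
                                ok = False
                                break
                        if not ok:
                            break
                    if not ok:
                        continue
                    for (lv, sr, fl), (c, w) in variants.items():
                        if not lv or sr:
                            continue
                        if not self.language.allow_nesting and not fl:
                            continue
                        cost = c + rep + rst[0]
                        wits = None
                        if self.cap and w:
                            wits = [
                                concat(Repeat(a, n), rw)
                                if rw is not None
                                else Repeat(a, n)
                                for a in w
                                for rw in (rst[1] or [None])
                            ]
                        self._merge(slot, cost, wits)

        wits = sorted({to_text(w): w for w in slot[1] if w is not None}.values(),
                      key=to_text)[: self.cap]
        return SequenceRecord(locations=s, K=slot[0], witnesses=wits)


# ---------------------------------------------------------------------------
# Module-level searchers and the public operations
# ---------------------------------------------------------------------------

_searchers: dict = {}


def get_searcher(
    language: LanguageConfig = FULL_LANGUAGE,
    cost_model: CostModel = DEFAULT_COST_MODEL,
    witness_cap: int = 3,
) -> ComplexitySearcher:
    key = (language, cost_model, witness_cap)
    if key not in _searchers:
        _searchers[key] = ComplexitySearcher(language, cost_model, witness_cap)
    return _searchers[key]


def minimal_description(
    seq,
    language: LanguageConfig = FULL_LANGUAGE,
    cost_model: CostModel = DEFAULT_COST_MODEL,
    max_witnesses: int = 50,
) -> SequenceRecord:
    """Complexity ``K`` of a sequence with its minimal programs.

    >>> minimal_description((0, 1, 2, 3, 4, 5, 6, 7)).K
    5
    """
    return get_searcher(language, cost_model, max_witnesses).search(seq)


def complexity(
    seq,
    language: LanguageConfig = FULL_LANGUAGE,
    cost_model: CostModel = DEFAULT_COST_MODEL,
) -> Optional[int]:
    """K alone (no witnesses); ``None`` when the sequence is inexpressible
    in the given language (possible only for restricted languages)."""
    k = get_searcher(language, cost_model, 0).search(seq).K
    return None if k >= INF else k


def degraded_complexity(seq, cost_model: CostModel = DEFAULT_COST_MODEL) -> int:
    """Complexity in the rotations-only control language (S-figure control):
    primitives +-1, +-2, +-3, +4 and plain repetition; no symmetries, no
    repetition-with-variation."""
    k = complexity(seq, DEGRADED, cost_model)
    assert k is not None  # every transition is a rotation
    return k


def normalized_jump_length(seq) -> float:
    """Mean circular distance between successive locations (the geometry-free
    control predictor)."""
    s = tuple(int(x) for x in seq)
    if len(s) < 2:
        raise LanguageError("need at least 2 emissions")
    total = 0
    for a, b in zip(s, s[1:]):
        d = (b - a) % 8
        total += min(d, 8 - d)
    return total / (len(s) - 1)


def resource_flags(
    seq_or_record,
    cost_model: CostModel = DEFAULT_COST_MODEL,
    k_max: int = 12,
) -> tuple[bool, bool]:
    """Whether reaching the sequence's minimal complexity requires the point
    symmetry P, and whether it requires nested repetitions.

    A flag is set when the restricted-language complexity exceeds the full
    complexity (in particular when the sequence is inexpressible at all
    without the resource, which happens without P for any sequence
    containing a half-turn transition).
    """
    if isinstance(seq_or_record, SequenceRecord):
        rec = seq_or_record
        seq = rec.locations
    else:
        rec = None
        seq = validate_sequence(seq_or_record)
    k = complexity(seq, cost_model=cost_model)
    k_no_p = complexity(seq, NO_P, cost_model)
    k_no_nest = complexity(seq, NO_NESTING, cost_model)
    uses_p = k_no_p is None or k_no_p > k
    uses_nest = k_no_nest is None or k_no_nest > k
    if rec is not None:
        rec.uses_P = uses_p
        rec.uses_nesting = uses_nest
        rec.K_no_p = k_no_p
        rec.K_no_nesting = k_no_nest
    return uses_p, uses_nest


def all_octagon_sequences(origin: int = 0):
    """All 5040 length-8 no-revisit sequences from a fixed origin, in
    lexicographic order."""
    rest = [v for v in range(8) if v != origin]
    for perm in permutations(rest):
        yield (origin,) + perm
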