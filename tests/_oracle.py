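"""Independent brute-force oracle for the minimal-description search.

The production search is an interval dynamic program over affine
signatures.  This oracle shares nothing with it except the language's
execution semantics: it structurally enumerates candidate items (all block
shapes up to half a sequence, with repetition counts up to the remaining
length), *executes* every candidate with the emitter, and backtracks over
item decompositions keeping the cheapest program whose emissions match the
target.  Anything the emitter rejects (open repetitions and the like) is
skipped, so the oracle's notion of validity is exactly the emitter's.
"""

from __future__ import annotations

from functools import lru_cache

import geomlang.language as gl
from geomlang.complexity import FULL_LANGUAGE, INF, LanguageConfig
from geomlang.language import (
    DEFAULT_COST_MODEL,
    Atom,
    Concat,
    Repeat,
    RepeatVar,
    program_cost,
)


def _depth(ast) -> int:
    if isinstance(ast, Atom):
        return 0
    if isinstance(ast, Concat):
        return max(_depth(p) for p in ast.parts)
    return 1 + _depth(ast.block)


@lru_cache(maxsize=None)
def _blocks(emlen: int, lang: LanguageConfig) -> tuple:
    """Every program shape with the given nominal (non-initial) emission
    length over the language's instruction set."""
    out: list = []
    if emlen == 1:
        out.extend(Atom(m) for m in lang.atoms)
        return tuple(out)
    for n in range(2, emlen + 1):
        if emlen % n == 0:
            for blk in _blocks(emlen // n, lang):
                if isinstance(blk, (Repeat, Concat)) and isinstance(blk, Repeat):
                    continue
                if not lang.allow_nesting and _depth(blk) > 0:
                    continue
                out.append(Repeat(blk, n))
    for f in range(2, emlen + 2):
        n, r = divmod(emlen + 1, f)
        if r or n < 2:
            continue
        for blk in _blocks(f - 1, lang):
            if not lang.allow_nesting and _depth(blk) > 0:
                continue
            for v in lang.variations:
                out.append(RepeatVar(blk, n, v))
    for head_len in range(1, emlen):
        for head in _blocks(head_len, lang):
            if isinstance(head, Concat):
                continue
            for tail in _blocks(emlen - head_len, lang):
                tail_parts = tail.parts if isinstance(tail, Concat) else (tail,)
                out.append(Concat((head,) + tail_parts))
    seen: set = set()
    uniq = []
    for p in out:
        t = gl.to_text(p)
        if t not in seen:
            seen.add(t)
            uniq.append(p)
    return tuple(uniq)


def _try_emit(item, pos: int, nonempty: bool):
    try:
        return gl._emit(item, pos, nonempty, False)[0]
    except gl.LanguageError:
        return None


@lru_cache(maxsize=None)
def _first_emission(ast) -> tuple[int, bool]:
    """(affine map of the first emitted location, leads-with-variation).
    A leads-with-variation item on a blank screen emits its entry (the
    current position) first instead."""
    if isinstance(ast, Atom):
        return gl.MOVES[ast.move], False
    if isinstance(ast, Concat):
        return _first_emission(ast.parts[0])
    if isinstance(ast, Repeat):
        return _first_emission(ast.block)
    return _first_emission(ast.block)[0], True


def oracle_min_cost(
    seq,
    lang: LanguageConfig = FULL_LANGUAGE,
    cost_model=DEFAULT_COST_MODEL,
) -> int:
    """Minimum program cost emitting ``seq`` from any anchor (INF when the
    language cannot express the sequence at all)."""
    s = tuple(int(x) for x in seq)
    L = len(s)
    bound = 2 * L + 1  # a plain list costs 2L whenever it exists
    best = [bound]

    max_block = max(1, L // 2)

    def items_for(remaining: int) -> tuple:
        """(item, cost, first-map, leads-var) tuples, grouped by the map of
        the item's first emission for cheap position filtering."""
        out = []
        items_by_len = {b: _blocks(b, lang) for b in range(1, max_block + 1)}
        for a in items_by_len[1]:
            out.append(a)
        for b in range(1, min(max_block, remaining) + 1):
            for blk in items_by_len[b]:
                if not lang.allow_nesting and _depth(blk) > 0:
                    continue
                if not isinstance(blk, Repeat):
                    for n in range(2, remaining // b + 1):
                        out.append(Repeat(blk, n))
                for n in range(2, (remaining + 1) // (b + 1) + 1):
                    for v in lang.variations:
                        out.append(RepeatVar(blk, n, v))
        return tuple(
            (item, program_cost(item, cost_model), *_first_emission(item))
            for item in out
        )

    items_cache = {r: items_for(r) for r in range(1, L + 1)}

    def dfs(i: int, pos: int, cost: int):
        if cost >= best[0]:
            return
        if i == L:
            best[0] = cost
            return
        remaining = L - i
        target = s[i]
        initial = i == 0
        for item, ic, fm, leads in items_cache[remaining]:
            c = cost + ic
            if c >= best[0]:
                continue
            first = pos if (leads and initial) else gl.APPLY[fm][pos]
            if first != target:
                continue
            out = _try_emit(item, pos, nonempty=i > 0)
            if out is None or len(out) > remaining:
                continue
            if tuple(out) != s[i : i + len(out)]:
                continue
            dfs(i + len(out), out[-1], c)

    for anchor in range(8):
        dfs(0, anchor, 0)
    return best[0] if best[0] < bound else INF
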