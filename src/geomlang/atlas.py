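"""The complexity atlas: every octagon sequence with its description length.

All 5040 sequences of 8 distinct vertices from a fixed origin, each scored
with its complexity K in the full language, its complexity in the
resource-restricted languages (no point symmetry; single-level repetition),
and the derived resource flags.  The atlas is the hypothesis space of the
sequence predictor: a prefix of an unfolding sequence is matched against
atlas rows, and the predictor bets on the least complex completion.

Rows are stored in lexicographic order, so prefix matching is a pair of
binary searches over base-8 codes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .complexity import (
    FULL_LANGUAGE,
    INF,
    NO_NESTING,
    NO_P,
    SequenceRecord,
    all_octagon_sequences,
    get_searcher,
    validate_sequence,
)
from .language import CostModel, DEFAULT_COST_MODEL, LanguageError, from_text

SCHEMA = "geomlang-atlas/1"

#: Sentinel for "inexpressible in this language" in integer columns.
UNREACHABLE = -1


def _codes(seqs: np.ndarray) -> np.ndarray:
    """Base-8 integer code of each row (lexicographic order preserving)."""
    w = 8 ** np.arange(7, -1, -1, dtype=np.int64)
    return seqs.astype(np.int64) @ w


@dataclass
class ComplexityAtlas:
    """Table of all no-revisit length-8 sequences from one origin."""

    seqs: np.ndarray  # (N, 8) int8, lexicographically sorted
    K: np.ndarray  # (N,) int16
    K_no_p: np.ndarray  # (N,) int16, UNREACHABLE when inexpressible
    K_no_nesting: np.ndarray  # (N,) int16
    uses_P: np.ndarray  # (N,) bool
    uses_nesting: np.ndarray  # (N,) bool
    witnesses: list[list[str]]  # canonical text, up to witness_cap per row
    metadata: dict = field(default_factory=dict)
    _code_cache: Optional[np.ndarray] = field(default=None, repr=False)

    # -- construction --------------------------------------------------------

    @classmethod
    def build(
        cls,
        origin: int = 0,
        cost_model: CostModel = DEFAULT_COST_MODEL,
        witness_cap: int = 3,
    ) -> "ComplexityAtlas":
        """Enumerate and score all 5040 sequences (a few seconds)."""
        full = get_searcher(FULL_LANGUAGE, cost_model, witness_cap)
        no_p = get_searcher(NO_P, cost_model, 0)
        no_nest = get_searcher(NO_NESTING, cost_model, 0)
        rows, ks, kps, kns, wits = [], [], [], [], []
        for seq in all_octagon_sequences(origin):
            rec = full.search(seq)
            rows.append(seq)
            ks.append(rec.K)
            kp = no_p.search(seq).K
            kn = no_nest.search(seq).K
            kps.append(UNREACHABLE if kp >= INF else kp)
            kns.append(UNREACHABLE if kn >= INF else kn)
            wits.append(rec.witness_texts())
        seqs = np.array(rows, dtype=np.int8)
        K = np.array(ks, dtype=np.int16)
        K_no_p = np.array(kps, dtype=np.int16)
        K_no_nesting = np.array(kns, dtype=np.int16)
        uses_p = (K_no_p == UNREACHABLE) | (K_no_p > K)
        uses_nest = (K_no_nesting == UNREACHABLE) | (K_no_nesting > K)
        meta = {
            "schema": SCHEMA,
            "origin": origin,
            "n": len(rows),
            "cost_model": {
                "atom_cost": cost_model.atom_cost,
                "rep_cost": "ceil(log2 n)",
                "variation_overhead": cost_model.variation_overhead,
            },
            "axes": {"H": 7, "V": 3, "A": 1, "B": 5},
            "max_K": int(K.max()),
            "count_at_max": int((K == K.max()).sum()),
        }
        return cls(seqs, K, K_no_p, K_no_nesting, uses_p, uses_nest, wits, meta)

    # -- lookups -------------------------------------------------------------

    @property
    def codes(self) -> np.ndarray:
        if self._code_cache is None:
            self._code_cache = _codes(self.seqs)
        return self._code_cache

    def __len__(self) -> int:
        return len(self.K)

    def prefix_range(self, prefix: Iterable[int]) -> tuple[int, int]:
        """Half-open row range of sequences starting with ``prefix`` (which
        must itself start at the atlas origin)."""
        p = tuple(int(x) for x in prefix)[:8]
        lo_code = sum(v * 8 ** (7 - i) for i, v in enumerate(p))
        hi_code = lo_code + 8 ** (8 - len(p))
        lo = int(np.searchsorted(self.codes, lo_code, side="left"))
        hi = int(np.searchsorted(self.codes, hi_code, side="left"))
        return lo, hi

    def lookup(self, seq) -> SequenceRecord:
        s = validate_sequence(seq)
        lo, hi = self.prefix_range(s)
        if len(s) != 8 or hi != lo + 1:
            raise LanguageError(f"sequence not in atlas: {s}")
        return self.record(lo)

    def record(self, i: int) -> SequenceRecord:
        return SequenceRecord(
            locations=tuple(int(x) for x in self.seqs[i]),
            K=int(self.K[i]),
            witnesses=[from_text(t) for t in self.witnesses[i]],
            uses_P=bool(self.uses_P[i]),
            uses_nesting=bool(self.uses_nesting[i]),
            K_no_p=None if self.K_no_p[i] == UNREACHABLE else int(self.K_no_p[i]),
            K_no_nesting=None
            if self.K_no_nesting[i] == UNREACHABLE
            else int(self.K_no_nesting[i]),
        )

    def stats(self) -> dict:
        ks, counts = np.unique(self.K, return_counts=True)
        return {
            "n": len(self),
            "min_K": int(self.K.min()),
            "max_K": int(self.K.max()),
            "count_at_max": int((self.K == self.K.max()).sum()),
            "histogram": {int(k): int(c) for k, c in zip(ks, counts)},
            "uses_P": int(self.uses_P.sum()),
            "uses_nesting": int(self.uses_nesting.sum()),
        }

    # -- serialization -------------------------------------------------------

    def save(self, path) -> None:
        """Versioned JSON-lines: one header line, then one record per row."""
        with open(path, "w") as fh:
            fh.write(json.dumps(self.metadata) + "\n")
            for i in range(len(self)):
                rec = {
                    "locations": [int(x) for x in self.seqs[i]],
                    "K": int(self.K[i]),
                    "K_no_p": None
                    if self.K_no_p[i] == UNREACHABLE
                    else int(self.K_no_p[i]),
                    "K_no_nesting": None
                    if self.K_no_nesting[i] == UNREACHABLE
                    else int(self.K_no_nesting[i]),
                    "uses_P": bool(self.uses_P[i]),
                    "uses_nesting": bool(self.uses_nesting[i]),
                    "witnesses": self.witnesses[i][:3],
                }
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def load(cls, path) -> "ComplexityAtlas":
        with open(path) as fh:
            meta = json.loads(fh.readline())
            if meta.get("schema") != SCHEMA:
                raise LanguageError(f"not a {SCHEMA} file: {path}")
            rows = [json.loads(line) for line in fh if line.strip()]
        seqs = np.array([r["locations"] for r in rows], dtype=np.int8)
        K = np.array([r["K"] for r in rows], dtype=np.int16)
        K_no_p = np.array(
            [UNREACHABLE if r["K_no_p"] is None else r["K_no_p"] for r in rows],
            dtype=np.int16,
        )
        K_no_nesting = np.array(
            [
                UNREACHABLE if r["K_no_nesting"] is None else r["K_no_nesting"]
                for r in rows
            ],
            dtype=np.int16,
        )
        uses_p = np.array([r["uses_P"] for r in rows], dtype=bool)
        uses_nest = np.array([r["uses_nesting"] for r in rows], dtype=bool)
        wits = [r["witnesses"] for r in rows]
        return cls(seqs, K, K_no_p, K_no_nesting, uses_p, uses_nest, wits, meta)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": ["".join(map(str, row)) for row in self.seqs],
                "K": self.K,
                "K_no_p": self.K_no_p,
                "K_no_nesting": self.K_no_nesting,
                "uses_P": self.uses_P,
                "uses_nesting": self.uses_nesting,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


_default_atlas: Optional[ComplexityAtlas] = None


def default_atlas() -> ComplexityAtlas:
    """The origin-0 atlas under the default cost model, built once per
    process."""
    global _default_atlas
    if _default_atlas is None:
        _default_atlas = ComplexityAtlas.build(0)
    return _default_atlas


def enumerate_octagon_sequences(
    origin: int = 0, cost_model: CostModel = DEFAULT_COST_MODEL
) -> ComplexityAtlas:
    """Enumerate the sequence space from an origin and score every
    sequence (alias of :meth:`ComplexityAtlas.build`)."""
    return ComplexityAtlas.build(origin, cost_model)
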