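"""Branching-process model of mini-chromosome inheritance through cell division.

Each cell is described by a state ``(copies, expressing)``: the number of
mini-chromosome copies it carries (0..k_max) and how many of them still express
the GFP reporter.  At division, every copy is replicated into two sister
chromatids that segregate independently of the other copies:

* faithful segregation — one chromatid to each daughter
  (probability ``1 - p_nondisjunction - p_lag_loss``);
* nondisjunction — both chromatids to one daughter, chosen uniformly
  (``p_nondisjunction``); this is the source of double-GFP cells;
* anaphase-lag loss — one chromatid is lost; one daughter inherits a single
  chromatid, the other none (``p_lag_loss``).

Expression status is heritable: chromatids of an expressing copy are
expressing.  After segregation each expressing copy is independently and
permanently silenced with probability ``p_silence``, so silenced cells score
GFP-negative by flow cytometry while still carrying the chromosome.

For a one-copy mother the per-daughter probability of failing to inherit the
chromosome is ``(p_nondisjunction + p_lag_loss) / 2``, which is the quantity
the retention model ``f_n = f0 (1 - r)^n`` estimates.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from functools import lru_cache
from math import comb
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)

State = tuple[int, int]

__all__ = [
    "SegregationParams",
    "PopulationState",
    "FlowSample",
    "daughter_pair_distribution",
    "sample_division",
    "propagate_generation_stochastic",
    "propagate_generation_expected",
    "effective_loss_rate",
    "expected_retention",
    "classify_gfp",
    "retained_dna_fraction",
]


@dataclass(frozen=True)
class SegregationParams:
    """Per-division missegregation, loss and silencing probabilities.

    ``divisions_per_day`` defaults to 3 (DT40 doubling time ~8 h).  ``k_max``
    caps the tracked copy number; divisions that would exceed it are truncated
    with a logged warning.
    """

    p_nondisjunction: float = 0.0
    p_lag_loss: float = 0.0
    p_silence: float = 0.0
    divisions_per_day: int = 3
    k_max: int = 4

    def __post_init__(self) -> None:
        for name in ("p_nondisjunction", "p_lag_loss", "p_silence"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.p_nondisjunction + self.p_lag_loss > 1.0:
            raise ValueError("p_nondisjunction + p_lag_loss must not exceed 1")
        if self.divisions_per_day < 1:
            raise ValueError("divisions_per_day must be >= 1")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")


def _check_state(copies: int, expressing: int, k_max: int | None = None) -> None:
    if copies < 0 or expressing < 0 or expressing > copies:
        raise ValueError(f"invalid cell state (copies={copies}, expressing={expressing})")
    if k_max is not None and copies > k_max:
        raise ValueError(f"copies={copies} exceeds k_max={k_max}")


@dataclass
class PopulationState:
    """Cell counts indexed by ``(copies, expressing)``."""

    counts: dict[State, int]

    def __post_init__(self) -> None:
        cleaned: dict[State, int] = {}
        for (c, e), n in self.counts.items():
            _check_state(c, e)
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for state ({c}, {e})")
            if n:
                cleaned[(int(c), int(e))] = n
        if not cleaned:
            raise ValueError("population must contain at least one cell")
        self.counts = cleaned

    @classmethod
    def from_cells(cls, n_cells: int, copies: int = 1, expressing: int = 1) -> "PopulationState":
        return cls({(copies, expressing): int(n_cells)})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fractions(self) -> dict[State, float]:
        total = self.total
        return {state: n / total for state, n in self.counts.items()}


@dataclass(frozen=True)
class FlowSample:
    """GFP-class fractions observed at one flow-cytometry timepoint."""

    day: float
    fraction_gfp_negative: float
    fraction_gfp_single: float
    fraction_gfp_double: float

    def __post_init__(self) -> None:
        fracs = (
            self.fraction_gfp_negative,
            self.fraction_gfp_single,
            self.fraction_gfp_double,
        )
        if min(fracs) < 0 or abs(sum(fracs) - 1.0) > 1e-6:
            raise ValueError(f"GFP fractions must be non-negative and sum to 1, got {fracs}")


@lru_cache(maxsize=None)
def daughter_pair_distribution(
    copies: int, expressing: int, params: SegregationParams
) -> tuple[tuple[tuple[State, State], ...], tuple[float, ...]]:
    """Exact distribution of unordered daughter-state pairs for one division.

    Enumerates the independent per-copy segregation outcomes, applies binomial
    silencing to the expressing copies of each daughter, and truncates copy
    numbers above ``params.k_max``.  Cached per ``(copies, expressing, params)``.
    """
    _check_state(copies, expressing)
    pns, pll, psil = params.p_nondisjunction, params.p_lag_loss, params.p_silence
    pf = 1.0 - pns - pll
    # per-copy deltas: (d_copies_A, d_expr_A, d_copies_B, d_expr_B)
    expressing_outcomes = (
        ((1, 1, 1, 1), pf),
        ((2, 2, 0, 0), pns / 2),
        ((0, 0, 2, 2), pns / 2),
        ((1, 1, 0, 0), pll / 2),
        ((0, 0, 1, 1), pll / 2),
    )
    silenced_outcomes = (
        ((1, 0, 1, 0), pf),
        ((2, 0, 0, 0), pns / 2),
        ((0, 0, 2, 0), pns / 2),
        ((1, 0, 0, 0), pll / 2),
        ((0, 0, 1, 0), pll / 2),
    )
    dist: dict[tuple[int, int, int, int], float] = {(0, 0, 0, 0): 1.0}
    per_copy = (expressing_outcomes,) * expressing + (silenced_outcomes,) * (copies - expressing)
    for outcomes in per_copy:
        nxt: dict[tuple[int, int, int, int], float] = defaultdict(float)
        for key, p in dist.items():
            for delta, q in outcomes:
                if q > 0.0:
                    nxt[
                        (key[0] + delta[0], key[1] + delta[1], key[2] + delta[2], key[3] + delta[3])
                    ] += p * q
        dist = nxt

    if psil > 0.0:
        thinned: dict[tuple[int, int, int, int], float] = defaultdict(float)
        for (ca, ea, cb, eb), p in dist.items():
            for ka in range(ea + 1):
                wa = comb(ea, ka) * (1 - psil) ** ka * psil ** (ea - ka)
                for kb in range(eb + 1):
                    wb = comb(eb, kb) * (1 - psil) ** kb * psil ** (eb - kb)
                    thinned[(ca, ka, cb, kb)] += p * wa * wb
        dist = thinned

    pairs: dict[tuple[State, State], float] = defaultdict(float)
    truncated = False
    for (ca, ea, cb, eb), p in dist.items():
        if ca > params.k_max or cb > params.k_max:
            truncated = True
            ca, cb = min(ca, params.k_max), min(cb, params.k_max)
            ea, eb = min(ea, ca), min(eb, cb)
        a, b = sorted(((ca, ea), (cb, eb)))
        pairs[(a, b)] += p
    if truncated:
        logger.warning(
            "division of state (%d, %d) exceeded k_max=%d; copy number truncated",
            copies,
            expressing,
            params.k_max,
        )
    items = sorted(pairs.items())
    return tuple(k for k, _ in items), tuple(v for _, v in items)


def sample_division(
    copies: int,
    expressing: int,
    params: SegregationParams,
    rng: np.random.Generator,
) -> tuple[State, State]:
    """Draw one division outcome mechanistically, copy by copy.

    Independent of :func:`daughter_pair_distribution`, which serves as its
    exact oracle in tests.
    """
    _check_state(copies, expressing)
    pns, pll = params.p_nondisjunction, params.p_lag_loss
    pf = 1.0 - pns - pll
    ca = ea = cb = eb = 0
    for i in range(copies):
        expr = i < expressing
        u = rng.random()
        to_a = rng.random() < 0.5
        if u < pf:
            ca += 1
            cb += 1
            if expr:
                ea += 1
                eb += 1
        elif u < pf + pns:
            if to_a:
                ca += 2
                ea += 2 * expr
            else:
                cb += 2
                eb += 2 * expr
        else:  # anaphase-lag loss: one chromatid vanishes
            if to_a:
                ca += 1
                ea += 1 * expr
            else:
                cb += 1
                eb += 1 * expr
    if params.p_silence > 0.0:
        ea -= int(rng.binomial(ea, params.p_silence))
        eb -= int(rng.binomial(eb, params.p_silence))
    if ca > params.k_max or cb > params.k_max:
        logger.warning("daughter copy number exceeded k_max=%d; truncated", params.k_max)
        ca, cb = min(ca, params.k_max), min(cb, params.k_max)
        ea, eb = min(ea, ca), min(eb, cb)
    return (ca, ea), (cb, eb)


def _propagate_class_counts(
    counts: Mapping[State, np.ndarray],
    params: SegregationParams,
    rng: np.random.Generator,
) -> dict[State, np.ndarray]:
    """One synchronous generation for parallel populations (vector per class)."""
    out: dict[State, np.ndarray] = {}
    for (c, e), n in counts.items():
        n = np.asarray(n, dtype=np.int64)
        if not n.any():
            continue
        pairs, probs = daughter_pair_distribution(c, e, params)
        if len(pairs) == 1:
            draws = n[..., None]
        else:
            p = np.asarray(probs)
            draws = rng.multinomial(n, p / p.sum())
        for j, (da, db) in enumerate(pairs):
            col = draws[..., j]
            for d in (da, db):
                if d in out:
                    out[d] = out[d] + col
                else:
                    out[d] = col.copy()
    return {s: v for s, v in out.items() if np.any(v)}


def propagate_generation_stochastic(
    state: PopulationState,
    params: SegregationParams,
    rng: np.random.Generator,
) -> PopulationState:
    """Divide every cell once; per-class multinomial sampling of pair outcomes.

    The total cell count doubles exactly (lag losses remove chromatids, not
    cells).
    """
    counts = {s: np.asarray([n], dtype=np.int64) for s, n in state.counts.items()}
    out = _propagate_class_counts(counts, params, rng)
    return PopulationState({s: int(v[0]) for s, v in out.items()})


def propagate_generation_expected(
    distribution: Mapping[State, float],
    params: SegregationParams,
) -> dict[State, float]:
    """Exact one-generation transition applied to a state distribution.

    Deterministic twin of :func:`propagate_generation_stochastic`; input and
    output proportions both sum to 1.
    """
    total = sum(distribution.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"distribution must sum to 1, got {total}")
    out: dict[State, float] = defaultdict(float)
    for state, p in distribution.items():
        if p <= 0.0:
            continue
        pairs, probs = daughter_pair_distribution(state[0], state[1], params)
        for (da, db), q in zip(pairs, probs):
            half = 0.5 * p * q
            out[da] += half
            out[db] += half
    return dict(out)


def effective_loss_rate(params: SegregationParams) -> float:
    """Per-daughter probability of not inheriting the chromosome from a
    one-copy mother: ``(p_nondisjunction + p_lag_loss) / 2``."""
    return 0.5 * (params.p_nondisjunction + params.p_lag_loss)


def expected_retention(r_eff: float, n, f0: float = 1.0):
    """Retention model ``f_n = f0 (1 - r)^n``; n may be a scalar or array."""
    if not 0.0 <= r_eff <= 1.0:
        raise ValueError(f"r_eff must be in [0, 1], got {r_eff}")
    n = np.asarray(n)
    if np.any(n < 0):
        raise ValueError("n must be >= 0")
    if not 0.0 < f0 <= 1.0:
        raise ValueError(f"f0 must be in (0, 1], got {f0}")
    result = f0 * (1.0 - r_eff) ** n
    return float(result) if np.isscalar(result) or result.ndim == 0 else result


def classify_gfp(
    state: PopulationState | Mapping[State, int], day: float = 0.0
) -> FlowSample:
    """GFP-class fractions of a population: negative (0 expressing copies),
    single (1), double-or-more (>= 2).  Silenced copies do not express."""
    counts = state.counts if isinstance(state, PopulationState) else state
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("population is empty")
    neg = sum(n for (c, e), n in counts.items() if e == 0)
    single = sum(n for (c, e), n in counts.items() if e == 1)
    double = total - neg - single
    return FlowSample(day, neg / total, single / total, double / total)


def retained_dna_fraction(state: PopulationState | Mapping[State, int]) -> float:
    """Fraction of cells carrying at least one copy, regardless of expression."""
    counts = state.counts if isinstance(state, PopulationState) else state
    total = sum(counts.values())
    return sum(n for (c, _e), n in counts.items() if c >= 1) / total
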