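"""Efficient exact p-values for fixed-margin table statistics.

Computing a score's null probability by full enumeration costs O(n^4)
(signed-only tables) to O(n^6) (mixed tables).  This module implements the
class-decomposition approach: tables are grouped into nested classes
``M[S]``, ``M[S, n_++]``, ``M[S, n_++, n_--]`` (extended with ``n_r+`` and
``n_r-`` for mixed tables), whose innermost level is a one-degree-of-freedom
family swept by the elementary move ``sigma_1``.  The probability of each
innermost family is a short positive sum, and entire classes whose
maximum-probability table falls below a D-value threshold are discarded,
which is what makes large, sparse tables (universes of tens of thousands of
genes with a few hundred differentially expressed) tractable.

Margin-preserving integer moves are first-class objects here:

* *transpositions* exchange two different symbols between two prediction
  buckets (18 of them for 3x3 tables, 36 for 4x3);
* *minimal moves* are deduplicated sums of a few distinct transpositions;
* *principal moves* are the minimal moves that transition between adjacent
  classes of the hierarchy (change one class coordinate by a step, or the
  score by an attainable gap) with a minimal set of applicability
  constraints.

The tail accumulation in :func:`pvalue_fast` visits the same classes the
peak-to-peak walk would visit, but sweeps the class coordinates directly
(vectorised) and sums each innermost family along the ``sigma_1`` axis via
a convolution, so that with a zero threshold the result is exactly the
brute-force tail.  The threshold policy follows the maximum-D-value-times-
epsilon rule.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
import numpy as np
from scipy.special import gammaln

from .tables import (
    CountsTable,
    EmptyClassError,
    InfeasibleTableError,
    MarginSet,
    StatisticKind,
    collapse_signed,
    complete_table,
    dict_order,
    log_dtot,
    log_dvalue,
    max_score_table,
    min_score_table,
    score,
    _require_scoreable,
)

__all__ = [
    "MoveMatrix",
    "ClassKey",
    "ThresholdPolicy",
    "generate_transpositions",
    "generate_minimal_moves",
    "principal_moves",
    "score_steps",
    "max_probability_table",
    "score_probability",
    "pvalue_fast",
    "max_dvalue_reference",
]

_ROWS = {"3x3": ("p", "m", "0"), "4x3": ("p", "m", "r", "0")}
_COLS = ("p", "m", "0")
_SYM = {"p": "+", "m": "-", "0": "0", "r": "r"}

#: Maximum number of distinct transpositions combined into one minimal move.
#: Three suffices to realise every class-adjacent transition of the
#: hierarchy; larger combinations only produce reducible moves.
MAX_COMBINATION_SIZE = 3


@dataclass(frozen=True)
class MoveMatrix:
    """A margin-preserving integer adjustment of a counts table.

    ``deltas`` lists the per-cell adjustment in the dictionary enumeration
    ordering of the given shape.  ``decomposition`` records one witnessing
    multiset of transpositions, each as ``((bucket_i, sym_x), (bucket_j,
    sym_y))`` meaning "move an x from bucket i to bucket j and a y back".
    ``constraints`` are the cells the move decrements — the cells that must
    be positive (by the decrement amount) for the move to apply.
    """

    shape: str
    deltas: tuple[int, ...]
    decomposition: tuple[tuple[tuple[str, str], tuple[str, str]], ...]

    def __post_init__(self) -> None:
        if len(self.deltas) != len(dict_order(self.shape)):
            raise ValueError("delta vector does not match shape")

    def delta(self, cell: str) -> int:
        return self.deltas[dict_order(self.shape).index(cell)]

    @property
    def cell_deltas(self) -> dict[str, int]:
        return dict(zip(dict_order(self.shape), self.deltas))

    @property
    def constraints(self) -> frozenset[str]:
        return frozenset(c for c, d in self.cell_deltas.items() if d < 0)

    def delta_score(self, kind: StatisticKind = StatisticKind.QUATERNARY) -> int:
        d = self.cell_deltas
        if kind is StatisticKind.ENRICHMENT:
            return d.get("n_rp", 0) + d.get("n_rm", 0)
        base = d["n_pp"] + d["n_mm"] - d["n_mp"] - d["n_pm"]
        if kind is StatisticKind.QUATERNARY:
            base += d.get("n_rp", 0) + d.get("n_rm", 0)
        return base

    def apply(self, table: CountsTable) -> CountsTable:
        """Apply to a table; raises InfeasibleTableError if any cell drops
        below zero."""
        return table.apply_delta(self.cell_deltas)

    def __neg__(self) -> "MoveMatrix":
        return MoveMatrix(self.shape, tuple(-d for d in self.deltas),
                          tuple((b, a) for a, b in self.decomposition))

    def describe(self) -> str:
        """Human-readable decomposition, e.g. '(q+,+,q-)(q-,0,q+)'."""
        parts = []
        for (bi, x), (bj, y) in self.decomposition:
            parts.append(f"(q{_SYM[bi]},{_SYM[x]},q{_SYM[bj]})"
                         f"(q{_SYM[bj]},{_SYM[y]},q{_SYM[bi]})")
        return "".join(parts)


def _move_from_cells(shape: str, cells: dict[str, int],
                     decomposition) -> MoveMatrix:
    order = dict_order(shape)
    return MoveMatrix(shape, tuple(cells.get(c, 0) for c in order),
                      tuple(decomposition))


@lru_cache(maxsize=None)
def generate_transpositions(shape: str) -> tuple[MoveMatrix, ...]:
    """All transpositions for the table shape (18 for 3x3, 36 for 4x3).

    A transposition moves a symbol x from bucket i to bucket j and a
    different symbol y back, which preserves all margins.
    """
    rows = _ROWS[shape]
    out = []
    for a in range(len(rows)):
        for b in range(a + 1, len(rows)):
            for x in _COLS:
                for y in _COLS:
                    if x == y:
                        continue
                    cells = {
                        f"n_{rows[a]}{x}": -1, f"n_{rows[b]}{x}": +1,
                        f"n_{rows[b]}{y}": -1, f"n_{rows[a]}{y}": +1,
                    }
                    decomp = (((rows[a], x), (rows[b], y)),)
                    out.append(_move_from_cells(shape, cells, decomp))
    return tuple(out)


@lru_cache(maxsize=None)
def generate_minimal_moves(
        shape: str,
        max_size: int = MAX_COMBINATION_SIZE) -> tuple[MoveMatrix, ...]:
    """Deduplicated nonzero sums of up to ``max_size`` distinct transpositions.

    Each distinct resulting matrix is kept once, with a smallest witnessing
    decomposition.  The identity (zero matrix) is excluded.  Sums of many
    distinct transpositions reproduce moves that are already reachable by
    smaller combinations composed sequentially, so the catalogue is
    truncated at ``max_size``; every class-adjacent transition used by the
    inference algorithm is realised within this bound.
    """
    taus = generate_transpositions(shape)
    ncells = len(dict_order(shape))
    seen: dict[tuple[int, ...], MoveMatrix] = {}
    zero = (0,) * ncells
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(taus, size):
            deltas = tuple(sum(t.deltas[i] for t in combo)
                           for i in range(ncells))
            if deltas == zero or deltas in seen:
                continue
            decomp = tuple(itertools.chain.from_iterable(
                t.decomposition for t in combo))
            seen[deltas] = MoveMatrix(shape, deltas, decomp)
    return tuple(seen.values())


@lru_cache(maxsize=None)
def score_steps(shape: str) -> tuple[int, ...]:
    """Attainable positive score steps between adjacent score classes.

    These are the positive quaternary-score changes achievable by a single
    transposition; consecutive attained scores of the statistic differ by
    one of these values ({1, 2, 4} for both shapes).
    """
    steps = {t.delta_score() for t in generate_transpositions(shape)}
    return tuple(sorted(s for s in steps if s > 0))


#: Class-hierarchy coordinates per shape (after the score itself).
_CLASS_COORDS = {"3x3": ("n_pp", "n_mm"), "4x3": ("n_pp", "n_mm", "n_rp", "n_rm")}


def _constraint_minimal(moves: list[MoveMatrix]) -> list[MoveMatrix]:
    keep = []
    for mv in moves:
        cs = mv.constraints
        if any(other is not mv and other.constraints < cs for other in moves):
            continue
        keep.append(mv)
    return keep


def principal_moves(shape: str, transition: str) -> tuple[MoveMatrix, ...]:
    """Minimal moves realising one transition of the class hierarchy.

    ``transition`` is one of ``"decrease <coord>"`` / ``"increase <coord>"``
    for a class coordinate (``n_pp``, ``n_mm`` and, for 4x3, ``n_rp``,
    ``n_rm``) — these fix the score and every shallower coordinate —
    ``"score +k"`` / ``"score -k"`` for an attainable score step, or
    ``"inner"`` for the moves that sweep the innermost one-degree-of-freedom
    family (``sigma_1`` and its inverse).  Among signature-matching moves
    only those with a minimal constraint set are returned.
    """
    coords = _CLASS_COORDS[shape]
    catalogue = generate_minimal_moves(shape)

    def fixed(mv: MoveMatrix, upto: int) -> bool:
        return (mv.delta_score() == 0
                and all(mv.delta(c) == 0 for c in coords[:upto]))

    token = transition.strip()
    if token in ("inner", "inner sigma1", "inner σ1"):
        cands = [mv for mv in catalogue
                 if fixed(mv, len(coords)) and abs(mv.delta("n_mp")) == 1]
        return tuple(sorted(cands, key=lambda m: m.deltas))
    words = token.split()
    if len(words) == 2 and words[0] in ("decrease", "increase"):
        coord = words[1]
        if coord not in coords:
            raise ValueError(
                f"unknown class coordinate {coord!r} for shape {shape}")
        sign = -1 if words[0] == "decrease" else +1
        depth = coords.index(coord)
        cands = [mv for mv in catalogue
                 if fixed(mv, depth) and sign * mv.delta(coord) > 0]
        if not cands:
            return ()
        step = min(abs(mv.delta(coord)) for mv in cands)
        cands = [mv for mv in cands if abs(mv.delta(coord)) == step]
        return tuple(sorted(_constraint_minimal(cands),
                            key=lambda m: m.deltas))
    if len(words) == 2 and words[0] == "score":
        try:
            k = int(words[1])
        except ValueError:
            raise ValueError(f"malformed score transition {transition!r}")
        if k == 0:
            raise ValueError("score transition must be nonzero")
        if abs(k) not in score_steps(shape):
            return ()
        cands = [mv for mv in catalogue if mv.delta_score() == k]
        return tuple(sorted(_constraint_minimal(cands),
                            key=lambda m: m.deltas))
    raise ValueError(f"unknown transition {transition!r}")


@dataclass(frozen=True)
class ClassKey:
    """Coordinates of a table class in the enumeration hierarchy.

    ``coords`` is a prefix of ``(S, n_pp, n_mm[, n_rp, n_rm])``: the score
    alone selects ``M[S]``, deeper prefixes select progressively thinner
    classes down to the innermost one-degree-of-freedom family.
    """

    kind: StatisticKind
    coords: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.coords:
            raise ValueError("ClassKey needs at least the score coordinate")

    @property
    def score(self) -> int:
        return self.coords[0]


@dataclass(frozen=True)
class ThresholdPolicy:
    """D-value pruning policy: discard classes whose best table has a
    D-value below ``epsilon`` times the maximum D-value of any table with
    the same margins.  ``epsilon = 0`` disables pruning (exact mode)."""

    epsilon: float = 1e-16

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")

    @classmethod
    def exact(cls) -> "ThresholdPolicy":
        return cls(epsilon=0.0)

    def log_cutoff(self, margins: MarginSet) -> float:
        if self.epsilon == 0.0:
            return -math.inf
        return max_dvalue_reference(margins) + math.log(self.epsilon)


@lru_cache(maxsize=8192)
def _even_table_cells(margins: MarginSet) -> tuple[tuple[int, ...], ...]:
    """Greedily rounded independence table ``q_i * n_j / N`` (4x3 cells)."""
    m = margins
    qs = (m.q_plus, m.q_minus, m.q_r, m.q_zero)
    ns = (m.n_plus, m.n_minus, m.n_zero)
    cells = np.zeros((4, 3), dtype=np.int64)
    if m.N == 0:
        return tuple(map(tuple, cells))
    for i, q in enumerate(qs):
        targets = np.array([q * n / m.N for n in ns])
        base = np.floor(targets).astype(np.int64)
        rem = q - int(base.sum())
        order = np.argsort(-(targets - base))
        base[order[:rem]] += 1
        cells[i] = base
    # Row sums are exact; repair column sums by moving units between
    # columns inside whichever row has the most to spare.
    col_err = cells.sum(axis=0) - np.array(ns)
    while col_err.any():
        j_hi = int(np.argmax(col_err))
        j_lo = int(np.argmin(col_err))
        i = int(np.argmax(cells[:, j_hi]))
        cells[i, j_hi] -= 1
        cells[i, j_lo] += 1
        col_err = cells.sum(axis=0) - np.array(ns)
    return tuple(map(tuple, cells))


def max_dvalue_reference(margins: MarginSet) -> float:
    """Log of a reference close to the maximum D-value over all tables.

    The maximum-probability (= maximum-D) table is approximately the most
    evenly divided one, near the independence counts ``q_i * n_j / N``.
    The reference is the D-value of the greedily rounded independence
    table.  It is used only to anchor the pruning threshold: a reference
    slightly below the true maximum merely prunes a little less.
    """
    if margins.N == 0:
        return 0.0
    cells = _even_table_cells(margins)
    qs = (margins.q_plus, margins.q_minus, margins.q_r, margins.q_zero)
    out = 0.0
    for i, q in enumerate(qs):
        out += gammaln(q + 1) - sum(gammaln(c + 1) for c in cells[i])
    return float(out)


def _mode_score(margins: MarginSet) -> int:
    """Quaternary score of the (approximately) most probable table."""
    c = _even_table_cells(margins)
    return c[0][0] + c[1][1] + c[2][0] + c[2][1] - c[0][1] - c[1][0]


# ---------------------------------------------------------------------------
# Class enumeration internals
# ---------------------------------------------------------------------------

def _effective_margins(margins: MarginSet,
                       kind: StatisticKind) -> MarginSet:
    """Margins on which the statistic is a quaternary score.

    Correctness requires a fully signed table; enrichment collapses the
    signed rows into the unsigned row; the quaternary statistic uses the
    margins as given.
    """
    if kind is StatisticKind.CORRECTNESS:
        if margins.q_r > 0:
            raise ValueError("correctness statistic requires q_r == 0")
        return margins
    if kind is StatisticKind.ENRICHMENT:
        return collapse_signed(margins)
    return margins


def _score_range(margins: MarginSet) -> tuple[int, int]:
    lo = score(min_score_table(margins, StatisticKind.QUATERNARY)[0],
               StatisticKind.QUATERNARY)
    hi = score(max_score_table(margins, StatisticKind.QUATERNARY),
               StatisticKind.QUATERNARY)
    return lo, hi


_CHUNK_CELLS = 4_000_000

#: Target element count for one batched family-sum block.
_BATCH_CELLS = 4_000_000


@lru_cache(maxsize=64)
def _log_factorials(n: int) -> np.ndarray:
    """log(i!) for i = 0 .. ~4n, oversized so that index arithmetic on
    infeasible grid entries (masked out downstream) stays in bounds."""
    size = 1 << max(8, (4 * n + 8).bit_length())
    return gammaln(np.arange(size, dtype=np.float64) + 1.0)

@lru_cache(maxsize=65536)
def _window_log_numerator(margins: MarginSet, s_lo: int, s_hi: int,
                          epsilon: float) -> float:
    """Log of the summed D-values of all tables with score in [s_lo, s_hi].

    Sweeps the class hierarchy (n_pp, n_mm, n_rp, n_rm); each innermost
    one-degree-of-freedom family (the sigma_1 axis) is a short positive
    sum, evaluated for all surviving classes in vectorised batches.
    Classes whose separable D-value upper bound falls below the pruning
    cutoff are discarded.  The cutoff is ``epsilon`` times the smaller of
    the global maximum-D reference and the window's own best class bound,
    so a far-tail window is never discarded wholesale and the retained
    mass stays accurate to roughly ``epsilon`` in relative terms.  With
    ``epsilon = 0`` the sum is exact.
    """
    m = margins
    if s_lo > s_hi:
        return -math.inf
    if m.N == 0:
        return 0.0 if s_lo <= 0 <= s_hi else -math.inf
    lf = _log_factorials(m.N)
    top = len(lf) - 1
    lq = (lf[m.q_plus] + lf[m.q_minus] + lf[m.q_r] + lf[m.q_zero])
    X1 = min(m.q_plus, m.n_plus)
    X2 = min(m.q_minus, m.n_minus)
    # (n_rp, n_rm) pairs of the unsigned row.
    ev, fv = [], []
    for e0 in range(min(m.q_r, m.n_plus) + 1):
        fmax = min(m.q_r - e0, m.n_minus)
        ev.extend([e0] * (fmax + 1))
        fv.extend(range(fmax + 1))
    ev = np.asarray(ev, dtype=np.int64)
    fv = np.asarray(fv, dtype=np.int64)

    x1g = np.arange(X1 + 1, dtype=np.int64)[None, :, None]
    x2g = np.arange(X2 + 1, dtype=np.int64)[None, None, :]
    grid_cells = (X1 + 1) * (X2 + 1)
    chunk = max(1, _CHUNK_CELLS // max(grid_cells, 1))

    # Pass 1: flatten every feasible class; compute the family windows and
    # a separable upper bound on each class's best D-value.
    pieces: list[np.ndarray] = []
    for start in range(0, len(ev), chunk):
        eg = ev[start:start + chunk, None, None]
        fg = fv[start:start + chunk, None, None]
        k_hi = np.minimum(m.q_minus - x2g, m.n_plus - x1g - eg)
        m_hi = np.minimum(m.q_plus - x1g, m.n_minus - x2g - fg)
        dp = (m.n_plus - x1g - eg) + (m.n_minus - x2g - fg)
        cc = x1g + x2g + eg + fg
        c_a = np.maximum(np.maximum(0, dp - m.q_zero), cc - s_hi)
        c_b = np.minimum(k_hi + m_hi, cc - s_lo)
        feas = (k_hi >= 0) & (m_hi >= 0) & (c_a <= c_b)
        flat = np.flatnonzero(feas)
        if not len(flat):
            continue
        pi, i1, i2 = np.unravel_index(flat, feas.shape)
        e = ev[start:start + chunk][pi]
        f = fv[start:start + chunk][pi]
        x1 = i1.astype(np.int64)
        x2 = i2.astype(np.int64)
        pieces.append((m.q_minus - x2, m.n_plus - x1 - e,      # a1, b1
                       m.q_plus - x1, m.n_minus - x2 - f,      # a2, b2
                       dp.reshape(-1)[flat], c_a.reshape(-1)[flat],
                       c_b.reshape(-1)[flat], e, f, x1, x2))
    if not pieces:
        return -math.inf
    if len(pieces) > 1:
        a1, b1, a2, b2, dp, c_a, c_b, e, f, x1, x2 = (
            np.concatenate(parts) for parts in zip(*pieces))
    else:
        a1, b1, a2, b2, dp, c_a, c_b, e, f, x1, x2 = pieces[0]
    const = (lq - lf[x1] - lf[x2] - lf[e] - lf[f] - lf[m.q_r - e - f])
    k_hi = np.minimum(a1, b1)
    m_hi = np.minimum(a2, b2)
    if epsilon > 0.0:
        g1 = _concave_max(lf, a1, b1, np.maximum(0, c_a - m_hi),
                          np.minimum(k_hi, c_b))
        g2 = _concave_max(lf, a2, b2, np.maximum(0, c_a - k_hi),
                          np.minimum(m_hi, c_b))
        bound = const + g1 + g2 - lf[np.clip(m.q_zero - dp + c_a, 0, top)]
        cutoff = (math.log(epsilon)
                  + min(float(bound.max()), max_dvalue_reference(m)))
        keep = bound >= cutoff
        a1, b1, a2, b2, dp, c_a, c_b, const, k_hi, m_hi = (
            arr[keep] for arr in (a1, b1, a2, b2, dp, c_a, c_b,
                                  const, k_hi, m_hi))

    # Pass 2: exact family sums for the surviving classes.  Each family's
    # (k, m) rectangle is clipped to its effective window and batches group
    # families of similar window size.
    k_lo = np.maximum(0, c_a - m_hi)
    k_up = np.minimum(k_hi, c_b)
    m_lo = np.maximum(0, c_a - k_hi)
    m_up = np.minimum(m_hi, c_b)
    kw = k_up - k_lo
    mw = m_up - m_lo
    order = np.argsort(kw * mw, kind="stable")
    out: list[np.ndarray] = []
    pos = 0
    n = len(order)
    while pos < n:
        # Rows are sorted by rectangle size, so a batch sized from the
        # first row's rectangle and then re-clipped is near-homogeneous.
        rect0 = int((kw[order[pos]] + 1) * (mw[order[pos]] + 1))
        end = min(n, pos + max(1, _BATCH_CELLS // rect0))
        sel = order[pos:end]
        kmax = int(kw[sel].max())
        mmax = int(mw[sel].max())
        width = (kmax + 1) * (mmax + 1)
        if len(sel) * width > 2 * _BATCH_CELLS:
            end = min(n, pos + max(1, _BATCH_CELLS // width))
            sel = order[pos:end]
            kmax = int(kw[sel].max())
            mmax = int(mw[sel].max())
        pos = end
        out.append(_batched_family_log_sums(
            lf, m.q_zero, a1[sel], b1[sel], a2[sel], b2[sel], dp[sel],
            c_a[sel], c_b[sel], const[sel],
            k_lo[sel], k_up[sel], m_lo[sel], m_up[sel], kmax, mmax))
    vals = np.concatenate(out)
    peak = float(vals.max())
    if peak == -math.inf:
        return -math.inf
    return peak + math.log(float(np.exp(vals - peak).sum()))


def _concave_max(lf: np.ndarray, a, b, lo, hi) -> np.ndarray:
    """Vectorised max over integer k in [lo, hi] of
    -(lf[k] + lf[a-k] + lf[b-k]) for a discrete log-concave sequence."""
    with np.errstate(invalid="ignore"):
        s = a + b + 1
        disc = np.maximum(s * s - 4.0 * (a * b - 1.0), 0.0)
        root = (s - np.sqrt(disc)) / 2.0
    hi_eff = np.maximum(hi, lo)
    k0 = np.clip(np.floor(root).astype(np.int64), lo, hi_eff)
    k1 = np.clip(k0 + 1, lo, hi_eff)
    top = len(lf) - 1

    def val(k):
        # k is clipped into [lo, hi] with 0 <= lo and hi <= min(a, b),
        # so all three lookups are in range.
        return -(lf[k] + lf[a - k] + lf[b - k])

    return np.maximum(val(k0), val(k1))


def _batched_family_log_sums(lf, q_zero, a1, b1, a2, b2, dp, c_a, c_b,
                             const, k_lo, k_up, m_lo, m_up,
                             kwmax, mwmax) -> np.ndarray:
    """Exact log-sums of D-values for a batch of innermost families.

    Each family is parametrised by ``k = n_mp`` and ``m = n_pm`` with the
    score window restricting ``c = k + m`` to [c_a, c_b]; the zero-row
    factor depends on c only.  Families are evaluated on their effective
    (k, m) windows, padded to a common rectangle, and reduced in one
    einsum.  All terms are non-negative, so the reduction is free of
    cancellation and exact to double-precision accumulation.
    """
    top = len(lf) - 1
    kg = k_lo[:, None] + np.arange(kwmax + 1, dtype=np.int64)[None, :]
    mg = m_lo[:, None] + np.arange(mwmax + 1, dtype=np.int64)[None, :]

    def row_factors(a, b, grid, hi):
        # grid rows span [k_lo, k_lo + width]; entries beyond the row's
        # upper limit are masked (k_lo >= 0 and hi <= min(a, b) hold by
        # construction, so the factorial lookups stay in range).
        gc = np.minimum(grid, hi[:, None])
        lg = -(lf[gc] + lf[a[:, None] - gc] + lf[b[:, None] - gc])
        lg = np.where(grid <= hi[:, None], lg, -np.inf)
        scale = lg.max(axis=1)
        return np.exp(lg - scale[:, None]), scale

    G1, s1 = row_factors(a1, b1, kg, k_up)
    G2, s2 = row_factors(a2, b2, mg, m_up)
    clen = kwmax + mwmax + 1
    cg = (k_lo + m_lo)[:, None] + np.arange(clen, dtype=np.int64)[None, :]
    cmask = (cg >= c_a[:, None]) & (cg <= c_b[:, None])
    lh = -lf[np.clip(q_zero - dp[:, None] + cg, 0, top)]
    lh = np.where(cmask, lh, -np.inf)
    s3 = lh.max(axis=1)
    H = np.exp(lh - s3[:, None])
    tsum = (np.arange(kwmax + 1, dtype=np.int64)[:, None]
            + np.arange(mwmax + 1, dtype=np.int64)[None, :])
    H3 = np.lib.stride_tricks.as_strided(
        H, shape=(H.shape[0], kwmax + 1, mwmax + 1),
        strides=(H.strides[0], H.strides[1], H.strides[1]))
    tot = np.einsum("bm,bm->b", np.einsum("bk,bkm->bm", G1, H3), G2)
    scales = s1 + s2 + s3
    with np.errstate(divide="ignore"):
        out = np.where(tot > 0.0, np.log(tot) + scales + const, -np.inf)
    # The batched result is reliable when it lies within ~600 log-units of
    # the per-factor scales: terms flushed to zero in the scaled products
    # are then below e^-145 of the family total.  Families with strongly
    # misaligned factor peaks (possible under very wide score windows at
    # large margins) are redone with joint scaling, which is exact for
    # arbitrary dynamic range.
    redo = np.flatnonzero((tot <= 0.0) | (out < scales + const - 600.0))
    for i in redo:
        # Rebuild the log factors from the log-factorial table (an
        # individually underflowed factor may still carry the joint peak
        # once the zero-row factor is added).
        lg1 = np.where(kg[i] <= k_up[i],
                       -(lf[kg[i]] + lf[np.clip(a1[i] - kg[i], 0, top)]
                         + lf[np.clip(b1[i] - kg[i], 0, top)]), -np.inf)
        lg2 = np.where(mg[i] <= m_up[i],
                       -(lf[mg[i]] + lf[np.clip(a2[i] - mg[i], 0, top)]
                         + lf[np.clip(b2[i] - mg[i], 0, top)]), -np.inf)
        lh3 = np.where((tsum + (k_lo[i] + m_lo[i]) >= c_a[i])
                       & (tsum + (k_lo[i] + m_lo[i]) <= c_b[i]),
                       -lf[np.clip(q_zero - dp[i] + k_lo[i] + m_lo[i]
                                   + tsum, 0, top)], -np.inf)
        joint = lg1[:, None] + lg2[None, :] + lh3
        peak = joint.max()
        if peak > -math.inf:
            out[i] = (peak
                      + math.log(float(np.exp(joint - peak).sum()))
                      + const[i])
    return out


# ---------------------------------------------------------------------------
# Public inference operations
# ---------------------------------------------------------------------------

def _class_family_iter(margins: MarginSet, coords: tuple[int, ...]):
    """Yield (x1, x2, e, f, k) completions of a (possibly partial) class
    coordinate tuple (S[, n_pp[, n_mm[, n_rp[, n_rm]]]])."""
    m = margins
    s = coords[0]
    x1s = [coords[1]] if len(coords) > 1 else range(min(m.q_plus, m.n_plus) + 1)
    for x1 in x1s:
        x2s = ([coords[2]] if len(coords) > 2
               else range(min(m.q_minus, m.n_minus) + 1))
        for x2 in x2s:
            es = ([coords[3]] if len(coords) > 3
                  else range(min(m.q_r, m.n_plus - x1) + 1))
            for e in es:
                fs = ([coords[4]] if len(coords) > 4
                      else range(min(m.q_r - e, m.n_minus - x2) + 1))
                for f in fs:
                    c = x1 + x2 + e + f - s
                    if c < 0:
                        continue
                    k_hi = min(m.q_minus - x2, m.n_plus - x1 - e, c)
                    for k in range(max(0, c - (m.q_plus - x1),
                                       c - (m.n_minus - x2 - f)), k_hi + 1):
                        yield x1, x2, e, f, k


def _table_from_family(margins: MarginSet, s: int, x1: int, x2: int,
                       e: int, f: int, k: int) -> CountsTable:
    c = x1 + x2 + e + f - s
    free = dict(n_pp=x1, n_mm=x2, n_mp=k, n_pm=c - k)
    if margins.q_r:
        free.update(n_rp=e, n_rm=f)
    return complete_table(margins, free)


def max_probability_table(margins: MarginSet, kind: StatisticKind,
                          key: ClassKey,
                          current: CountsTable | None = None) -> CountsTable:
    """The maximum-probability table of the class selected by ``key``.

    The innermost families are unimodal (at most two adjacent modes), so
    the class mode is located by sweeping the class coordinates and reading
    each family's mode; ties are broken toward the dictionary-smallest
    table.  ``current``, when given, must share the margins and serves as
    the walk's starting point hint; it does not affect the result.

    Raises :class:`EmptyClassError` if no table has the requested
    coordinates.
    """
    eff = _effective_margins(margins, kind)
    if current is not None and current.margins != margins:
        raise ValueError("current table has different margins")
    best: tuple[float, tuple[int, ...], CountsTable] | None = None
    for x1, x2, e, f, k in _class_family_iter(eff, key.coords):
        try:
            t = _table_from_family(eff, key.score, x1, x2, e, f, k)
        except InfeasibleTableError:
            continue
        lp = log_dvalue(t)
        rank = (-lp, t.as_vector())
        if best is None or rank < (-best[0], best[1]):
            best = (lp, t.as_vector(), t)
    if best is None:
        raise EmptyClassError(f"no table in class {key.coords} for {eff}")
    return best[2]


def score_probability(margins: MarginSet, kind: StatisticKind, s: int,
                      policy: ThresholdPolicy = ThresholdPolicy()) -> float:
    """P(S = s) under the fixed-margin null, via class accumulation.

    With ``policy.epsilon == 0`` this equals the brute-force probability of
    the score class exactly (up to floating-point summation); with a
    positive epsilon, families whose best table falls below the D-value
    threshold are discarded.  Returns 0.0 for an empty score class.
    """
    eff = _effective_margins(margins, kind)
    lo, hi = _score_range(eff)
    if s < lo or s > hi:
        return 0.0
    mass = _window_log_numerator(eff, s, s, policy.epsilon)
    if mass == -math.inf:
        return 0.0
    return math.exp(mass - log_dtot(eff))


def pvalue_fast(margins: MarginSet, kind: StatisticKind, observed: int,
                policy: ThresholdPolicy = ThresholdPolicy()) -> float:
    """Upper-tail p-value P(S >= observed) via pruned class accumulation.

    Accumulates score classes on whichever side of the distribution the
    observed score falls: when the observed score exceeds the null mode,
    the upper tail is summed directly (a small, positive, cancellation-free
    sum); otherwise the complement of the lower tail is taken, which is the
    accurate and cheap side for p-values near one.  With ``epsilon = 0``
    the result reproduces the brute-force p-value exactly.
    """
    eff = _effective_margins(margins, kind)
    lo, hi = _score_range(eff)
    if observed <= lo:
        return 1.0
    if observed > hi:
        return 0.0
    ldt = log_dtot(eff)
    if observed > _mode_score(eff):
        upper = _window_log_numerator(eff, observed, hi, policy.epsilon)
        p = math.exp(upper - ldt)
    else:
        lower = _window_log_numerator(eff, lo, observed - 1, policy.epsilon)
        p = 1.0 - math.exp(lower - ldt)
    return min(1.0, max(0.0, p))
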