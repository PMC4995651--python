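"""Fixed-margin contingency tables for causal upstream-regulator scoring.

A putative upstream regulator predicts, for every gene in the universe, one
of four states: up-regulated (``+``), down-regulated (``-``), regulated with
unknown direction (``r``), or not regulated (``0``).  The expression profile
observes one of three states per gene (``+``, ``-``, ``0``).  Cross-tabulating
predictions against observations yields a 4x3 table whose margins are fixed
by the network (row margins ``q``) and the profile (column margins ``n``).

Under the null hypothesis that observed gene states are assigned at random
subject to the margins, the probability of a table is a generalized
hypergeometric ratio: the product of per-row multinomial coefficients (the
*D-value*) over the multinomial coefficient of the column margins (*D_tot*).

Three integer statistics are scored on a table:

* Enrichment score  ``ES = n_r+ + n_r-`` (sign-blind; its null is Fisher's
  exact test),
* Correctness score ``CS = n_++ + n_-- - (n_+- + n_-+)`` (signed edges only),
* Quaternary score  ``QS = n_++ + n_-- + n_r+ + n_r- - (n_+- + n_-+)``,
  which interpolates between ES and CS as the fraction of unsigned edges
  varies.

This module holds the domain types, the log-space table probability, the
score functions, the evenness (dispersion) measure used to locate
high-probability tables, and closed-form constructions of the extreme-score
tables.  Everything here is pure computation on small integer tables.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "StatisticKind",
    "MarginSet",
    "CountsTable",
    "InfeasibleTableError",
    "EmptyClassError",
    "CELL_NAMES",
    "dict_order",
    "complete_table",
    "table_log_probability",
    "log_dvalue",
    "log_dtot",
    "score",
    "evenness",
    "max_score_table",
    "min_score_table",
    "collapse_signed",
    "most_even_table",
]


class InfeasibleTableError(Exception):
    """No table exists with the requested margins / cell values.

    Raised when derived cells would be negative.  Distinct from
    :class:`ValueError`, which signals malformed arguments.
    """


class EmptyClassError(Exception):
    """A requested table class (score / coordinate slice) contains no table."""


class StatisticKind(enum.Enum):
    """The three scoring statistics defined on a prediction/observation table."""

    ENRICHMENT = "enrichment"
    CORRECTNESS = "correctness"
    QUATERNARY = "quaternary"


#: Canonical storage order of the twelve cells (row-major over the 4x3 table).
CELL_NAMES = (
    "n_pp", "n_pm", "n_p0",
    "n_mp", "n_mm", "n_m0",
    "n_rp", "n_rm", "n_r0",
    "n_0p", "n_0m", "n_00",
)

#: Dictionary (enumeration) ordering of the free cells, 3x3 case.  The first
#: four entries are the degrees of freedom; the rest are margin-determined.
DICT_ORDER_3X3 = (
    "n_pp", "n_mm", "n_mp", "n_pm",
    "n_p0", "n_m0", "n_0p", "n_0m", "n_00",
)

#: Dictionary ordering for the 4x3 case: class coordinates first
#: (n_pp, n_mm, n_rp, n_rm), then the inner coordinate n_mp, then n_pm,
#: then the margin-determined cells.
DICT_ORDER_4X3 = (
    "n_pp", "n_mm", "n_rp", "n_rm", "n_mp", "n_pm",
    "n_p0", "n_m0", "n_r0", "n_0p", "n_0m", "n_00",
)


def dict_order(shape: str) -> tuple[str, ...]:
    """Return the cell enumeration order for ``shape`` ('3x3' or '4x3')."""
    if shape == "3x3":
        return DICT_ORDER_3X3
    if shape == "4x3":
        return DICT_ORDER_4X3
    raise ValueError(f"unknown table shape {shape!r}; expected '3x3' or '4x3'")


@dataclass(frozen=True)
class MarginSet:
    """Fixed row and column margins of a prediction/observation table.

    Row margins count the regulator's predictions: ``q_plus`` up-regulated,
    ``q_minus`` down-regulated, ``q_r`` regulated without sign, ``q_zero``
    not predicted.  Column margins count the observed profile: ``n_plus``
    up, ``n_minus`` down, ``n_zero`` unchanged.  Both must sum to the same
    universe size ``N``.
    """

    q_plus: int
    q_minus: int
    q_r: int
    q_zero: int
    n_plus: int
    n_minus: int
    n_zero: int

    def __post_init__(self) -> None:
        for name in ("q_plus", "q_minus", "q_r", "q_zero",
                     "n_plus", "n_minus", "n_zero"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValueError(f"margin {name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"margin {name} must be >= 0, got {v}")
        if self.q_plus + self.q_minus + self.q_r + self.q_zero != self.N:
            raise ValueError(
                "row margins and column margins must sum to the same total "
                f"(rows {self.q_plus + self.q_minus + self.q_r + self.q_zero}, "
                f"columns {self.N})"
            )

    @property
    def N(self) -> int:
        """Universe size (total gene count)."""
        return self.n_plus + self.n_minus + self.n_zero

    @property
    def shape(self) -> str:
        """'3x3' when there are no unsigned predictions, else '4x3'."""
        return "3x3" if self.q_r == 0 else "4x3"


@dataclass(frozen=True)
class CountsTable:
    """A full 4x3 table of prediction-vs-observation counts.

    Cells follow the naming ``n_<row><col>`` with rows ``p`` (+), ``m`` (-),
    ``r`` (unsigned), ``0`` (not predicted) and columns ``p``/``m``/``0``.
    When ``margins.q_r == 0`` the ``r`` row is identically zero and the
    table is effectively 3x3.
    """

    margins: MarginSet
    n_pp: int
    n_pm: int
    n_p0: int
    n_mp: int
    n_mm: int
    n_m0: int
    n_rp: int
    n_rm: int
    n_r0: int
    n_0p: int
    n_0m: int
    n_00: int

    def __post_init__(self) -> None:
        m = self.margins
        cells = self.cells()
        if any(c < 0 for c in cells.values()):
            raise InfeasibleTableError(f"negative cell in {cells}")
        rows = {
            "q_plus": self.n_pp + self.n_pm + self.n_p0,
            "q_minus": self.n_mp + self.n_mm + self.n_m0,
            "q_r": self.n_rp + self.n_rm + self.n_r0,
            "q_zero": self.n_0p + self.n_0m + self.n_00,
        }
        for name, total in rows.items():
            if total != getattr(m, name):
                raise InfeasibleTableError(
                    f"row sum {name}: {total} != margin {getattr(m, name)}")
        cols = {
            "n_plus": self.n_pp + self.n_mp + self.n_rp + self.n_0p,
            "n_minus": self.n_pm + self.n_mm + self.n_rm + self.n_0m,
            "n_zero": self.n_p0 + self.n_m0 + self.n_r0 + self.n_00,
        }
        for name, total in cols.items():
            if total != getattr(m, name):
                raise InfeasibleTableError(
                    f"column sum {name}: {total} != margin {getattr(m, name)}")

    def cells(self) -> dict[str, int]:
        """All twelve cells keyed by name, in canonical order."""
        return {name: getattr(self, name) for name in CELL_NAMES}

    def as_vector(self, shape: str | None = None) -> tuple[int, ...]:
        """Cell values in the dictionary (enumeration) ordering."""
        shape = shape or self.margins.shape
        return tuple(getattr(self, name) for name in dict_order(shape))

    def apply_delta(self, deltas: Mapping[str, int]) -> "CountsTable":
        """Return a new table with ``deltas`` added cell-wise.

        Raises :class:`InfeasibleTableError` if the result is not a valid
        table for the same margins.
        """
        new = {name: getattr(self, name) + deltas.get(name, 0)
               for name in CELL_NAMES}
        return CountsTable(margins=self.margins, **new)


def complete_table(margins: MarginSet,
                   free_cells: Mapping[str, int]) -> CountsTable:
    """Build the unique table with ``margins`` and the given free cells.

    The free-cell parametrization is ``n_pp, n_mm, n_mp, n_pm`` for a 3x3
    table (four degrees of freedom) plus ``n_rp, n_rm`` for 4x3 (six).
    Cells not named default to zero.  The remaining cells are derived from
    the margin equations.

    Raises
    ------
    ValueError
        If a non-free cell is named, or a free cell is negative.
    InfeasibleTableError
        If any derived cell would be negative (no such table exists).
    """
    allowed = {"n_pp", "n_mm", "n_mp", "n_pm"}
    if margins.q_r > 0:
        allowed |= {"n_rp", "n_rm"}
    extra = set(free_cells) - allowed
    if extra:
        raise ValueError(
            f"cells {sorted(extra)} are not free for a {margins.shape} table; "
            f"free cells are {sorted(allowed)}")
    vals = {name: int(free_cells.get(name, 0)) for name in
            ("n_pp", "n_mm", "n_mp", "n_pm", "n_rp", "n_rm")}
    if any(v < 0 for v in vals.values()):
        raise ValueError(f"free cells must be >= 0, got {free_cells}")
    m = margins
    derived = {
        "n_p0": m.q_plus - vals["n_pp"] - vals["n_pm"],
        "n_m0": m.q_minus - vals["n_mp"] - vals["n_mm"],
        "n_r0": m.q_r - vals["n_rp"] - vals["n_rm"],
        "n_0p": m.n_plus - vals["n_pp"] - vals["n_mp"] - vals["n_rp"],
        "n_0m": m.n_minus - vals["n_pm"] - vals["n_mm"] - vals["n_rm"],
    }
    derived["n_00"] = m.q_zero - derived["n_0p"] - derived["n_0m"]
    bad = {k: v for k, v in {**vals, **derived}.items() if v < 0}
    if bad:
        raise InfeasibleTableError(
            f"margins {m} admit no table with free cells {dict(free_cells)}: "
            f"derived {bad} negative")
    return CountsTable(margins=m, **vals, **derived)


def log_dvalue(table: CountsTable) -> float:
    """Log of the table's D-value (the null-probability numerator).

    The D-value is the number of permutations of gene labels that leave the
    table unchanged: the product over rows of the multinomial coefficient
    ``C(q_i; n_i+, n_i-, n_i0)``.
    """
    m = table.margins
    lg = math.lgamma
    out = 0.0
    for q, cells in (
        (m.q_plus, (table.n_pp, table.n_pm, table.n_p0)),
        (m.q_minus, (table.n_mp, table.n_mm, table.n_m0)),
        (m.q_r, (table.n_rp, table.n_rm, table.n_r0)),
        (m.q_zero, (table.n_0p, table.n_0m, table.n_00)),
    ):
        out += lg(q + 1) - sum(lg(c + 1) for c in cells)
    return out


def log_dtot(margins: MarginSet) -> float:
    """Log of D_tot: the multinomial count of all margin-respecting assignments."""
    lg = math.lgamma
    return (lg(margins.N + 1) - lg(margins.n_plus + 1)
            - lg(margins.n_minus + 1) - lg(margins.n_zero + 1))


def table_log_probability(table: CountsTable) -> float:
    """Log-probability of ``table`` under the fixed-margin null.

    Equals ``log_dvalue(table) - log_dtot(table.margins)``; always <= 0.
    Computed entirely via log-factorials so that universe sizes in the tens
    of thousands do not overflow.
    """
    return log_dvalue(table) - log_dtot(table.margins)


def score(table: CountsTable, kind: StatisticKind) -> int:
    """Integer score of ``table`` under the given statistic.

    ``CORRECTNESS`` is defined on signed edges only and therefore rejects
    tables with unsigned predictions (``q_r > 0``).  ``ENRICHMENT`` reads
    the unsigned row only; callers scoring a mixed table for enrichment
    should first collapse the signed rows (see :func:`collapse_signed`).
    """
    if kind is StatisticKind.ENRICHMENT:
        return table.n_rp + table.n_rm
    if kind is StatisticKind.CORRECTNESS:
        if table.margins.q_r > 0:
            raise ValueError(
                "the correctness score is defined only on fully signed "
                "networks (q_r == 0); drop or reassign unsigned edges first")
        return table.n_pp + table.n_mm - (table.n_pm + table.n_mp)
    if kind is StatisticKind.QUATERNARY:
        return (table.n_pp + table.n_mm + table.n_rp + table.n_rm
                - (table.n_pm + table.n_mp))
    raise ValueError(f"unknown statistic {kind!r}")


def _d3(x: int, y: int, z: int) -> int:
    return (x - y) ** 2 + (x - z) ** 2 + (y - z) ** 2


def evenness(table: CountsTable) -> int:
    """Dispersion d(T) of the cell counts; 0 iff all compared cells agree.

    For a 3x3 table this is the six-term sum of squared pairwise differences
    within each row and each column.  For 4x3 the ``r`` row contributes its
    own row term and the column terms extend to all pairwise squared
    differences among each column's four cells.  The most evenly divided
    table (minimum d) approximates the maximum-probability table.
    """
    t = table
    if t.margins.q_r == 0:
        return (_d3(t.n_pp, t.n_pm, t.n_p0) + _d3(t.n_mp, t.n_mm, t.n_m0)
                + _d3(t.n_0p, t.n_0m, t.n_00)
                + _d3(t.n_pp, t.n_mp, t.n_0p) + _d3(t.n_pm, t.n_mm, t.n_0m)
                + _d3(t.n_p0, t.n_m0, t.n_00))
    rows = (_d3(t.n_pp, t.n_pm, t.n_p0) + _d3(t.n_mp, t.n_mm, t.n_m0)
            + _d3(t.n_rp, t.n_rm, t.n_r0) + _d3(t.n_0p, t.n_0m, t.n_00))
    cols = 0
    for col in ((t.n_pp, t.n_mp, t.n_rp, t.n_0p),
                (t.n_pm, t.n_mm, t.n_rm, t.n_0m),
                (t.n_p0, t.n_m0, t.n_r0, t.n_00)):
        for i in range(4):
            for j in range(i + 1, 4):
                cols += (col[i] - col[j]) ** 2
    return rows + cols


def collapse_signed(margins: MarginSet) -> MarginSet:
    """Fold the signed prediction rows into the unsigned row.

    This is the margin transformation under which the Quaternary statistic
    reduces to the Enrichment statistic: every predicted target is treated
    as regulated-without-sign.
    """
    return MarginSet(
        q_plus=0, q_minus=0,
        q_r=margins.q_plus + margins.q_minus + margins.q_r,
        q_zero=margins.q_zero,
        n_plus=margins.n_plus, n_minus=margins.n_minus,
        n_zero=margins.n_zero,
    )


def _require_scoreable(margins: MarginSet, kind: StatisticKind) -> None:
    if kind is StatisticKind.CORRECTNESS and margins.q_r > 0:
        raise ValueError("correctness statistic requires q_r == 0")
    if kind is StatisticKind.ENRICHMENT and (margins.q_plus or margins.q_minus):
        raise ValueError(
            "enrichment operates on sign-collapsed margins; apply "
            "collapse_signed(margins) first")


def max_score_table(margins: MarginSet, kind: StatisticKind) -> CountsTable:
    """The (3x3: unique) table attaining the maximum score.

    Greedy construction: place as many observed ``+`` in the ``+`` row and
    observed ``-`` in the ``-`` row as capacities allow, route remaining
    differentially expressed genes through the ``r`` row (for the
    quaternary/enrichment statistics) and then the not-predicted row, and
    fill everything else with unchanged genes.
    """
    _require_scoreable(margins, kind)
    m = margins
    n_pp = min(m.q_plus, m.n_plus)
    n_mm = min(m.q_minus, m.n_minus)
    n_rp = min(m.q_r, m.n_plus - n_pp)
    n_rm = min(m.q_r - n_rp, m.n_minus - n_mm)
    n_0p = min(m.q_zero, m.n_plus - n_pp - n_rp)
    n_0m = min(m.q_zero - n_0p, m.n_minus - n_mm - n_rm)
    # Whatever differential expression remains is forced into wrong cells.
    n_mp = m.n_plus - n_pp - n_rp - n_0p
    n_pm = m.n_minus - n_mm - n_rm - n_0m
    return complete_table(m, dict(n_pp=n_pp, n_mm=n_mm, n_mp=n_mp, n_pm=n_pm,
                                  **({"n_rp": n_rp, "n_rm": n_rm}
                                     if m.q_r else {})))


def min_score_table(margins: MarginSet,
                    kind: StatisticKind) -> tuple[CountsTable, ...]:
    """Tables attaining the minimum score.

    For a 3x3 table the minimizer is unique and follows the closed-form
    assignment ``n_+- = min(q_+, n_-)``, ``n_-+ = min(q_-, n_+)`` with the
    not-predicted row absorbing the remaining differential expression.  In
    the 4x3 case the minimum is attained by a one-degree-of-freedom family:
    when differentially expressed genes are forced into the ``r`` row, the
    split between ``n_r+`` and ``n_r-`` can slide against the not-predicted
    row without changing the score.
    """
    _require_scoreable(margins, kind)
    m = margins
    # Maximal wrong placements (each scores -1; for enrichment margins the
    # signed buckets are empty and these are zero).
    n_pm = min(m.q_plus, m.n_minus)
    n_mp = min(m.q_minus, m.n_plus)
    cap_p = m.q_plus - n_pm
    cap_m = m.q_minus - n_mp
    rem_p = m.n_plus - n_mp
    rem_m = m.n_minus - n_pm
    # Unchanged genes prefer the signed and r buckets, freeing the
    # not-predicted bucket for the remaining differential expression.
    z = m.n_zero
    z_p = min(cap_p, z); z -= z_p
    z_m = min(cap_m, z); z -= z_m
    z_r = min(m.q_r, z); z -= z_r
    z_0 = z
    cap_0 = m.q_zero - z_0
    cap_r = m.q_r - z_r
    # Remaining DE genes: not-predicted row first (free), then the r row,
    # then correct cells (each of the latter two costs +1).
    n_0p = min(cap_0, rem_p)
    n_0m = min(cap_0 - n_0p, rem_m)
    rem_p -= n_0p
    rem_m -= n_0m
    n_rp = min(cap_r, rem_p)
    n_rm = min(cap_r - n_rp, rem_m)
    rem_p -= n_rp
    rem_m -= n_rm
    n_pp = min(cap_p - z_p, rem_p)
    n_mm = min(cap_m - z_m, rem_m)
    rem_p -= n_pp
    rem_m -= n_mm
    if rem_p or rem_m:  # pragma: no cover - capacities always suffice
        raise InfeasibleTableError(f"could not place all symbols for {m}")
    base = complete_table(m, dict(n_pp=n_pp, n_mm=n_mm, n_mp=n_mp, n_pm=n_pm,
                                  **({"n_rp": n_rp, "n_rm": n_rm}
                                     if m.q_r else {})))
    if m.q_r == 0:
        return (base,)
    # 1-dof family: exchange a + in the r row against a - in the 0 row
    # (and vice versa); score e+f is unchanged.
    family = [base]
    for step in (+1, -1):
        t = base
        while True:
            try:
                t = t.apply_delta({"n_rp": step, "n_rm": -step,
                                   "n_0p": -step, "n_0m": step})
            except InfeasibleTableError:
                break
            family.append(t)
    family.sort(key=lambda t: t.as_vector())
    return tuple(family)


def most_even_table(margins: MarginSet) -> CountsTable:
    """A locally most evenly divided table (minimal dispersion d).

    Starts from a feasible table and hill-climbs with single margin-
    preserving transpositions until no move decreases d.  Used as the
    anchor for the maximum-D-value reference of the thresholding policy.
    """
    return _hill_climb(margins, lambda t: -float(evenness(t)))


def _transposition_deltas(shape: str) -> list[dict[str, int]]:
    rows = ["p", "m", "0"] if shape == "3x3" else ["p", "m", "r", "0"]
    cols = ["p", "m", "0"]
    out = []
    for a in range(len(rows)):
        for b in range(a + 1, len(rows)):
            for x in cols:
                for y in cols:
                    if x == y:
                        continue
                    out.append({
                        f"n_{rows[a]}{x}": -1, f"n_{rows[b]}{x}": +1,
                        f"n_{rows[b]}{y}": -1, f"n_{rows[a]}{y}": +1,
                    })
    return out


def _hill_climb(margins: MarginSet, objective) -> CountsTable:
    t = max_score_table(margins, StatisticKind.QUATERNARY
                        if margins.q_r else StatisticKind.CORRECTNESS)
    moves = _transposition_deltas(margins.shape)
    best = objective(t)
    improved = True
    while improved:
        improved = False
        for mv in moves:
            try:
                cand = t.apply_delta(mv)
            except InfeasibleTableError:
                continue
            val = objective(cand)
            if val > best + 1e-12:
                t, best = cand, val
                improved = True
    return t
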