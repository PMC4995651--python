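"""Exhaustive enumeration of fixed-margin tables and exact score nulls.

This module is the reference implementation: it enumerates every table with
the given margins, accumulates the full null distribution of a statistic,
and computes exact tail p-values by direct summation.  It is deliberately
simple and is the oracle against which the efficient class-based algorithm
in :mod:`causalq.fast_inference` is validated.  Cost grows polynomially in
the universe size (degree 4 for signed-only tables, degree 6 for mixed
tables), so enumeration is guarded by a size cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Mapping

from .tables import (
    CountsTable,
    MarginSet,
    StatisticKind,
    complete_table,
    table_log_probability,
    score,
    _require_scoreable,
)

__all__ = ["ScoreDistribution", "enumerate_tables", "score_distribution",
           "pvalue_exact", "EnumerationCapExceeded", "DEFAULT_N_CAP"]

DEFAULT_N_CAP = 60


class EnumerationCapExceeded(Exception):
    """Refusal to enumerate: the universe exceeds the configured cap."""


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact null distribution of an integer score statistic.

    ``pmf`` maps each attained score to its probability; probabilities are
    non-negative and sum to one up to floating-point accumulation error.
    """

    margins: MarginSet
    kind: StatisticKind
    pmf: Mapping[int, float]

    @property
    def support(self) -> tuple[int, ...]:
        return tuple(sorted(self.pmf))

    def pvalue(self, observed: int) -> float:
        """Upper-tail probability P(S >= observed).

        Off-support values are allowed: at or below the minimum the whole
        mass (1.0) is returned, above the maximum 0.0.
        """
        return math.fsum(p for s, p in self.pmf.items() if s >= observed)


def enumerate_tables(margins: MarginSet,
                     n_cap: int = DEFAULT_N_CAP) -> Iterator[CountsTable]:
    """Yield every feasible table with ``margins`` exactly once.

    Free cells are swept in the dictionary enumeration ordering
    (``n_pp, n_mm, [n_rp, n_rm,] n_mp, n_pm``) with feasibility pruning, so
    the stream order is deterministic.
    """
    if margins.N > n_cap:
        raise EnumerationCapExceeded(
            f"universe size {margins.N} exceeds the enumeration cap {n_cap}; "
            "raise n_cap explicitly if this is intentional")
    m = margins
    for n_pp in range(min(m.q_plus, m.n_plus) + 1):
        for n_mm in range(min(m.q_minus, m.n_minus) + 1):
            for n_rp in range(min(m.q_r, m.n_plus - n_pp) + 1):
                for n_rm in range(min(m.q_r - n_rp, m.n_minus - n_mm) + 1):
                    mp_hi = min(m.q_minus - n_mm, m.n_plus - n_pp - n_rp)
                    for n_mp in range(mp_hi + 1):
                        pm_hi = min(m.q_plus - n_pp,
                                    m.n_minus - n_mm - n_rm)
                        for n_pm in range(pm_hi + 1):
                            # Remaining cells are margin-determined; the only
                            # constraint left to check is n_00 >= 0.
                            n_0p = m.n_plus - n_pp - n_mp - n_rp
                            n_0m = m.n_minus - n_pm - n_mm - n_rm
                            if m.q_zero - n_0p - n_0m < 0:
                                continue
                            free = dict(n_pp=n_pp, n_mm=n_mm,
                                        n_mp=n_mp, n_pm=n_pm)
                            if m.q_r:
                                free.update(n_rp=n_rp, n_rm=n_rm)
                            yield complete_table(m, free)


def score_distribution(margins: MarginSet, kind: StatisticKind,
                       n_cap: int = DEFAULT_N_CAP) -> ScoreDistribution:
    """Exact null distribution of ``kind`` by full enumeration."""
    _require_scoreable(margins, kind)
    acc: dict[int, list[float]] = {}
    for t in enumerate_tables(margins, n_cap=n_cap):
        acc.setdefault(score(t, kind), []).append(
            math.exp(table_log_probability(t)))
    pmf = {s: math.fsum(ps) for s, ps in acc.items()}
    return ScoreDistribution(margins=margins, kind=kind, pmf=pmf)


def pvalue_exact(margins: MarginSet, kind: StatisticKind, observed: int,
                 n_cap: int = DEFAULT_N_CAP) -> float:
    """Exact upper-tail p-value P(S >= observed) by full enumeration."""
    return score_distribution(margins, kind, n_cap=n_cap).pvalue(observed)
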