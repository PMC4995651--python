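"""From a mixed causal network and a DE profile to ranked regulators.

A causal network is a set of directed edges ``source -> target`` labelled
``+`` (the regulator's activity increases the target transcript), ``-``
(decreases it) or ``r`` (regulates it, direction unknown or conflicting).
Given a differential-expression profile assigning each measured gene +1,
-1 or 0, every regulator is tested under two hypotheses — that it is
itself up-regulated, or down-regulated (which flips all signed
predictions) — by tabulating predictions against observations, scoring
the table with the enrichment, correctness and quaternary statistics, and
computing exact null p-values.  Benjamini-Hochberg adjustment across all
regulator x direction hypotheses yields the final ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .fast_inference import ThresholdPolicy, pvalue_fast
from .tables import (
    CountsTable,
    MarginSet,
    StatisticKind,
    complete_table,
    score,
)

__all__ = [
    "CausalNetwork",
    "DEProfile",
    "RegulatorResult",
    "collapse_conflicts",
    "build_table",
    "enrichment_view",
    "correctness_view",
    "score_all",
    "fdr_adjust",
]

RELATIONS = ("+", "-", "r")


@dataclass(frozen=True)
class CausalNetwork:
    """A conflict-free causal edge set.

    ``edges`` maps each source regulator to a mapping of target gene ->
    relation in {'+', '-', 'r'}.  Build instances through
    :func:`collapse_conflicts` (or the file reader), which merges duplicate
    source/target pairs.
    """

    edges: Mapping[str, Mapping[str, str]]
    conflict_count: int = 0

    @property
    def regulators(self) -> tuple[str, ...]:
        return tuple(sorted(self.edges))

    @property
    def targets(self) -> frozenset[str]:
        out: set[str] = set()
        for tmap in self.edges.values():
            out.update(tmap)
        return frozenset(out)

    def n_edges(self) -> int:
        return sum(len(t) for t in self.edges.values())

    def targets_of(self, regulator: str) -> Mapping[str, str]:
        if regulator not in self.edges:
            raise KeyError(f"regulator {regulator!r} not in network")
        return self.edges[regulator]


def collapse_conflicts(
        raw_edges: Iterable[tuple[str, str, str]]) -> CausalNetwork:
    """Merge duplicate (source, target) pairs into a single relation.

    Identical relations deduplicate silently; a ``+``/``-`` conflict — two
    sources of evidence asserting opposite directions — collapses to the
    ambiguous relation ``r``, as does any pairing that already involves
    ``r``.  The number of collapsed sign conflicts is recorded on the
    returned network.
    """
    edges: dict[str, dict[str, str]] = {}
    conflicts = 0
    for src, tgt, rel in _normalise(raw_edges):
        tmap = edges.setdefault(src, {})
        old = tmap.get(tgt)
        if old is None or old == rel:
            tmap[tgt] = rel
        else:
            tmap[tgt] = "r"
            conflicts += 1
    return CausalNetwork(edges=edges, conflict_count=conflicts)


def _normalise(raw_edges):
    for i, (src, tgt, rel) in enumerate(raw_edges, start=1):
        if rel not in RELATIONS:
            raise ValueError(
                f"edge {i} ({src!r} -> {tgt!r}): relation must be one of "
                f"{RELATIONS}, got {rel!r}")
        yield str(src), str(tgt), rel


@dataclass(frozen=True)
class DEProfile:
    """Ternary differential-expression calls: gene -> +1, -1 or 0."""

    values: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = {g: v for g, v in self.values.items() if v not in (-1, 0, 1)}
        if bad:
            raise ValueError(
                f"profile values must be in {{+1, -1, 0}}; offending "
                f"entries: {dict(list(bad.items())[:5])}")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.values)

    def __getitem__(self, gene: str) -> int:
        return self.values.get(gene, 0)

    def counts(self, universe: Iterable[str]) -> tuple[int, int, int]:
        """(n_plus, n_minus, n_zero) over ``universe``; genes absent from
        the profile count as unchanged."""
        up = down = zero = 0
        for g in universe:
            v = self.values.get(g, 0)
            if v > 0:
                up += 1
            elif v < 0:
                down += 1
            else:
                zero += 1
        return up, down, zero


def resolve_universe(network: CausalNetwork, profile: DEProfile,
                     policy: str | Iterable[str] = "intersection"
                     ) -> tuple[str, ...]:
    """The gene universe defining table size N and the 0-prediction row.

    ``"intersection"`` (default) uses profile genes that are targets of at
    least one regulator; ``"profile"`` uses all profile genes;
    ``"targets"`` all network target nodes.  An explicit iterable of gene
    ids is accepted as-is.
    """
    if not isinstance(policy, str):
        return tuple(sorted(set(policy)))
    if policy == "intersection":
        return tuple(sorted(network.targets & profile.genes))
    if policy == "profile":
        return tuple(sorted(profile.genes))
    if policy == "targets":
        return tuple(sorted(network.targets))
    raise ValueError(
        f"unknown universe policy {policy!r}; expected 'intersection', "
        "'profile', 'targets' or an explicit gene collection")


def build_table(network: CausalNetwork, regulator: str, direction: str,
                profile: DEProfile,
                universe: str | Iterable[str] = "intersection"
                ) -> CountsTable:
    """Tabulate one regulator-direction hypothesis against the profile.

    Rows are the hypothesis' predictions: under the ``"up"`` hypothesis
    the edge labels are the predictions; under ``"down"`` the signed
    predictions flip (``r`` and not-predicted are direction-blind).
    Universe genes without an edge from the regulator fill the
    not-predicted row.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    genes = resolve_universe(network, profile, universe)
    if not genes:
        raise ValueError("empty gene universe")
    tmap = network.targets_of(regulator)
    flip = direction == "down"
    cells = {name: 0 for name in
             ("n_pp", "n_pm", "n_p0", "n_mp", "n_mm", "n_m0",
              "n_rp", "n_rm", "n_r0", "n_0p", "n_0m", "n_00")}
    row_for = {"+": "m" if flip else "p", "-": "p" if flip else "m", "r": "r"}
    col_for = {1: "p", -1: "m", 0: "0"}
    for g in genes:
        rel = tmap.get(g)
        row = row_for[rel] if rel is not None else "0"
        cells[f"n_{row}{col_for[profile[g]]}"] += 1
    margins = MarginSet(
        q_plus=cells["n_pp"] + cells["n_pm"] + cells["n_p0"],
        q_minus=cells["n_mp"] + cells["n_mm"] + cells["n_m0"],
        q_r=cells["n_rp"] + cells["n_rm"] + cells["n_r0"],
        q_zero=cells["n_0p"] + cells["n_0m"] + cells["n_00"],
        n_plus=cells["n_pp"] + cells["n_mp"] + cells["n_rp"] + cells["n_0p"],
        n_minus=cells["n_pm"] + cells["n_mm"] + cells["n_rm"] + cells["n_0m"],
        n_zero=cells["n_p0"] + cells["n_m0"] + cells["n_r0"] + cells["n_00"],
    )
    return CountsTable(margins=margins, **cells)


def enrichment_view(table: CountsTable) -> CountsTable:
    """The table with signed rows folded into the unsigned row.

    The enrichment statistic is sign-blind: every predicted target counts
    as regulated-without-direction.
    """
    m = table.margins
    margins = MarginSet(
        q_plus=0, q_minus=0, q_r=m.q_plus + m.q_minus + m.q_r,
        q_zero=m.q_zero, n_plus=m.n_plus, n_minus=m.n_minus,
        n_zero=m.n_zero)
    return complete_table(margins, dict(
        n_rp=table.n_pp + table.n_mp + table.n_rp,
        n_rm=table.n_pm + table.n_mm + table.n_rm))


def correctness_view(table: CountsTable) -> CountsTable:
    """The table with unsigned edges ignored (their targets re-filed as
    not predicted), as required by the correctness statistic."""
    m = table.margins
    margins = MarginSet(
        q_plus=m.q_plus, q_minus=m.q_minus, q_r=0,
        q_zero=m.q_zero + m.q_r, n_plus=m.n_plus, n_minus=m.n_minus,
        n_zero=m.n_zero)
    return complete_table(margins, dict(
        n_pp=table.n_pp, n_pm=table.n_pm,
        n_mp=table.n_mp, n_mm=table.n_mm))


_VIEWS = {
    StatisticKind.ENRICHMENT: enrichment_view,
    StatisticKind.CORRECTNESS: correctness_view,
    StatisticKind.QUATERNARY: lambda t: t,
}


@dataclass(frozen=True)
class RegulatorResult:
    """Scores and p-values for one regulator-direction hypothesis."""

    regulator: str
    direction: str
    table: CountsTable
    scores: Mapping[StatisticKind, int]
    pvalues: Mapping[StatisticKind, float]
    adjusted: Mapping[StatisticKind, float] = field(default_factory=dict)


def score_all(network: CausalNetwork, profile: DEProfile,
              statistics: Sequence[StatisticKind] = tuple(StatisticKind),
              policy: ThresholdPolicy = ThresholdPolicy(),
              universe: str | Iterable[str] = "intersection",
              sort_by: StatisticKind = StatisticKind.QUATERNARY,
              adjust: bool = True) -> list[RegulatorResult]:
    """Score every regulator under both direction hypotheses.

    For each hypothesis the quaternary table is built once; the
    enrichment and correctness statistics evaluate their respective views
    of it.  Raw upper-tail p-values come from the fast exact algorithm;
    per statistic, Benjamini-Hochberg adjustment runs across all
    hypotheses.  Results are sorted by the adjusted (or raw, if
    ``adjust=False``) p-value of ``sort_by``, ties broken by raw p-value
    and then regulator id.
    """
    statistics = tuple(statistics)
    genes = resolve_universe(network, profile, universe)
    if not set(genes) & profile.genes and profile.genes:
        raise ValueError("network and profile share no genes")
    results: list[RegulatorResult] = []
    for reg in network.regulators:
        for direction in ("up", "down"):
            table = build_table(network, reg, direction, profile, genes)
            scores: dict[StatisticKind, int] = {}
            pvals: dict[StatisticKind, float] = {}
            for kind in statistics:
                view = _VIEWS[kind](table)
                obs = score(view, kind)
                scores[kind] = obs
                pvals[kind] = pvalue_fast(view.margins, kind, obs, policy)
            results.append(RegulatorResult(
                regulator=reg, direction=direction, table=table,
                scores=scores, pvalues=pvals))
    if adjust:
        adj_by_kind = {
            kind: fdr_adjust([r.pvalues[kind] for r in results])
            for kind in statistics}
        results = [
            RegulatorResult(
                regulator=r.regulator, direction=r.direction, table=r.table,
                scores=r.scores, pvalues=r.pvalues,
                adjusted={k: adj_by_kind[k][i] for k in statistics})
            for i, r in enumerate(results)]
        key = lambda r: (r.adjusted[sort_by], r.pvalues[sort_by],
                         r.regulator, r.direction)
    else:
        key = lambda r: (r.pvalues[sort_by], r.regulator, r.direction)
    if sort_by not in statistics:
        raise ValueError(f"sort_by statistic {sort_by} was not computed")
    return sorted(results, key=key)


def fdr_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    arr = np.asarray(list(pvalues), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])
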