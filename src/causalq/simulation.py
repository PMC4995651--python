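"""Planted-regulator simulation for the three scoring statistics.

The design emulates a transcriptome-wide experiment: a universe of 20,000
transcripts with 5,000 potential upstream regulators, of which only two are
materialised.  An *active, up-regulated* regulator R1 drives 100 downstream
transcripts with random signs; an *inactive* regulator R2 shares exactly
the same 100 targets but disagrees with R1 on the direction of 50 of them.
Each simulated expression profile assigns differential expression to 15 %
of R1's targets concordantly with its up-regulation and to 5 % discordantly,
and adds 200 down- and 300 up-regulated background transcripts outside
R1's target set.  The remaining 4,998 regulators are represented solely by
the Bonferroni significance threshold 0.05 / 5,000 = 1e-5.

To probe robustness to incomplete sign knowledge, a growing fraction of
the network's signed edges is relabelled as unsigned (``r``), and the
enrichment, correctness and quaternary p-values of R1 and R2 (up
hypothesis) are recomputed at each fraction.  The quaternary statistic
coincides with correctness at fraction 0 and with enrichment at fraction
1, per replicate and exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fast_inference import ThresholdPolicy, pvalue_fast
from .network_scoring import (
    CausalNetwork,
    DEProfile,
    build_table,
    correctness_view,
    enrichment_view,
)
from .tables import StatisticKind, score

__all__ = [
    "SimConfig",
    "make_planted_network",
    "ambiguate",
    "simulate_profile",
    "ambiguity_sweep",
    "summarize_sweep",
]

R1 = "R1"
R2 = "R2"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the two-regulator planted simulation.

    Defaults reproduce the reference design; ``n_regulators`` enters only
    through the Bonferroni significance threshold.
    """

    n_transcripts: int = 20000
    n_regulators: int = 5000
    n_targets: int = 100
    n_sign_disagree: int = 50
    frac_correct: float = 0.15
    frac_incorrect: float = 0.05
    n_background_down: int = 200
    n_background_up: int = 300
    ambiguity_fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    replicates: int = 100
    seed: int = 0
    epsilon: float = 1e-16

    def __post_init__(self) -> None:
        if not 0 <= self.frac_correct <= 1 or not 0 <= self.frac_incorrect <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_correct + self.frac_incorrect > 1:
            raise ValueError("correct + incorrect fractions exceed 1")
        if self.n_sign_disagree > self.n_targets:
            raise ValueError("cannot disagree on more targets than exist")
        if self.n_targets > self.n_transcripts:
            raise ValueError("more planted targets than transcripts")
        n_bg = self.n_background_down + self.n_background_up
        if n_bg > self.n_transcripts - self.n_targets:
            raise ValueError("background DE exceeds the non-target pool")
        if any(not 0 <= f <= 1 for f in self.ambiguity_fractions):
            raise ValueError("ambiguity fractions must lie in [0, 1]")

    @property
    def threshold(self) -> float:
        """Bonferroni significance level 0.05 / n_regulators."""
        return 0.05 / self.n_regulators

    @property
    def n_correct(self) -> int:
        return round(self.frac_correct * self.n_targets)

    @property
    def n_incorrect(self) -> int:
        return round(self.frac_incorrect * self.n_targets)


def _transcripts(config: SimConfig) -> list[str]:
    width = len(str(config.n_transcripts))
    return [f"T{i:0{width}d}" for i in range(1, config.n_transcripts + 1)]


def make_planted_network(config: SimConfig,
                         rng: np.random.Generator | int | None = None
                         ) -> CausalNetwork:
    """Build the two-regulator network with planted sign structure.

    R1 receives ``n_targets`` signed edges with independent fair-coin
    signs; R2 targets the same transcripts, agreeing with R1 everywhere
    except on a random subset of ``n_sign_disagree`` targets whose signs
    flip.
    """
    rng = np.random.default_rng(rng)
    genes = _transcripts(config)
    targets = [genes[i] for i in
               rng.choice(config.n_transcripts, size=config.n_targets,
                          replace=False)]
    signs = rng.integers(0, 2, size=config.n_targets)  # 1 -> '+', 0 -> '-'
    disagree = set(rng.choice(config.n_targets,
                              size=config.n_sign_disagree, replace=False))
    r1 = {t: "+" if s else "-" for t, s in zip(targets, signs)}
    r2 = {t: ("-" if s else "+") if i in disagree else ("+" if s else "-")
          for i, (t, s) in enumerate(zip(targets, signs))}
    return CausalNetwork(edges={R1: r1, R2: r2})


def ambiguate(network: CausalNetwork, fraction: float,
              rng: np.random.Generator | int | None = None) -> CausalNetwork:
    """Relabel a random fraction of the signed edges as unsigned.

    Exactly ``floor(fraction * signed_edge_count)`` edges, drawn uniformly
    without replacement across the whole network, become ``r``; topology
    is untouched (no edges are inserted or deleted).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    rng = np.random.default_rng(rng)
    signed = [(src, tgt) for src, tmap in sorted(network.edges.items())
              for tgt, rel in sorted(tmap.items()) if rel in "+-"]
    n_flip = int(np.floor(fraction * len(signed)))
    chosen = {signed[i] for i in
              rng.choice(len(signed), size=n_flip, replace=False)} \
        if n_flip else set()
    edges = {src: {tgt: ("r" if (src, tgt) in chosen else rel)
                   for tgt, rel in tmap.items()}
             for src, tmap in network.edges.items()}
    return CausalNetwork(edges=edges, conflict_count=network.conflict_count)


def simulate_profile(network: CausalNetwork, config: SimConfig,
                     rng: np.random.Generator | int | None = None
                     ) -> DEProfile:
    """Draw one expression profile from R1's active (up-regulated) state.

    ``n_correct`` of R1's targets change concordantly with their edge sign
    and ``n_incorrect`` discordantly (disjoint uniform draws); background
    differential expression is drawn from transcripts outside R1's target
    set.  All other transcripts are unchanged.  The true (pre-ambiguation)
    edge signs must be used, so pass the planted network here.
    """
    rng = np.random.default_rng(rng)
    genes = _transcripts(config)
    tmap = network.targets_of(R1)
    targets = sorted(tmap)
    if any(rel not in "+-" for rel in tmap.values()):
        raise ValueError(
            "profiles are generated from the true signed network; "
            "ambiguate afterwards")
    n_c, n_i = config.n_correct, config.n_incorrect
    picked = rng.choice(len(targets), size=n_c + n_i, replace=False)
    values: dict[str, int] = {g: 0 for g in genes}
    for j in picked[:n_c]:
        g = targets[j]
        values[g] = 1 if tmap[g] == "+" else -1
    for j in picked[n_c:]:
        g = targets[j]
        values[g] = -1 if tmap[g] == "+" else 1
    non_targets = sorted(set(genes) - set(targets))
    n_bg = config.n_background_down + config.n_background_up
    if n_bg > len(non_targets):
        raise ValueError("background DE exceeds the non-target pool")
    bg = rng.choice(len(non_targets), size=n_bg, replace=False)
    for j in bg[:config.n_background_down]:
        values[non_targets[j]] = -1
    for j in bg[config.n_background_down:]:
        values[non_targets[j]] = 1
    return DEProfile(values=values)


_STAT_VIEW = {
    StatisticKind.ENRICHMENT: enrichment_view,
    StatisticKind.CORRECTNESS: correctness_view,
    StatisticKind.QUATERNARY: lambda t: t,
}


def ambiguity_sweep(config: SimConfig) -> pd.DataFrame:
    """Run the full replicate x ambiguity-fraction experiment.

    For every replicate a fresh planted network and profile are drawn;
    for every ambiguity fraction a fresh random edge subset is relabelled
    unsigned, and R1 and R2 are scored under the up hypothesis with all
    three statistics (the universe is the full transcript set).  Returns
    a long-format frame with one row per
    (replicate, fraction, regulator, statistic).

    All randomness descends from ``config.seed``; the sweep is
    bit-for-bit reproducible.
    """
    policy = ThresholdPolicy(epsilon=config.epsilon)
    rows: list[dict] = []
    root = np.random.SeedSequence(config.seed)
    for rep, rep_seq in enumerate(root.spawn(config.replicates)):
        net_seq, prof_seq, amb_seq = rep_seq.spawn(3)
        network = make_planted_network(config, np.random.default_rng(net_seq))
        profile = simulate_profile(network, config,
                                   np.random.default_rng(prof_seq))
        universe = tuple(sorted(profile.genes))
        amb_seqs = amb_seq.spawn(len(config.ambiguity_fractions))
        for frac, frac_seq in zip(config.ambiguity_fractions, amb_seqs):
            ambiguous = ambiguate(network, frac,
                                  np.random.default_rng(frac_seq))
            for reg in (R1, R2):
                table = build_table(ambiguous, reg, "up", profile, universe)
                for kind in StatisticKind:
                    view = _STAT_VIEW[kind](table)
                    obs = score(view, kind)
                    p = pvalue_fast(view.margins, kind, obs, policy)
                    rows.append(dict(
                        replicate=rep, fraction=frac, regulator=reg,
                        statistic=kind.value, score=obs, pvalue=p))
    return pd.DataFrame(rows)


def summarize_sweep(results: pd.DataFrame) -> pd.DataFrame:
    """Per-fraction mean of -log10 p for each regulator and statistic."""
    df = results.copy()
    df["neglog10_p"] = -np.log10(df["pvalue"].clip(lower=1e-300))
    out = (df.groupby(["regulator", "statistic", "fraction"])
             ["neglog10_p"].mean().reset_index()
             .rename(columns={"neglog10_p": "mean_neglog10_p"}))
    return out
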