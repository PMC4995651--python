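"""Rank upstream regulators of a small differential-expression profile.

Builds a six-gene toy system in which regulator TF1's predictions match
the observed changes (including one target whose direction of regulation
is unknown) while TF2's predictions point the wrong way, then scores
every regulator under both direction hypotheses.
"""

from causalq import (DEProfile, StatisticKind, collapse_conflicts,
                     score_all)

network = collapse_conflicts([
    ("TF1", "g1", "+"), ("TF1", "g2", "+"), ("TF1", "g3", "-"),
    ("TF1", "g4", "r"),
    ("TF2", "g1", "-"), ("TF2", "g3", "+"), ("TF2", "g5", "+"),
])
profile = DEProfile(values={"g1": 1, "g2": 1, "g3": -1, "g4": 1,
                            "g5": 0, "g6": 0})

results = score_all(network, profile, universe="profile")

print(f"{'regulator':<10}{'direction':<10}{'QS':>4}{'p(QS)':>10}"
      f"{'FDR(QS)':>10}")
for r in results:
    qs = StatisticKind.QUATERNARY
    print(f"{r.regulator:<10}{r.direction:<10}{r.scores[qs]:>4}"
          f"{r.pvalues[qs]:>10.4f}{r.adjusted[qs]:>10.4f}")

# TF1(up) should lead: all four of its targets moved as predicted (the
# unsigned edge to g4 still counts as evidence), giving the largest
# quaternary score and the smallest exact p-value.  TF2's signed
# predictions are anti-correlated with the data, so its up-hypothesis
# scores negatively and its down-hypothesis explains only part of the
# profile.
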