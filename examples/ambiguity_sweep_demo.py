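"""How sign ambiguity degrades the three scoring statistics.

Runs a small version of the planted two-regulator experiment: an active
regulator R1 and an inactive look-alike R2 share 100 targets but
disagree on 50 signs; profiles are simulated from R1's up-regulated
state, and a growing fraction of edges is stripped of its sign.  The
full-size experiment (20,000 transcripts, 100 replicates) runs the same
way via ``causalq simulate``.
"""

import math

from causalq import SimConfig, ambiguity_sweep, summarize_sweep

config = SimConfig(replicates=3, seed=42)
results = ambiguity_sweep(config)
summary = summarize_sweep(results)

print(f"Bonferroni threshold: -log10 p = "
      f"{-math.log10(config.threshold):.1f}\n")
table = summary.pivot_table(index="fraction",
                            columns=["regulator", "statistic"],
                            values="mean_neglog10_p").round(2)
print(table.to_string())

# Reading the table: the enrichment (ES) column is flat — relabelling
# edge signs cannot change a sign-blind statistic.  Correctness (CS)
# starts strong for R1 but decays toward 0 as edges lose their signs.
# The quaternary statistic tracks CS at fraction 0, ES at fraction 1,
# and stays above the significance line for R1 throughout, while R2
# remains non-significant until most sign information is gone.
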