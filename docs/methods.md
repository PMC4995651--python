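# Methods

## Null model

A regulator–direction hypothesis partitions the gene universe into four
prediction buckets (up `+`, down `-`, unsigned `r`, not predicted `0`);
the expression profile partitions it into three observation classes
(`+`, `-`, `0`).  With both partitions fixed, the cross-tabulation T is a
4×3 table with fixed row margins (q₊, q₋, q_r, q₀) and column margins
(n₊, n₋, n₀).  The null hypothesis randomises the assignment of observed
states to genes subject to the margins; the probability of a table is
the number of assignments producing it (the *D-value*, a product of
per-row multinomial coefficients) divided by the total number of
margin-respecting assignments (D_tot = C(N; n₊, n₋, n₀)).  All D-values
are handled as log-factorials (`scipy.special.gammaln`), so universes of
tens of thousands of genes never overflow.

The three statistics — enrichment ES, correctness CS, quaternary QS —
are linear in the table cells.  Internally every p-value reduces to the
quaternary statistic on transformed margins: the correctness statistic
requires q_r = 0 (unsigned targets are re-filed as not-predicted by
`correctness_view`), and the enrichment statistic collapses both signed
rows into the unsigned row (`enrichment_view` / `collapse_signed`).
These transformations make the limit identities (QS = CS at q_r = 0,
QS = ES at q₊ = q₋ = 0) hold bit-for-bit, not just numerically.

## Exact tail computation

Tables with the same margins are organised by the dictionary ordering
(n_++, n_−−, n_r+, n_r−, n_−+, n_+−, …): fixing the score S and the
leading cells yields nested classes M[S] ⊃ M[S, n_++] ⊃ … down to a
one-degree-of-freedom family swept by the elementary move
σ₁ = (0, 0, −1, 1, −1, 1, 1, −1, 0), along which the probability
sequence is unimodal with at most two adjacent modes (the ratio of
consecutive D-values is a monotone rational function of n_−+).

The tail Σ_{S ≥ S₀} P(S) is accumulated class by class.  For each class
(n_++, n_−−, n_r+, n_r−) the inner family is the set of (n_−+, n_+−)
splits whose sum c = n_−+ + n_+− lies in the window implied by the score
bounds; its mass factorises as Σ_c h(c) Σ_{k+m=c} g₁(k) g₂(m), with g₁
and g₂ the row factors of the `-` and `+` rows and h the not-predicted
row's zero-column factor, which depends on c only.  These sums involve
only non-negative terms, so they are free of cancellation; they are
evaluated in vectorised batches over classes (the k+m coupling is a
Hankel-structured tensor handled by a strided view).  Each batch is
scaled by the per-factor maxima; if a family's result lands more than
600 log-units below its scales — possible only when the factor peaks
are strongly misaligned under very wide score windows — that family is
recomputed with joint scaling, which is exact for arbitrary dynamic
range.  With the pruning threshold disabled the accumulation visits
every feasible table exactly once and reproduces brute-force enumeration
to full double precision (verified to 1e-12 relative error on hundreds
of random margin sets).

Whether the upper tail is summed directly or via the complement of the
lower tail is decided by comparing the observed score with the score of
the (approximately) most probable table: observed scores above the mode
give small p-values, which must be summed directly to preserve relative
accuracy; observed scores at or below the mode give p-values of order
one, where the complement is both accurate and cheap.

## Thresholding

Following the D-value thresholding scheme, a class is discarded when an
upper bound on its best table's D-value falls below ε times a reference
maximum D-value (default ε = 1e-16; ε = 0 disables pruning).  The
reference (`max_dvalue_reference`) is the D-value of the greedily
rounded independence table q_i·n_j/N — the most evenly divided table is
the most probable one, and a slightly low reference only prunes less.
Two refinements keep the scheme sound in the far tail: the cutoff is
anchored at the *smaller* of the global reference and the accumulated
window's own best class bound, so the tail of a highly significant score
is never discarded wholesale and the retained mass stays accurate to
roughly ε in relative terms; and the per-class bound is separable
(independent maxima of the three log-concave factors, located through
the closed-form root of the ratio equation), hence always an
over-estimate, so pruning never removes a class above threshold.

## Moves

Margin-preserving integer moves are first-class objects.  The 18 (3×3)
or 36 (4×3) transpositions exchange two different symbols between two
prediction buckets.  The minimal-move catalogue consists of the
deduplicated nonzero sums of at most three distinct transpositions; this
bound realises every class-adjacent transition used by the algorithm
(validated by the reachability test: iterated principal moves from the
minimum-score table visit every nonempty score class) while excluding
composite moves that repeat transpositions.  Principal moves for a
transition ("decrease n_++ fixing S", "score +k", the inner σ₁ pair, and
the 4×3 analogues for n_r+/n_r−) are obtained by filtering the catalogue
on its effect signature and keeping moves with minimal constraint sets
(the cells a move decrements).  Attainable score steps are the positive
score changes of single transpositions — {1, 2, 4} for both shapes —
which matches the enumerated support gaps of the correctness statistic.

`max_probability_table` locates the mode of any class by sweeping the
class coordinates and reading each inner family's closed-form mode; this
is the same set of tables the peak-to-peak walk visits, evaluated
exhaustively so the returned table is guaranteed to be the class
maximum (checked against enumeration).

## Extreme-score tables

The maximum-score table follows the greedy assignment n_++ = min(q₊,
n₊), n_−− = min(q₋, n₋), remaining differential expression routed
through the r row, then the not-predicted row, with any residue forced
into wrong cells; for 3×3 margins it is the unique maximiser.  The
minimum-score construction maximises wrong placements (n_+− = min(q₊,
n₋), n_−+ = min(q₋, n₊)) and routes leftover differential expression
into the not-predicted row first; when capacity forces DE genes into the
r row the minimiser is a one-degree-of-freedom family obtained by
sliding the (n_r+, n_r−) split against the not-predicted row.  The
returned family is a subset of the argmin set (sign-row variants of
equal score exist for some margins); attainment of the true minimum is
verified against enumeration.

## Network scoring

The gene universe defaults to the intersection of profile genes and
network target nodes; "all profile genes" and "all network targets" are
selectable (the simulation uses all profile genes, making N the
transcriptome size).  Both direction hypotheses are always evaluated;
the down hypothesis swaps the `+` and `-` prediction rows.  Duplicate
edges collapse before scoring: identical labels deduplicate, opposing
signs and any pairing with `r` collapse to `r`.  Benjamini–Hochberg
adjustment (statsmodels) runs per statistic across all regulator ×
direction hypotheses.

## Simulation design

The planted experiment emulates a transcriptome of 20,000 transcripts
and 5,000 candidate regulators.  Only two regulators are materialised:
R1 (active, up-regulated) with 100 signed targets (independent fair-coin
signs; the sign mix is not otherwise constrained), and R2 sharing the
same 100 targets with 50 signs flipped.  Each replicate assigns
differential expression to 15 targets concordantly and 5 discordantly
with R1's up-regulation, plus 200 down- and 300 up-regulated background
transcripts drawn outside R1's target set (disjointness keeps the
planted effect size exact).  The absent 4,998 regulators enter only
through the Bonferroni threshold 0.05/5,000 = 1e-5.  Ambiguation
relabels ⌊fraction × 200⌋ uniformly chosen signed edges as `r`, redrawn
independently per replicate and fraction (nesting across fractions is
an equally defensible reading; independent redraws match the
independent-simulation framing).  All randomness descends from one seed
through `numpy.random.SeedSequence.spawn`, making the sweep reproducible
bit for bit.

The full universe is retained rather than scaled down: the planted
correctness signal (CS = 10 against ~500 background DE genes) clears the
1e-5 threshold only when the null expectation of chance agreement is
kept small, which requires the 20,000-gene universe; the algorithm's
cost is insensitive to the not-predicted count, so the full design also
runs comfortably (about 5 s per replicate across five fractions; the
100-replicate sweep takes ~8 minutes on one CPU).  Replicates are set to
100 (the delivered study size); the per-fraction means are stable at
this size.

What the simulation does *not* emulate: edge insertion/deletion noise,
correlated expression changes, regulator cascades deeper than one step,
and realistic degree distributions — conclusions about those require
real networks.

## Numerical choices and limitations

* Probabilities are exact positive sums; p-values are clamped to [0, 1]
  only to absorb last-ulp excursions.
* Ties when ranking hypotheses break by raw p-value, then regulator id,
  then direction, so output order is deterministic.
* Degenerate margins (empty rows or columns) are legal throughout;
  derived cells are forced to zero.
* Brute-force enumeration refuses universes above N = 60 unless the cap
  is raised explicitly; it exists for validation, not production.
* The minimal-move catalogue is a finite truncation (sums of ≤ 3
  distinct transpositions); it is complete for the transitions the
  algorithm uses but is not the full (infinite) move monoid.
* `max_dvalue_reference` is a near-maximal anchor, not a certified
  global maximum; both of its failure directions are benign (less
  pruning, or pruning still bounded by the window-relative cutoff).
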