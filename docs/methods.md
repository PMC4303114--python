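# Methods

This note records the models, conventions and design choices behind the
package, and what the synthetic generators do and do not emulate.

## Dose-matrix combination analysis

### Relative growth and inhibition

Readouts (cell counts or OD) at day 0 and day *n* are converted to
relative growth as `(dayN − day0)_treated / mean(dayN − day0)_ref × 100`.
The denominator is the mean delta across the reference cell's replicates:
the formula divides by a single control quantity, and each treated
replicate keeps its own day-0 reading. For interaction analysis the
reference is the endocrine-backdrop-alone cell (dose 0, 0), which
therefore has inhibition rate 0; an external control delta (e.g. an
estrogen condition run alongside the matrix) can be supplied instead for
display normalization.

Per-cell *mean* growth is computed as the ratio of mean deltas rather
than the mean of per-replicate ratios — mathematically identical, but it
makes the self-normalized reference exactly 100% in floating point, so
the inhibition of the reference cell is exactly 0.

Growth inhibition is `100 − mean growth%`. Negative inhibition
(stimulation above the backdrop) is preserved in the data model; it is
floored at 0 only in the rendered heatmap, whose values are additionally
scaled by the matrix maximum so the hottest cell is exactly 100%. The
scaling requires at least one positive inhibition and is idempotent.
Statistics are always computed on relative-growth replicates, never on
scaled values.

### The Min test

Each combination cell is compared with the two monotherapy cells at the
same doses by one-tailed two-sample t tests (alternative: the combination
grows less, i.e. inhibits more); the Min-test p-value is the maximum of
the two. This is an intersection–union test: the union null "not better
than both single agents" is rejected only if both components reject, so
the test holds level α without multiplicity correction across the two
comparisons. Its least-favorable configuration is combination mean equal
to the better single agent's mean — the `highest_single_agent` mode of
the simulator constructs exactly that for level studies. Because the
p-values are one-tailed, `p_min ≥ 1 − α` indicates the combination is
significantly *worse* than at least one single agent; the default call
thresholds (0.05 enhanced / 0.95 attenuated) are configuration values,
not constants.

Choices worth stating:

* **Pooled-variance (Student) t** is the default — the classical Min-test
  presentation, stable at quadruplicate sample sizes; Welch is available
  via a flag (`welch=True` / `--welch`). The Welch df is computed with
  normalized variance ratios so extreme variance scales cannot underflow.
* **Zero-variance ties**: both groups identical → p = 0.5 (no evidence);
  zero variance with unequal means → p = 0 or 1 by the direction sign.
* **No multiplicity correction across the cells of a matrix** is applied;
  the matrix summary (percent enhanced / attenuated among both-doses-
  positive cells) is descriptive.
* `pairwise_bonferroni` provides the two-sided pooled-t pairwise
  comparisons with Bonferroni adjustment (raw p × number of requested
  comparisons, capped at 1) used for ordinary group contrasts.

### Combination simulator

Monotherapy effects follow Hill curves on the inhibited-fraction scale,
`e(d) = emax·d^h / (ec50^h + d^h)`; the no-interaction baseline for a
combination is Bliss independence (surviving growth fractions multiply).
A signed interaction γ is added on the inhibition scale where both doses
are positive, then clipped to [0, 1]: γ = 0 is the Bliss null, γ > 0
enhancement, γ < 0 attenuation. Note the Bliss null is *stronger* than
the Min test's null — under Bliss with two active drugs the combination
genuinely beats both single agents, so enhanced calls there are power,
not type-I error; level is assessed under `highest_single_agent`.

Replicate noise is i.i.d. Gaussian on the growth-fraction scale
(default SD 0.05, a typical replicate CV for OD-style readouts),
truncated below at 0 by clipping — at the default SD the clipping mass is
negligible. Growth fractions are encoded as day-0/day-n readout pairs
(day 0 = 0.2, backdrop delta = 0.8 arbitrary OD units) so the reading
pipeline sees plate-style data. Defaults mirror the assay design the
package targets: 6×6 dose grids, quadruplicates, one common layout per
matrix including the single-agent rows.

## Gene-signature statistics

`derive_signature` is a deliberately simple gene-level stand-in for
isoform-resolution RNA-seq differential calling: per-gene two-sample
pooled t tests with Benjamini–Hochberg control, selected at FDR < 0.05
and split into up/down by the sign of the group-2 − group-1 mean. Genes
with zero variance in both groups carry no evidence (p set to 1). An
empty result is representable — a null contrast should select nothing —
but an empty signature cannot be scored.

A consequence worth knowing: with ~100 truly differential genes on a
2,000-gene background, BH at 0.05 admits about five false discoveries in
expectation (its threshold is ≈ 0.05·k/m), so exact recovery of an
embedded signature is only the correct expectation on a signature-only
panel or at stricter thresholds; the tests treat it accordingly.

Scoring statistics:

* **Sample t score**: Pearson r between the sample's expression over the
  signature genes and the ±1 up/down pattern, reported as
  `t = r·√(n−2)/√(1−r²)`. Invariant to additive shifts and positive
  rescaling of the sample. Cohort-median centering of genes is available
  (`center_genes=True`) but not the default.
* **Signature similarity**: the same correlation-t between two per-gene
  differential patterns over shared genes, with a two-sided p from
  Student t(n−2). Symmetric in its arguments.
* **Fisher enrichment**: one-sided hypergeometric upper-tail p for
  over-representation, mapped to a signed two-sided z,
  `z = sign(obs − exp)·Φ⁻¹(1 − p/2)`, with z = 0 when the overlap equals
  its expectation or p = 1. Depletion therefore saturates at z = 0 under
  this one-sided convention rather than going negative beyond what the
  half-p mapping allows.
* `|r| = 1` would give infinite t; it is reported as the ±1e6 sentinel
  with a `saturated` flag so tabular output stays finite.

The expression simulator draws per-gene baselines N(8, 2) on the log2
scale with N(0, 0.5) sample noise and shifts the embedded up/down genes
by ±2 in group 2 (defaults: 2,000 genes, 5 + 5 samples, 50 up / 50 down)
— a clean two-group design with independent genes. It does not emulate
gene–gene correlation, library-size effects, count noise, or batch
structure, so passing tests demonstrate the statistics, not robustness to
those real-data features.

## Xenograft endpoints

Volume is `width²·length/2` (mm³). "Tumor size" in the endpoint
definitions is this volume. TTR is the first measurement day with volume
≤ ½ × the day-0 (randomization) volume, TTP the first with ≥ 2×; event
timing uses the first measurement at/after the true crossing with no
interpolation, since tumors are only observed on the measurement grid.
Subjects never crossing within the horizon (default 470 days) are
censored at their last observation or the horizon, whichever is earlier.
An animal harvested early (stop rule at 1,000 mm³) contributes a
truncated series: if doubling occurred by harvest TTP is an event,
otherwise the subject is censored at harvest — this falls out of the
first-crossing rule with no extra flag.

Kaplan–Meier medians use the convention median = first time S(t) ≤ 0.5
(the R `survfit`/lifelines rule), reported "NA" when never reached; the
95% CI comes from inverting the log–log (exponential-Greenwood) band.
Arms are compared with the Gehan generalized Wilcoxon test in its
original conditional-permutation form: pairwise-ordering scores U_i,
statistic W = ΣU over one arm, variance n₁n₂ΣU²/(N(N−1)), W²/Var against
χ²(1). This weights early differences more than the log-rank — sensible
when regression happens early if at all. The Wilcoxon-weighted log-rank
(hypergeometric variance) is asymptotically equivalent but not identical
at small n; the tests cross-check against it at n = 50.

The trajectory simulator is exponential growth/regression with
multiplicative log-normal measurement noise (E[noise] = 1, default CV
0.1), a noise-free day-0 baseline, weekly measurements, and a 470-day
horizon; defaults of 10 subjects/arm and 200 mm³ at randomization match
typical xenograft designs. It does not model growth-rate heterogeneity
between animals, treatment delay, or regrowth after regression.

## Problem sizes and numerical checks

The statistical guarantees are exercised at these sizes, chosen to pin
each property with comfortable Monte-Carlo margins: 1,000 random
replicate pairs for t-test oracle agreement (tolerance 1e-12); 400
least-favorable-null matrices (10,000 combination cells) for the
intersection–union level at α = 0.05 within 3·SE; 200–500 matrices per γ
for the power curve; exhaustive enumeration of all ~24,000 hypergeometric
configurations with universe ≤ 25; 200 replicate datasets for null
signature selection and t-score discrimination. End-to-end pipeline runs
are byte-identical under a fixed seed; the manifest records versions and
thresholds and deliberately contains no timestamps.
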