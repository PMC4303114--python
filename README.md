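# preclin

Statistical machinery for preclinical endocrine-resistance studies in
ER-positive breast cancer models: dose-matrix drug-combination analysis
with the **Min test**, **gene-signature** derivation and scoring, and
**xenograft time-to-event** endpoints. Every stage can be exercised on
built-in synthetic data with known ground truth, so the whole pipeline is
testable without access to any experimental dataset.

## What it computes

**Drug combinations.** Two kinase inhibitors are dosed on a factorial
grid (e.g. 6×6, quadruplicate wells) on top of an endocrine backdrop
(estrogen deprivation, tamoxifen, ...). Raw day-0/day-n readouts become
relative growth against the backdrop-alone cell,

    growth% = (dayN − day0)_treated / mean(dayN − day0)_reference × 100,

and growth inhibition = 100 − mean growth%. Each combination cell (a, b)
is compared with its two matched monotherapies (a, 0) and (0, b) by the
Min test (intersection–union test): two one-tailed pooled-variance t
tests with alternative "combination grows less", and

    p_min = max(p_vs_A, p_vs_B).

`p_min ≤ 0.05` calls the combination **enhanced** (superior to both single
agents); because the p-values are one-tailed, `p_min ≥ 0.95` calls it
**attenuated** (worse than at least one). A matrix is summarized as the
percentage of enhanced/attenuated combination cells. For display the
inhibition surface is scaled by its maximum so the hottest cell is 100%.

**Gene signatures.** A two-group contrast yields an up/down signature by
per-gene t tests with Benjamini–Hochberg control (FDR < 0.05). Samples
are scored by the *t score* — the t statistic of the Pearson correlation
between the sample's expression over the signature genes and the ±1
up/down pattern, `t = r·√(n−2)/√(1−r²)`. Signature-to-signature
similarity is the same correlation-t over shared genes; gene-set
enrichment is a one-sided Fisher exact test reported as a signed two-sided
z score, `z = sign(obs − exp)·Φ⁻¹(1 − p/2)`.

**Xenograft endpoints.** Tumor volume is `width² × length / 2`. Time to
tumor regression (TTR) is the first measurement at or below half the
randomization volume; time to progression (TTP) the first at or above
double; subjects never crossing within the follow-up horizon (default
470 days) are censored. Arms are summarized by Kaplan–Meier (median =
first time S(t) ≤ 0.5, "NA" when never reached; log–log 95% CI) and
compared with the Gehan generalized Wilcoxon test (permutation variance).

## Worked example

```python
import numpy as np
import preclin as pc

# -- combination matrix with a moderate enhancement term
cfg = pc.ComboSimConfig(seed=5, interaction=0.15)
g = pc.growth_matrix(pc.simulate_dose_matrix(cfg))
results = pc.analyze_matrix(g)
s = pc.summarize_matrix(results)
print(f"{s.n_combinations} combinations: "
      f"{s.pct_enhanced:.0f}% enhanced, {s.pct_attenuated:.0f}% attenuated")
r = results[0]
print(f"doseA={r.dose_a}, doseB={r.dose_b}: p_min={r.p_min:.4f} -> {r.call}")
```

```
25 combinations: 100% enhanced, 0% attenuated
doseA=0.1, doseB=0.1: p_min=0.0001 -> enhanced
```

With `interaction=0.15` every combination inhibits more than the Bliss
product of its single agents, so all 25 combination cells reject at the
0.05 level; the first cell's Min-test p is the worse of its two one-tailed
comparisons.

```python
# -- signature derivation and scoring (50 up / 50 down embedded)
sim = pc.simulate_expression(pc.ExprSimConfig(seed=3))
sig = pc.derive_signature(sim.expr, sim.groups, name="PTEN_low")
print(f"signature: {len(sig.up_genes)} up, {len(sig.down_genes)} down")
print(pc.score_samples(sim.expr, sig)["t"].round(2).to_dict())
```

```
signature: 51 up, 47 down
{'WT_1': 0.68, 'WT_2': 0.53, 'WT_3': -0.06, 'WT_4': 0.41, 'WT_5': 0.17,
 'KD_1': 8.91, 'KD_2': 8.72, 'KD_3': 9.43, 'KD_4': 9.66, 'KD_5': 9.05}
```

The t scores separate the signature-bearing group (t ≈ 9) cleanly from
controls (t ≈ 0); the selected sets differ slightly from the embedded
50/50 truth because FDR control at 0.05 tolerates a few false discoveries
at transcriptome scale.

```python
# -- xenograft arms: fast vs slow tumor regression
trajs = pc.simulate_trajectories(pc.TrajSimConfig(
    rate=-np.log(2) / 25, noise_cv=0.1, seed=1, arm="Ful-Dox"))
trajs += pc.simulate_trajectories(pc.TrajSimConfig(
    rate=-np.log(2) / 110, noise_cv=0.1, seed=2, arm="Ful+Dox"))
print(pc.arm_summary(trajs, compare=[("Ful-Dox", "Ful+Dox")]).to_string())
```

```
    arm   n  TR_pct   TTR_median  TP_pct TTP_median    p_TTR  p_TTP
Ful-Dox  10   100.0   28 (21-28)     0.0 NA (NA-NA) 0.000097    1.0
Ful+Dox  10   100.0 105 (77-105)     0.0 NA (NA-NA)      NaN    NaN
```

Both arms regress fully (TR 100%), but the 25-day-half-life arm reaches
median TTR at day 28 versus day 105 for the slow arm — a generalized
Wilcoxon p of about 1e-4 — while TTP is never reached ("NA").

The same stages are available as a CLI: `preclin synth combo|expr|traj`,
`preclin combo normalize|inhibition|heatmap|mintest|run`,
`preclin sig derive|score|similarity|enrich`, `preclin endpoints`.

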