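# kinosim

Synthetic kinome peptide-microarray data generation, and a quantitative
framework for judging variance-stabilization methods by their effect on
differential-phosphorylation detection.

## The problem

Kinome arrays measure the phosphorylation activity of a few hundred
kinase-substrate peptides, each printed as *l* replicate spots (typically
*m* = 297 peptides × *l* = 9 spots).  Benchmarking analysis methods for
such data requires datasets with known ground truth, which the community
does not have.  `kinosim` provides them, for anyone comparing
normalization, variance-stabilization or detection methods on kinome-style
intensity data:

1. **Inter-array replicate synthesis.**  Given a repository *R* of
   measured peptide replicate sets pooled from *n* arrays, a technical
   replicate *Y* of a template *X* is built peptide by peptide.  With
   probability θ a peptide is *perturbed*: its mean background-corrected
   intensity `abc_t` defines fold-change bounds `v = T·abc_t`,
   `w = abc_t/T` (mirrored for `abc_t ≤ 0`), and the first repository
   entry, under a seeded random permutation, whose mean is not
   statistically outside `[w, v]` (one-sided one-sample t-tests at level α)
   replaces the peptide.  Otherwise the first entry whose mean is not
   significantly different from `abc_t` (two-sided one-sample t-test) is
   used.  If no entry qualifies the template's own spots are kept.  *Y*
   carries no differential phosphorylation relative to *X* by the
   fold-change criterion, yet its noise is authentic: every spot value is
   a real (or realistically simulated) measurement, never invented.

2. **Artificial differential phosphorylation.**  Selected peptides of *Y*
   are made differentially phosphorylated by substituting repository
   entries whose mean is statistically *beyond* the bound (`> v` to
   phosphorylate, `< w` to dephosphorylate).  Peptides that cannot be
   pushed further (saturation, small repository) are reported as failed,
   so the seeded set is exact ground truth.

3. **Evaluation.**  For each template/seeded pair, peptides are detected
   with a two-sided paired t-test (spots paired by replicate index) on
   raw, Log2- or glog-transformed values, and scored against the seeded
   truth via the confusion sets TP/FP/TN/FN and

   specificity = ‖TN‖/(‖TN‖+‖FP‖)  sensitivity = ‖TP‖/(‖TP‖+‖FN‖)
   precision = ‖TP‖/(‖TP‖+‖FP‖)  accuracy = (‖TP‖+‖TN‖)/‖N‖

   Methods are compared per measure with a Brown–Forsythe Levene test and
   a paired t-test over pairs.

Since no suitable public kinome dataset is deposited, a **template
simulator** stands in for real input arrays.  It draws spot intensities
from the Rocke–Durbin two-component error model
`Y = α + μ·e^γ + ε`, with right-skewed lognormal-mixture peptide
intensities μ, probe-specific background-correction offsets, and an
explicit background channel — reproducing the features that matter:
heteroscedasticity (spot variance grows with mean), non-normal peptide
mean distributions, and a substantial fraction of *negative*
background-corrected values.

The two normalizations under comparison are **Log2** (positive values →
log2, nonpositive → 0) and a **VSN-style generalized log**
`h_i(x) = arcsinh((x − a_i)/b_i)` with per-array calibration fitted by a
trimmed profile likelihood that minimizes pooled within-peptide variance
across arrays (robust to the seeded differential peptides).

## Worked example

```python
import numpy as np
import kinosim as ks

arrays = ks.simulate_repository(n=48, m=297, l=9, seed=7)
repo = ks.build_repository(arrays)
template = arrays[0]

result = ks.synthesize_replicate(repo, template, ks.SynthesisParams(seed=1))
print(f"perturbed fraction {result.perturbed_fraction:.4f}")
print(f"KS template vs replicate: p = {ks.ks_two_sample(template, result.array):.3f}")

rng = np.random.default_rng(2)
indices = np.sort(rng.choice(297, size=30, replace=False)) + 1
spec = ks.SeedSpec(tuple(map(int, indices)), tuple(map(int, rng.integers(0, 2, 30))))
seeding = ks.seed_phosphorylation(repo, template, result.array, spec, seed=3)
print(f"seeded {len(seeding.seeded)} peptides, {len(seeding.failed)} failed")

for method in ("log2", "vsn_glog"):
    if method == "log2":
        na, nb = ks.log2_transform(template), ks.log2_transform(seeding.array)
    else:
        (na, nb), params = ks.vsn_glog_transform([template, seeding.array])
    detected = ks.detect_differential(na, nb, alpha=0.05)
    rec = ks.performance_measures(
        ks.confusion_sets(seeding.seeded, detected, set(template.peptide_ids)))
    print(f"{method:8s} sensitivity={rec.sensitivity:.3f} "
          f"specificity={rec.specificity:.3f} precision={rec.precision:.3f} "
          f"accuracy={rec.accuracy:.3f}")
```

Output:

```
perturbed fraction 0.0539
KS template vs replicate: p = 1.000
seeded 29 peptides, 1 failed
log2     sensitivity=0.931 specificity=0.948 precision=0.659 accuracy=0.946
vsn_glog sensitivity=1.000 specificity=0.933 precision=0.617 accuracy=0.939
```

Reading the numbers: the replicate routes ≈ θ = 5% of peptides through the
perturbation branch and is distributionally indistinguishable from its
template (KS p = 1.0).  Of the 30 seeding candidates one was already too
extreme to push further, so the ground-truth positive set has 29 peptides.
Log2 misses two seeded peptides that live in the nonpositive intensity
range (where it collapses everything to 0) while the glog transform
recovers all 29 — sensitivity is the measure on which the generalized log
systematically beats Log2, at a small specificity cost from its larger
detection volume at low intensity.

A command-line interface mirrors the library
(`kinosim simulate-templates / synthesize-replicate / seed-phospho /
normalize / detect / score / evaluate`); see `kinosim --help`.

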