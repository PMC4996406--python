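# Methods

This note documents the models, statistical conventions, numerical choices
and known limitations behind `kinosim`.

## Data model

A kinome array is `m` peptides × `l` within-array replicate spots; every
spot stores raw foreground `F` and background `B` fluorescence.  All
statistics operate on background-corrected values `x = F − B`, which may
be negative — negatives are a load-bearing feature of kinome data (low
signal-to-noise spots) and are preserved through every I/O and synthesis
step.  Two arrays are *comparable* iff they share the peptide-id sequence
and `l`; spots are matched across arrays by replicate index, which is the
pairing convention used by the paired t-test in detection.  The canonical
on-disk form is a tab-separated long table
(`array_id, peptide_id, replicate_index, foreground, background`) with
full-precision serialization, so read∘write is the identity; a minimal
GenePix (ATF 1.0) reader covers the common scanner export.

## Template simulator

Spot intensities follow the two-component measurement-error model

    Y = α + δ_j + μ_j · e^γ + ε,
    γ ~ N(0, σ_γ²),  ε ~ N(0, σ_ε²)  (independent, zero mean)

with peptide-level signal `μ_j ≥ 0` from a lognormal mixture with a point
mass at zero (unphosphorylated probes) and a persistent probe-specific
offset `δ_j ~ N(0, σ_probe²)`.  The offset term models probe-dependent
background binding/overcorrection; without it the unphosphorylated
peptides collapse into a tight cluster at `α` and the data lack the
genuine range of negative mean intensities that real arrays show (and on
which the Log2-vs-glog contrast hinges — dephosphorylation within the
negative range is only possible when deeper-negative measurements exist).
The simulator emits raw channels: `B ~ N(bg_mean, bg_sd²)` truncated at 0,
`F = max(Y + B, 0)`, so negativity enters only through `F − B` as on a
physical scanner.

Repositories of `n` arrays share per-peptide anchors (`μ_j`, `δ_j`); each
array re-draws `μ` around its anchor with a log-scale between-array factor
(σ = 0.10), so the same peptide is similar but not identical across
arrays, well inside a 2-fold change.

Defaults (arbitrary fluorescence units): `n=48, m=297, l=9`; mixture
log-means (6.0, 7.8), log-sds (1.0, 0.8), weights (0.55, 0.45),
`zero_fraction = 0.20`, `σ_probe = 250`; `α = 0`, `σ_ε = 60`,
`σ_γ = 0.10`, background 800 ± 80.  These were fixed once, by a
calibration study against the joint set of qualitative properties the
synthetic data must reproduce, and not adjusted afterwards:

* ≥ 5% of spots with negative background-corrected intensity
  (defaults give ≈ 15%);
* Shapiro–Wilk rejects normality of the per-array peptide means for
  essentially every array;
* spot variance increases monotonically with peptide mean
  (heteroscedasticity);
* template-vs-replicate peptide-mean distributions indistinguishable by
  the two-sample KS test in ≥ 90% of pairs;
* the null (unseeded) paired-t detection rate on raw pairs is consistent
  with the nominal α = 0.05 (see "Calibration of the null" below);
* seeded 2-fold changes are detectable on raw data (sensitivity well
  above 0.5).

What the simulator deliberately does **not** model: spatial artifacts,
print-tip and hybridization effects, scanner saturation, and biological
dependence between functionally related peptides.  Passing tests on this
fixture therefore demonstrate correctness of the algorithms and the
claimed distributional properties, not performance on any particular real
dataset.

## Replicate synthesis and seeding

The synthesis procedures follow the literal statistical reading of their
predicates:

* "statistically bigger/less than a bound" — one-sided one-sample t-test
  on the candidate's `l` background-corrected values, level α;
* "not significantly different" — two-sided one-sample t-test against the
  template peptide's mean, level α;
* no multiple-testing correction anywhere (raw α per test, by design);
* zero-variance candidates use exact mean comparison (the t-test's
  limiting behaviour as s → 0).

Candidate scanning draws a fresh seeded random permutation of the whole
repository per peptide and takes the first qualifier; entries are sampled
with replacement (the repository is immutable, one entry may serve many
peptides), and the template's own entries are eligible.  Consequences:
runs are deterministic given seeds, termination is O(|R|) per peptide,
and different seeds may give different — equally valid — outputs.

Edge cases fixed by convention: at `abc_t = 0` the fold-change bounds
collapse (`v = w = 0`) and the perturbation branch falls back to the
equivalence test against 0; the generalized fold change is undefined for
sign-crossing pairs and returns a sentinel (`SIGN_CROSSING`) rather than
a number — the algorithms never need it, since all their decisions are
bound t-tests that are well defined for any signs.  Seeding requests
covering more than 15% of peptides trigger a warning (real kinome data
shows ~10–15% differential probes).

`synthesize_replicate` and `seed_phosphorylation` return result objects
with per-peptide provenance (branch taken, repository source, fallback
flag).  Provenance makes two guarantees testable: no output spot value is
ever invented (each peptide is bit-identical to the template's or a
repository entry's replicate set), and the perturbation-branch routing
frequency equals θ.

### Calibration of the null

An unseeded replicate is "null" by the fold-change criterion, not
spot-by-spot: equivalence-branch peptides are *selected* for similarity
(depressing the paired-t detection rate below α), while
perturbation-branch peptides carry real within-band shifts (raising it).
Under the frozen defaults these opposing effects balance to an overall
detection rate statistically consistent with α = 0.05; the acceptance
suite checks this against the binomial 99% interval over 20 pairs.

## Normalization

**Log2** maps positive values to `log2(x)` and everything `≤ 0` to exactly
0 (zero is grouped with the negatives since `log2(0)` is undefined).  It
is monotone on the positive range and constant on the nonpositive range —
the information-destroying collapse the evaluation quantifies.

**Glog (VSN-style)** applies `h_i(x) = arcsinh((x − a_i)/b_i)` with
per-array parameters; `arcsinh` behaves as `ln(2(x−a)/b)` for large `x`
and linearly near zero, is strictly increasing (injective, negatives map
to finite negatives).  Parameters are fitted by minimizing the trimmed
profile negative log-likelihood

    (N/2)·ln( Σ_j∈K RSS_j / N ) − Σ log h'(x)

where `RSS_j` is the within-peptide residual sum of squares of the
transformed values pooled across arrays (peptide groups are what tie the
arrays to a common scale), `K` keeps the fraction `trim = 0.9` of peptides
with the smallest `RSS_j` (least-trimmed-squares concentration step,
recomputed per sweep, sized to shrug off the ≤ 15% seeded differential
peptides), and the Jacobian term `Σ log h'` fixes the overall scale, which
makes all `(a_i, b_i)` identifiable without anchoring any array.
Optimization is coordinate descent over arrays (Nelder–Mead on
`(a_i, log b_i)` per array), initialized from robust moment estimates
(offset = median of the low-intensity peptides' spots; scale = their
additive sd divided by the bright peptides' relative sd), stopping when
the objective decreases by < 1e-8 or after 100 sweeps (non-convergence is
flagged, results still returned; degenerate constant input is an error).
On data simulated from the error model the fitted scale lands near the
theoretical stabilizing coefficient `σ_ε / sqrt(e^{σ_γ²}(e^{σ_γ²}−1))`
and flattens the within-peptide variance profile across intensity deciles
(max/min ratio < 2 versus ≫ 10 raw).  This is a re-implementation of the
transform *class*; bit-agreement with any released VSN implementation is
out of scope, the acceptance surface is the stabilization property.

The transformers follow the scikit-learn estimator contract on
`(n_arrays, n_spots)` matrices; glog calibration is per-array, so
`transform` applies only to the arrays it was fitted on (use
`fit_transform` on the pair or set being normalized — the evaluation
pipeline fits each template/seeded pair jointly).

## Detection, scoring, method comparison

Detection is a two-sided paired t-test per peptide on the `l`
spot values (paired by replicate index; the alternative of comparing
peptide-level summaries would discard the replicate structure).
Degenerate peptides: all-zero differences are never detected (p := 1),
constant nonzero differences always are (t diverges).  Confusion sets
follow the literal set algebra on (seeded, detected, all); degenerate
ratios are made total and flagged: precision with no detections := 0
(`precision_undefined`), sensitivity with no positives := 1
(`sensitivity_vacuous`), symmetric for specificity.

Method comparison runs, per measure, a Brown–Forsythe Levene test
(median-centered, matching the common R default) and a paired t-test on
per-pair values with df = n′ − 1.  A paired t-test has a single
difference variance, so an equal/unequal-variance switch does not apply
to it; the Levene result is reported alongside for workflow fidelity, and
a Welch two-sample t-test is included as a sensitivity check.  Paired
differences that are constant up to float rounding are reported as a
deterministic difference (flagged) rather than an unstable t statistic.

## Evaluation pipeline and problem sizes

`run_performance_evaluation` executes, per pair q: synthesis → random
seeding (uniform subset of ≤ nd = 30 indices, i.i.d. Bernoulli(0.5)
directions; failed seeds are excluded from the positive set) →
normalization per method (the template serves as both repository member
and control arm) → detection → scoring.  All child seeds spawn
deterministically from one master seed, so the full record table is
reproducible end to end.

Test and acceptance runs use the full-size array geometry (48 × 297 × 9)
with scaled repetition counts chosen for a desk-scale machine: 10 pairs
for construction self-consistency and seeding validity, 200 synthesis
runs for θ calibration, 50 pairs for KS distribution preservation, 20
pairs for null-detection calibration and for the Log2-vs-glog sensitivity
contrast, and ≥ 1000 random instances for the brute-force oracle
equivalence checks.

## Known limitations

* The glog contrast magnitude depends on how much of the intensity mass
  sits in the nonpositive range; the package asserts the *direction* of
  the Log2/glog sensitivity difference, not any particular magnitude,
  because magnitudes are properties of the input dataset.
* The equivalence/bounds predicates treat the template mean as a known
  constant (one-sample tests), the simplest reading of the construction;
  a two-sample variant would widen acceptance bands slightly.
* With very small repositories the fallback branch (copying the template
  peptide) dominates and replicates degenerate towards exact copies.
* GPR support is deliberately minimal (Name + two intensity columns);
  flags, morphology and multi-wavelength columns are ignored.
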