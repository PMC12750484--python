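# Methods

## The scoring instrument

Ten visual features are rated per lobe on ordinal scales in five bronchial
territories (RUL, RML, RLL, LUL, LLL). The canonical registry
(`bronchoscore.default_registry()`) fixes each feature's per-lobe maximum
`L` and aggregation rule:

| feature            | per-lobe scale | aggregation |
|--------------------|---------------:|-------------|
| secretion_color    | 0–8 (Murray)   | maximum     |
| secretion_amount   | 0–3            | threshold   |
| mucosal_edema      | 0–2            | threshold   |
| mucosal_ridging    | 0–2            | threshold   |
| erythema           | 0–2            | threshold   |
| mucosal_pallor     | 0–2            | threshold   |
| viscosity          | 0–2            | threshold   |
| bleeding           | 0–2            | threshold   |
| vascular_drawing   | 0–2            | threshold   |
| mucus_plugging     | 0–1 (binary)   | threshold   |

### The threshold composite

The instrument's rulebook is stated level by level for a 0–2 scale with
five lobes: composite 0 = all lobes 0; 1 = some lobe at 1 but fewer than
three; 2 = three or more lobes at 1, or some lobe at 2 but fewer than
three; 3 = three or more lobes at 2. For mixed vectors the rulebook is
silent about whether "lobes rated 1" includes lobes rated 2. We count
lobes rated **at or above** each level (`n_{≥v}`) and take the maximum
level-wise contribution:

    composite = 0                      if all lobes are 0
    composite = max over v with n_{≥v} ≥ 1 of
                (v + 1 if n_{≥v} > f·n_lobes else v)

with majority fraction `f = 0.5` ("more than 50% of lobes", i.e. ≥ 3 of 5).
This reproduces every enumerated pure case, is monotone in each lobe score,
is permutation-invariant, and generalizes to any scale length (the test
suite proves exhaustive equivalence with a literal case-by-case
transcription of the rulebook over all 3^5 and 4^5 vectors). The composite
range is `0..L+1` for threshold features and `0..L` for the maximum rule.

**Mucus plugging.** The per-lobe score is binary; the published composite
range for it is not available to us. By default we apply the same threshold
rule at `L = 1`, giving composite ∈ {0, 1, 2} (absent / present in a
minority of lobes / present in a majority). `plugging_binary=True`
collapses this to an any-lobe OR for users who want a strictly binary
composite.

**Missing lobes.** The default policy is strict (all five lobes required;
the study design mandated them). A lenient mode aggregates over the lobes
present and rescales the majority cutoff to the observed lobe count.

## Agreement estimation

### Coefficient

Gwet's AC2 with agreement weights `w_kl` (symmetric, unit diagonal). For
`n` subjects, `r_ik` raters assigning subject `i` to category `k`,
`r_i = Σ_k r_ik`, and `r*_ik = Σ_l w_kl r_il`:

    p_a  = (1/n') Σ_{i: r_i≥2} Σ_k r_ik (r*_ik − 1) / (r_i (r_i − 1))
    π_k  = (1/n) Σ_i r_ik / r_i
    p_e  = T_w/(q(q−1)) Σ_k π_k (1 − π_k),   T_w = Σ_kl w_kl
    AC   = (p_a − p_e) / (1 − p_e)

Identity weights give the unweighted AC1 (`T_w = q`). Subjects rated by
fewer than two raters contribute to the prevalences `π_k` but not to
`p_a`.

**Weight family.** Default `ordinal`
(`w_kl = 1 − d(d+1)/(q(q−1))`, `d = |k−l|`), appropriate for ordered
clinical categories where the weight should depend on the number of
categories straddled; `identity`, `linear` and `quadratic` are available
and every report records the family used.

**Category space.** `q` is the feature's full theoretical composite range
(e.g. 0–3 for a 0–2 threshold feature, 0–8 for secretion colour), whether
or not all categories are observed: the weighted chance agreement depends
on `q`, and the category space is a property of the instrument, not of the
sample.

### Variance and confidence intervals

The standard error is the linearized per-subject (influence-function)
estimator: with `γ_i = (n/n')(p_a|i − p_e)/(1 − p_e)` (single-rated
subjects contribute 0) and the chance-side linearization
`p_e|i = T_w/(q(q−1)) Σ_k (r_ik/r_i)(1 − π_k)`,

    γ*_i = γ_i − 2(1 − AC)(p_e|i − p_e)/(1 − p_e)
    var  = (1 − f)/(n(n−1)) Σ_i (γ*_i − AC)²

where `f` is the finite-population sampling fraction, 0 by default
(recordings treated as a sample from an infinite population). The 95% CI is
`AC ± t_{0.975, n−1}·se` and is deliberately **not** truncated to [−1, 1]
(upper bounds slightly above 1 are reported as computed). The exact
estimator variant is cross-validated two ways in the test suite: the SE
must fall within 15% of a leave-one-subject-out jackknife on 80-subject
4-rater studies, and the empirical CI coverage of the population
coefficient over 1000 simulated studies must lie in [93%, 97%]. Both
checks run in `tests/test_acceptance.py`.

### Kappa comparison and interpretation

Cohen's weighted kappa (two raters) is included purely for methodological
comparison: `κ_w = (p_a − p_e)/(1 − p_e)` with `p_e = Σ_kl w_kl p_k+ p_+l`,
SE by the Fleiss–Cohen–Everitt large-sample formula, cross-checked in the
tests against statsmodels. Because kappa's chance term multiplies the
raters' marginals, it collapses on rare findings even when raw agreement is
high; `paradox_fixture()` returns the fixed 2×2 table [[90, 5], [4, 1]]
(percent agreement 0.91, κ ≈ 0.135, AC1 ≈ 0.900) demonstrating why the
prevalence-robust coefficient is the primary estimator here.

Coefficients are interpreted on contiguous half-open Landis–Koch bands:
≤ 0.20 slight/poor, (0.20, 0.40] fair, (0.40, 0.60] moderate,
(0.60, 0.80] substantial, > 0.80 almost perfect. The printed convention
leaves gaps between bands (0.80 vs 0.81); we close them at the lower edge,
consistent with a 0.6 reference line separating "moderate or less" from
"substantial or better". Values above 1 (possible for CI bounds, not for
point estimates) map to almost perfect, negative values to slight/poor.

### Unit of analysis

Default: one composite per recording, with the recording as the sampling
unit (n = 80 in the emulated design). A `per_lobe` option treats every
(recording, lobe) pair as a unit on the raw per-lobe scale (n = 400);
this increases apparent precision by ignoring within-recording correlation
and is offered for sensitivity analysis only.

No multiple-testing adjustment is applied across features; CIs are
per-feature. Strata (CF / non-CF) are analysed independently on their
subject subsets and compared qualitatively only.

## The synthetic-data generator

`simulate_ratings` draws, per subject `i` and feature `f`, a latent
severity `θ_if ~ N(μ_group, σ_severity²)`; per lobe
`x_ifl = θ_if + N(0, σ_lobe²)`; per rater
`y_ifjl = x_ifl + bias_j + N(0, σ_j²)`; the per-lobe score is the number
of cutpoints below `y`. Seeds are explicit and mandatory; there is no
global random state.

The defaults emulate the target study design: 80 subjects with a 62.5% CF
share, four raters — one noisier "student" (bias 0.3, σ 0.8) and three
experts (σ 0.5, 0.5, 0.6 with small biases) — and the ten registry
features. σ_severity = 1 fixes the latent scale; σ_lobe = 0.5 makes lobes
correlated but not identical within a recording. Cutpoints sit about 1–2.2
severity SDs above the non-CF mean, so most per-lobe scores are 0: the
rare-finding, imbalanced-marginal regime that motivates a
prevalence-robust coefficient. Secretion-related features (colour, amount,
viscosity, plugging) get a +1 SD CF shift and mucosal features +0.5 SD, so
CF recordings score systematically higher. These values were chosen once
as a realistic emulation of visual airway scoring; they are conditions,
not tuning knobs.

What the generator does **not** emulate: rater learning or fatigue over
the session, feature-feature correlation beyond the shared group shift
(real secretion features co-vary more strongly), non-Gaussian severity
distributions, and video-quality artefacts. Passing tests therefore show
that the estimators behave correctly under a plausible latent-trait
mechanism, not that the instrument itself is valid on clinical data.

For variance-calibration tests a deliberately simpler configuration is
used (one 0–2 threshold feature, four unbiased raters with equal σ = 0.8,
cutpoints 0.5 and 1.5): a moderate-agreement regime away from the
coefficient boundary, where CI calibration is meaningfully testable.
Problem sizes in the test suite — 80-subject studies for jackknife checks,
1000 replicates for coverage, a single 50 000-subject run for the
population coefficient, 20 replicates per level on the noise grid — were
chosen to keep Monte-Carlo error well below the tolerances being asserted.

## Numerical and design notes

- All estimators are deterministic functions of their inputs; pipeline
  outputs (CSV/JSON/text forest) are byte-stable given the same report.
- Degenerate inputs raise typed errors rather than returning sentinel
  values: no lobes, out-of-range scores, all-single-rated subjects,
  `p_e = 1`, empty cross tables, rater pairs with no co-rated subjects
  (flagged absent, never reported as zero).
- The packaged `reference_weighted_kappa.csv` holds published two-rater
  weighted-kappa values for the six overlapping features of the earlier
  pediatric instrument; they are literature constants for comparison
  output and are never recomputed.
- The packaged `demo_ratings.csv` is a synthetic, hand-written
  three-subject example used in documentation and tests.

## Known limitations

- The composite range for mucus plugging (and the exact published
  supplementary ranges per feature) follow the generalized rule rather
  than a published table; the binary fallback covers the alternative
  reading.
- The linearized variance treats raters as fixed; no rater-population
  inference is attempted.
- Intra-rater (test-retest) reliability is out of scope.
- Agreement coefficients are reliability measures only; nothing here
  validates the instrument against clinical outcomes.
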