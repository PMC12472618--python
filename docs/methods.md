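# Methods

## Apparent permeability

Endpoint (single-timepoint) sampling of a transwell assay under sink
conditions gives

    Papp = (C_R · V_R) / (Δt · A · C_D)   [cm/s],

with C_R the receiver concentration at the end of the incubation (µM),
V_R the receiver volume (mL = cm³), Δt the incubation time (s), A the
monolayer area (cm²) and C_D the donor concentration at t = 0 (µM). The
expression is only dimensionally consistent when the transferred quantity
is expressed as a receiver *concentration* (µM = nmol/mL) multiplied by the
receiver volume; `permscreen` therefore takes C_R as a concentration and
documents that reading in `TransportMeasurement`. The defaults V_R = 1.5 mL,
A = 1.12 cm², Δt = 7200 s are the standard 12-well geometry the reference
dataset was produced with; under that geometry Papp/C_R is one constant for
every analyte, which the suite asserts. No multi-timepoint regression and no
basolateral-to-apical direction are modelled.

### Quality control

QC is advisory — values are flagged, never dropped — matching how screening
labs report rather than censor suspect inserts:

| gate | default | meaning |
|---|---|---|
| atenolol pass | Papp < 0.5 × 10⁻⁶ cm/s | monolayer intact |
| atenolol major | Papp > 1.1 × 10⁻⁶ cm/s | major integrity breach |
| atenolol moderate | closed band between the two | boundary values, and the 1.0–1.1 gap, are moderate |
| mass balance | donor recovery ≥ 0.84 | no unexplained drug loss |
| sink condition | receiver amount ≤ 10% of donor amount | flux ≈ constant |

The aqueous (cell-free) floor of 150 × 10⁻⁶ cm/s is carried in
`QcThresholds` for completeness but no cell-free records ship with the
package. Band boundaries are assigned to the moderate band because the pass
and major criteria are phrased as strict inequalities.

## Ratios and log-scale statistics

Effects are multiplicative, so all inference runs on ln Papp. A group is
summarized by (n, mean of logs, sample sd of logs). "Mean log" is the mean
of log-transformed replicates — the geometric-mean reading — not the log of
the arithmetic mean; the two differ by σ²/2 under a lognormal law.

When only printed summaries (arithmetic mean, SEM, n) are available the
log-scale statistics are reconstructed by lognormal moment matching:

    sd = SEM·√n,  CV = sd/mean,
    sd_log = √ln(1 + CV²),  mean_log = ln(mean) − sd_log²/2.

This inversion is exact for exact lognormal moments (property-tested) but
inherits the rounding of printed tables: comparisons whose interval sits
close to a classification limit can flip relative to an analysis of the raw
replicates. The two wide-margin drug columns of the embedded reference
table (acyclovir, sulpiride) are stable under reconstruction and are pinned
in the acceptance tests; the remaining columns are reported but not treated
as reproducible from summaries alone.

The normalized ratio nPR divides the drug's PR by the co-dosed minoxidil
marker's PR. Replicates are paired **per insert** (the drug and the marker
are co-dosed on the same insert, so per-insert log-ratios
ln Papp_drug − ln Papp_minoxidil are the natural observations); a
group-level normalization (`point_npr`) is also exposed. With an unaffected,
noise-free marker the nPR path reduces exactly to the PR path, which the
suite uses as a pipeline identity.

## Equivalence interval and classification

For treated and control groups with log-scale statistics (n′, m′, s′) and
(n, m, s):

    df = n′ + n − 2
    σ̂² = ((n′−1)s′² + (n−1)s²) / df
    half = t(1 − α/2, df) · √(A · σ̂² · (1/n′ + 1/n))
    CI = exp(m′ − m ∓ half)

with design constant A = 1 (parallel, independent groups — the default) or
0.5 (cross-over arithmetic only; no within-subject modelling). The t
quantile is computed from scipy at the actual df, never hard-coded; for the
default n = 3 + 3 design it is t(0.95, 4) ≈ 2.1318. Unequal group sizes are
supported through the (1/n′ + 1/n) term.

Classification against limits (L, U) = (0.8, 1.25): NE if the CI lies
within [L, U]; R if it extends strictly below L only; E strictly above U
only; NC if beyond both. A bound exactly on a limit counts as within —
"extends below/above" is read as strict crossing. Zero pooled variance
raises by default; `allow_degenerate=True` returns a point interval
(needed for noise-free toy inputs).

## ANOVA / Holm–Šidák screen

The competing detector: per drug, a fixed-effects one-way ANOVA across the
control and all excipient groups, then the 9 excipient-vs-control t
contrasts on the pooled within-group MSE (df = Σ(nᵢ−1)), two-sided, with
Holm–Šidák step-down adjustment (1 − (1−p)^k with a running maximum) at
α = 0.01. Design choices, each genuinely open and settled as follows:

- **Scale:** raw Papp by default. Group comparisons of permeability are
  conventionally run on the measured scale; a log-scale analysis is
  available by transforming replicates first. Marginal calls can differ
  between scales.
- **Family:** the 9 vs-control contrasts per drug, not all 45 pairwise
  comparisons, and no cross-drug adjustment — each drug is its own family.
- **No omnibus gate:** post hoc contrasts run regardless of the omnibus F,
  matching common statistical-software behaviour.

The summary-statistic path (n, mean, sd) is algebraically identical to the
replicate path and is exercised against scipy's replicate ANOVA and
statsmodels' Holm–Šidák implementation in the tests.

## Consensus

A CI call agrees with an ANOVA call as E↔up, R↔down, and NE *or* NC ↔ NS:
both NE and NC are "no called effect" for consensus purposes, since neither
method then asserts a direction. Consensus per excipient is the number of
drugs with agreement; a method always fully agrees with itself.

## Synthetic data and Monte-Carlo studies

`generate_experiment` draws replicate Papp values as
exp(N(ln(geomean · multiplier), sd_log²)) — lognormal noise reflects the
positivity and multiplicative biology of permeability data and matches the
GMR framework — with n = 3 inserts per group by default, a co-dosed
minoxidil marker (control geometric mean constrained to the plausible
0.92–4.58 × 10⁻⁶ cm/s window, default 2 × 10⁻⁶) and an atenolol marker
(geometric mean 0.3 × 10⁻⁶ cm/s, below the 0.5 × 10⁻⁶ integrity gate).
Marker multipliers default to 1 so nPR ≡ PR holds as an identity; an
atenolol multiplier is available to exercise integrity-breach flags.
`default_design()` calibrates control geometric means, log-sds and per-cell
true GMRs to the embedded reference table (reconstructed sd_log values fall
in ≈ 0.03–1.2, mostly 0.15–0.6), since no replicate-level dispersion beyond
SEMs is available.

What the generator does **not** emulate: between-plate or between-day
random effects (no plate structure is modelled — extension point),
analytical quantification error distinct from biological noise, correlation
between drug and marker on the same insert beyond independence, or
transporter-level mechanisms. Passing tests therefore validate the
statistical machinery under its stated model, not the biology of any real
monolayer.

Monte-Carlo problem sizes: coverage and familywise-error studies use 10⁴
simulated experiments (MC standard error ≈ 0.003 on a 90% coverage, ≈ 0.001
on a 1% error rate); the sensitivity grid uses 2 × 10³ families per
(GMR, sd_log) point over GMR ∈ {0.5, 2/3, 1.5, 2} × sd_log ∈
{0.15, 0.3, 0.6}. The vectorised simulation internals are checked
element-by-element against the per-experiment pipeline path on identical
draws, so the fast path cannot drift from the tested implementation.

## Known limitations

- With n = 3 per arm the pooled variance has only 4 df, so the four-way
  classification is a *screen*, not a calibrated test: under a true ratio
  of 1 the CI frequently lands past one limit while inside the other, and
  E/R calls then occur far more often than α. (The exact dual property —
  the CI90 excludes 1 in ≈ 10% of null experiments — does hold and is
  asserted in the suite.) The CI method's higher sensitivity relative to
  the α = 0.01 Holm–Šidák screen partly reflects this permissiveness.
- Reconstruction from rounded printed summaries cannot reproduce
  replicate-level analyses for near-limit comparisons (see above).
- The cross-over design constant is arithmetic only; period and sequence
  effects are out of scope, as are TOST p-values and sample-size planning.
- Log-scale ANOVA requires replicate input; rounded summaries cannot be
  re-scaled exactly.
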