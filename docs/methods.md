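# Methods

## Probability model

The engine computes 10-year probabilities of hip fracture and major
osteoporotic fracture (MOF) as a double-decrement process: fracture and
death compete as exits from a single intact state, first event wins, and
hazards are piecewise constant within each year of age. For year *t* of
follow-up (t = 0…9) at attained age a+t, with fracture hazard h_f and death
hazard h_d,

    P(exit in year t)        = S(t) · (1 − exp(−(h_f + h_d)))
    P(fracture | exit)       = h_f / (h_f + h_d)
    S(t+1)                   = S(t) · exp(−(h_f + h_d))

and the 10-year fracture probability is the sum of the yearly fracture
contributions. A year with zero total hazard contributes nothing and leaves
S unchanged. The symmetric death contributions plus 10-year event-free
survival complete the probability space exactly (`ten_year_decomposition`
returns all three; they sum to 1 to machine precision, and the constant-
hazard closed forms 1 − e^(−10h_f) and h_f/(h_f+h_d) · (1 − e^(−10(h_f+h_d)))
are reproduced to ≥ 10 decimals).

Assumptions: fracture is absorbing over the horizon (no multiple fractures);
no post-fracture excess mortality; mortality is a country-level input
unmodified by the risk profile; hazards do not vary within a year of age.

## Hazard inputs and age bands

Incidence tables store events per 100,000 person-years, mortality per
person-year, in half-open integer age bands [lo, hi) that must be
contiguous per sex and cover at least [50, 90). Unit conversion happens
only in `hazard_at`. Single-year expansion uses the band's constant rate —
no interpolation, matching abridged-life-table practice. An open-ended
final band extends to a hard ceiling of age 100; queries at or beyond the
ceiling (or outside coverage) raise rather than extrapolate.

MOF incidence is imputed as hip incidence × an age/sex-specific MOF:hip
ratio table (the assumption that the fracture-site pattern follows the
Malmö pattern); ratios must be ≥ 1 since MOF includes hip, and the two
tables must share band edges exactly.

## Risk-factor model

Six dichotomous clinical risk factors (prior fragility fracture, parental
hip fracture, current smoking, glucocorticoid use, rheumatoid arthritis,
alcohol ≥ 3 units/day — the standard set excluding secondary osteoporosis,
which is inert once BMD is entered) act multiplicatively on the fracture
hazard, together with a BMD term GR^(−T): the gradient of risk GR > 1 is
the multiplier per SD decrease of femoral-neck T-score, anchored at
multiplier 1 for T = 0 so that no external normative reference data are
needed. BMI is recorded on the profile but applies no multiplier (scenario
grids fix it at 26 kg/m²). Relative risks never touch mortality.

The authentic FRAX calibration is proprietary; the default
`RelativeRiskModel` is therefore a plausible configuration (per-factor
multipliers 1.25–1.9, GR = 1.6), not an estimate of FRAX. The defaults
apply identical multipliers to both outcomes: under the multiplicative
composition, outcome-specific multipliers (e.g. a steeper hip gradient)
can push the adjusted hip hazard above the adjusted MOF hazard at ages
where the MOF:hip ratio nears 1, breaking the superset ordering
P(hip) ≤ P(MOF) for extreme profiles. Equal multipliers preserve that
ordering structurally for any ratio table ≥ 1. Outcome-specific values
remain fully supported configuration (YAML) for users who prefer fidelity
to the published meta-analysis gradients over the strict ordering.

## Surrogate construction and the scenario grid

`build_surrogate` replaces only the mortality table (and label) of a source
model, after checking that the target mortality covers every sex/age span
of the source incidence; fracture epidemiology and relative risks are
shared by reference, so surrogate and source probabilities are identical
iff the mortality tables are value-identical.

The comparison grid crosses all 2⁶ = 64 risk-factor combinations with
8 T-scores (0 to −3.5 SD in 0.5 steps) at BMI 26 — 512 profiles per
(age, sex), ages 50/60/70/80 and both sexes by default. This is an array of
all combinations, not a population simulation: no prevalence weighting is
implied. Profiles carry deterministic ids (age, sex, CRF bitmask, T-score)
so paired comparisons align across models without floating-point joins.

## Comparison statistics

* **Piecewise regression.** Surrogate on reference probabilities (percent
  scale), least squares on the hinge basis {1, x, max(0, x − 40)}; the fit
  is continuous at the knot by construction. If every point lies on one
  side of the knot the hinge is not identifiable: the hinge coefficient is
  fixed at 0 (ordinary simple regression), both slopes are reported equal,
  and the fit is flagged degenerate. The reported r is the Pearson
  correlation of the paired probabilities (identically 1.0 for
  value-identical grids).
* **Percentile differences.** Profiles are ranked by their reference
  probability (ties broken by profile id). Percentile values use linear
  interpolation between closest ranks; the even-count median is the mean of
  the two central order statistics. The surrogate is read at the same
  reference-ranked profiles, so both models are evaluated on the same
  clinical scenarios; the relative difference uses the reference value as
  denominator.
* **Tolerance intervals.** The construction used by the original analyses
  of this kind is not published, so the package uses a documented
  stand-in: a distribution-free two-sided interval over the surrogate
  values of profiles within ±10 ranks of the reference percentile rank,
  taking the innermost symmetric pair of order statistics whose random
  coverage (Beta-distributed) reaches the stated coverage with the stated
  confidence, and falling back to the flagged sample range when the window
  is too small for the 95/95 guarantee — which it always is at the default
  window size, making the default interval the window's range. It is
  reproducible and order-statistic based, but not comparable numerically
  to any particular published interval.

## Burden projection

Expected counts are Σ rate/100,000 × persons over population bands whose
lower edge is ≥ 50 (bands starting below the cut-off are excluded whole);
incidence and population bands must match exactly — no proration. Each
projection year is an independent cross-section under fixed rates (the
"incidence remains stable" assumption); no cohort survival dynamics.
Counts stay real-valued internally; reports round counts to whole
fractures and percent increases half-up to integers, the convention that
reproduces published-style increase figures exactly from their count
tables.

## Synthetic data

Real hip-fracture incidence and adult mortality rise near-exponentially
with age, so generators use Gompertz band rates α·exp(β·(midpoint − 50))
with known parameters. Defaults (a moderate-risk source country): hip
incidence α = 20/10⁵ PY, β = 0.09 (women) and α = 15/10⁵, β = 0.075 (men);
mortality β = 0.095 for both sexes with α = 0.004 (women) and 0.006 (men)
per person-year — levels chosen as plausible for a middle-mortality
country, yielding 10-year probabilities in realistic clinical ranges.
These are fixtures with recoverable parameters, not estimates of any real
registry. The target country differs only in mortality level (+10% women,
+5% men), emulating neighbouring countries of similar life expectancy. The
MOF:hip ratio declines log-linearly from 7.0 at age 50 to 1.3 at 90
(configuration defaults reflecting the qualitative pattern that non-hip
major fractures dominate at younger ages). Population pyramids decline
geometrically with age band and grow geometrically in time, with a small
seeded lognormal perturbation fixed per (sex, band) across years so totals
still grow at exactly the stated rate.

What the synthetic tables do *not* emulate: registry noise, cohort effects,
non-Gompertz curvature at extreme ages, sex-specific growth, migration.
Passing tests therefore demonstrate correctness of the pipeline's
arithmetic and ordering properties, not calibration to any real country.

`simulate_cohort` is the engine's independent stochastic check: yearly
exits are drawn against the total hazard with a Bernoulli cause split
h_f/(h_f+h_d) — exactly the engine's decomposition — so the analytic
probability and the simulated fraction differ only by binomial noise. The
test suite and acceptance script verify agreement within 3 binomial
standard errors at n = 100,000 over 20 randomised hazard/profile
configurations (sizes chosen to make the check sharp while keeping the
default run fast).

## Numerical and design notes

* All randomness flows through explicitly passed seeds
  (`numpy.random.default_rng`); no global state. Repeated CLI runs with the
  same config and seed produce byte-identical CSVs (manifests carry
  timestamps and are not primary outputs).
* Exact equality is asserted only where the arithmetic is exact (identity
  comparisons, determinism); everything stochastic is tested against
  closed forms or the cohort oracle with explicit error bounds.
* Degenerate inputs have pinned behaviours rather than errors where a
  sensible value exists: zero total hazard years, one-sided piecewise
  fits, constant tolerance-interval samples, zero reference medians
  (difference reported as 0 when both are 0, infinite otherwise).
* Known limitations: no secondary-osteoporosis flag, no BMI effect, no
  interaction structure between risk factors, no post-fracture mortality,
  and absolute probabilities are only as good as the configured
  relative-risk values — the package's purpose is surrogate construction
  and comparison, not reproduction of authentic FRAX outputs.
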