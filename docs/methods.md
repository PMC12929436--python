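# Methods

## The photoperiod-response model

Barley is a long-day plant: lengthening days accelerate flowering up to a
genotype-specific saturation point.  `photothermal` models the mean thermal
time from emergence to heading (awn emergence, BBCH 49) of genotype *g* at
photoperiod *P* (hours of light per 24 h day) as a continuous linear-plateau
("hinge") function

    mu_g(P) = I_g + S_g * max(0, T_g − P)

with three interpretable parameters:

| parameter | units | meaning | default bounds |
|---|---|---|---|
| `intrinsic_earliness` (I) | °Cd | plateau: minimum flowering time once the photoperiod requirement is saturated | > 0 |
| `sensitivity` (S) | °Cd per h | slope magnitude of the declining arm | ≥ 0 |
| `threshold` (T) | h | breakpoint beyond which longer days no longer accelerate flowering | [12, 24] |
| `sigma` | °Cd | residual SD of individual plants around the genotype mean | ≥ 0 |

Individual plants are modelled as Gaussian around `mu_g(P)`.  The S ≥ 0
constraint encodes the long-day biology (flowering never slows with longer
days); it makes the predicted mean non-increasing in P and constant above T
by construction.

Thermal time is accumulated as growing degree-days above a 0 °C base:
the sum over calendar days of `max(0, daily mean temperature − base)`.
Partial first/last days of a window use the mean of the in-window readings.
This daily-mean convention is the field's standard; note it is additive
across midnight-aligned window splits only — a day split mid-way contributes
the mean of each part rather than the whole-day mean.  A `per_reading`
integration mode (each reading weighted by its cadence) is available when
exact additivity at arbitrary split points matters; it is not the default.

## Estimation

Fitting is deterministic maximum likelihood.  For any fixed threshold the
model is linear in (I, S), so the profile is solved in closed form
(`scipy.optimize.lsq_linear` with the S ≥ 0 bound) and the threshold is
optimised by a multi-start scan on a 0.05 h grid over its bounds followed
by bounded Brent refinement around the best node.  Estimates are invariant
to record order and reproducible bit-for-bit.

Two degenerate geometries are resolved explicitly rather than left to the
optimiser:

* **Zero fitted slope.**  If the non-negativity bound clamps S to 0 the
  likelihood is flat in T; the threshold is reported at its lower bound and
  flagged non-identifiable.
* **Threshold below the second tested photoperiod.**  With observations at
  photoperiods p1 < p2 < …, any T in (p1, p2] spans the same column space:
  only one photoperiod sits on the declining arm, and (S, T) trade off
  along an RSS-equivalent ridge.  The naive curvature-based covariance is
  singular there and produces misleading standard errors.  Such fits are
  canonicalised to T = p2 (identical RSS), where S becomes the identified
  effective slope of the first segment; the threshold is flagged
  non-identifiable.  This is the model-level counterpart of the
  experimental fact that a response already saturated at the shortest
  tested daylength cannot be distinguished from insensitivity without data
  at shorter days.

Standard errors come from the Gauss–Newton approximation at the optimum
(response Jacobian [1, max(0, T − P), S·1(P < T)]), with residual variance
on n − 3 degrees of freedom per genotype (n − 1 for the flat variant);
central 95% intervals are ± 1.96 SE, with the sensitivity interval floored
at 0.  In a recovery study at σ = 10 °Cd and 50 plants per photoperiod,
all three point estimates fall within 3 reported SEs of truth in ≈ 98–99%
of simulated experiments.

## Model variants and selection

A `ModelVariant` declares per-parameter sharing across genotypes:
`full` (per-genotype I, S, T), `flat` (S fixed at zero; T dropped from the
parameter vector), `sharedT` (one breakpoint common to all genotypes,
per-genotype I and S).  A per-genotype threshold is only supported together
with per-genotype I and S (the problem is then separable by genotype);
shared-threshold variants profile a single scalar T with a pooled linear
solve.  Residual SD is per-genotype by default with a shared-σ switch.

Variants fitted on the same records are ranked by an information
criterion; ties break by fewer parameters, then variant name.  Both BIC
and small-sample-corrected AICc are computed; **BIC is the default
ranking criterion** because variant selection here is a consistency
problem — deciding whether the hinge terms exist at all — and AIC-family
criteria remain liberal at any sample size when the superfluous
alternative adds a searched breakpoint plus a boundary-constrained slope.
In calibration runs (100 simulated experiments per direction, 100 plants
each) BIC selected the generating variant 100/100 under both flat and
bi-linear truth; AICc was 95/100 under flat truth.  AICc remains available
via `FitConfig(criterion="aicc")`; variants are only compared within one
criterion.

No sampling-based posterior backend is provided: the deterministic ML path
is the package's estimation contract, and its interval semantics are
frequentist throughout.

## Classification and photoperiod recommendation

`classify_response` labels each genotype over the tested range
(P_min, P_max):

* **responsive** — the 95% sensitivity interval lies entirely above a
  near-zero band (default 2 °Cd/h, configurable) and the threshold
  estimate exceeds P_min;
* **flat_saturated** — the fitted curve is constant over the tested range:
  slope indistinguishable from zero, exactly zero, or threshold at/below
  P_min.  The label deliberately conflates "insensitive" with "threshold
  below the tested range": the two are not separable without shorter-day
  data, and every flat classification carries that caveat in its note;
* **indeterminate** — everything else (typically a sensitivity interval
  straddling the band).

The pipeline classifies each genotype on its per-genotype
information-criterion winner (`flat` vs `full`), not on the raw full-model
fit: on truly flat data the full model's clamped-slope interval can be
wide enough to land in *indeterminate*, whereas selection resolves the
question the classification is actually asking.

`recommend_photoperiod` converts the class into a speed-breeding
photoperiod: responsive genotypes get the **tested photoperiod nearest to
the estimated threshold** (ties snap upward; estimates above the ladder
clamp to the top rung with a warning); flat-saturated genotypes get the
shortest tested photoperiod; indeterminate genotypes get a conservative
configurable default (22 h) with a warning.  Nearest-rung rather than
strict round-up is deliberate: the threshold estimator is unbiased around
the true breakpoint, so demanding a tested rung at or above the estimate
would jump to the next rung in half of replicate experiments even when the
true breakpoint sits exactly on a rung.

## Treatment contrasts

`photoperiod_contrasts` runs two-sided two-sample Student's t-tests
(pooled variance; Welch via `equal_var=False`) on plant-level thermal
times per genotype for requested photoperiod pairs, defaulting to
16 vs 20 h and 20 vs 22 h.  Repetitions are pooled within genotype ×
photoperiod; no multiplicity adjustment is applied.  Arms with fewer than
two observations are reported as skipped with a reason.  Calibration under
flat truth (1,000 simulated genotypes, n = 10/arm, α = 0.05) gives
empirical type-I rates around 0.04–0.07; under a responsive genotype
(S = 50 °Cd/h, T = 20 h, σ = 10 °Cd) the 16 v 20 contrast is essentially
always significant while 20 v 22 rejects at the nominal level, since both
arms sit on the plateau.

## qPCR analysis

Technical replicates collapse to one Ct per biological replicate (mean of
detected wells; a bio rep with no detected well is undetected, one of two
detected wells sets a partial-detection flag).  Relative expression uses
the delta-Ct method against a reference gene measured on the same
(genotype, photoperiod, ZT, bio rep): `rel_expr = 2^−(Ct_target −
Ct_ref)`, with *HvTubA* as the default reference.  No calibrator sample
(ΔΔCt) and no primer-efficiency correction are applied.  Group
comparisons are two-sided t-tests on log2 relative expression
(equivalently −ΔCt), the scale on which qPCR noise is closest to
homoscedastic.  Cells with fewer than two detected biological replicates
in either group are flagged untestable rather than dropped.  Adding a
constant to every Ct (target and reference alike) leaves relative
expression exactly unchanged.

## Energy ledger

The lighting model is linear: a fixture of power W kW run h hours/day
saves `W · Δh · days` kWh/yr when the photoperiod drops by Δh.  Reference
assumptions: 0.65 kW LED fixture covering 8 sq ft, 22 h/day baseline,
£0.22/kWh.  Two operating conventions coexist deliberately and are never
mixed: a 365-day year for annual per-fixture savings (one hour cut →
0.65 × 365 = 237.25 kWh/yr) and 3,000 h/yr × 15 years for lifetime
bookkeeping (29,250 kWh).  Per-quantity rounding is fixed so printed
figures are bit-reproducible: the per-hour percentage truncates (not
rounds) to two decimals (100/22 → 4.54), percentage reductions round
half-up to integers (22→20 h: 9%; 22→16 h: 27%), kWh report half-up to
the nearest unit (474.5 → 475), facility costs report to the nearest
£1,000.  Facility scaling uses the exact (possibly fractional) ratio of
facility area to fixture coverage: 10,000 sq ft at 22→20 h and £0.22/kWh
gives £130,487.50/yr, reported £130,000.  The 22→16 h case gives
£391,462.50/yr; the commonly quoted ≈£392,000 is not reproducible from
these inputs and the report annotates the derived value instead of
matching it.

## Synthetic data

The generator reproduces the reference experiment's statistical structure:
7 genotypes × 5 photoperiods (16/18/20/22/24 h) × 5 replicates × 2
repetitions (350 plants) at a constant 20 °C, with plant thermal time
drawn Gaussian around the bi-linear genotype mean and truncated below at
1 °Cd.  An optional additive repetition offset (default 0) represents a
between-run (year) effect.  The shipped per-genotype parameters are an
illustrative fixture, not measured values: recessive *ppd-H1* lines
responsive with T = 20 h (S = 50–55 °Cd/h), dominant *Ppd-H1* lines flat,
wild *ELF3* lowering I by ~40–80 °Cd, *PhyC-e* halving S, the *elf3*
mutant flat and earliest, all with σ = 12 °Cd (no residual variance is
published for the real experiment; 12 °Cd is ~2% of a typical 600 °Cd
heading time).  The temperature generator emits Normal(mean, sd²)
readings at 30-min cadence; the Ct generator draws nested biological
(SD 0.3 cycles) and technical (SD 0.15 cycles) components with per-well
dropout probabilities, including 50% dropout cells that mimic transcripts
falling below the detection floor.

What the generator does *not* emulate: block/spatial effects within
tents (the block column exists but no block effect is drawn), light
intensity and spectrum, photoperiod × temperature interaction, outliers
and curation artefacts, and day/night temperature cycling.  Passing tests
therefore demonstrate correctness of the estimation and decision machinery
under the stated noise model, not robustness to those real-data features.

## Numerical and engineering choices

* Threshold grid step 0.05 h with Brent refinement to xatol 1e-6;
  unconstrained least squares first, bounded BVLS only on constraint
  violation.
* Degenerate identical samples in t-tests (zero variance in both arms,
  equal means) report t = 0, p = 1.
* CSV files are comma-separated UTF-8 with a mandatory header and a
  `#schema=photothermal-v1` first line; readers validate schemas and
  report row-level errors with file line numbers.
* Temperature-log gaps larger than twice the cadence raise a
  `ThermalGapWarning`; accumulation proceeds assuming linear coverage.
* All randomness flows through `numpy.random.default_rng(seed)`; the
  pipeline's outputs are byte-identical for identical config + seed (the
  report echoes the config without the output directory for exactly this
  reason).
* Simulation sizes in the test-suite and acceptance studies (200 recovery
  seeds at 250 plants each, 100 selection seeds per direction at 100
  plants, 1,000 type-I genotypes, 20 oracle instances) were chosen to
  bound Monte-Carlo error well below the decision margins they feed.

## Known limitations

* Thresholds below 16 h are not estimable from a 16–24 h ladder; the
  flat/saturated ambiguity is surfaced, not resolved.
* The shared-threshold variant does not apply the ridge canonicalisation
  (pooling across genotypes makes the degenerate layout unlikely, but a
  pathological pooled dataset could still hit it).
* Uncertainty for the threshold near a data photoperiod relies on a
  one-sided Jacobian convention (P < T); profile-likelihood intervals
  would be more faithful very close to the kink.
* The energy model covers lighting only — no HVAC co-savings, tariff
  structure, or fixture-degradation effects.
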