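# Methods

## Model

All three models are population-threshold models of germination timing.
The lot-level assumption is a normal distribution of seed base water
potentials, ψ_b ~ Normal(Ψ_b(50), σ_ψb), with all other parameters shared
across seeds:

- **Thermal time.** At sub-optimal temperatures germination rate rises
  linearly with temperature above the base T_b: (T − T_b)·t_g = θ_T1.
  Above the optimum it falls linearly toward the ceiling T_c:
  (T_c − T)·t_g = θ_T2.  (The supra-optimal constant uses the ceiling
  span T_c − T; both branches share one code path up to sign.)
- **Hydrotime.** At fixed temperature, (Ψ − ψ_b)·t_g = θ_H.
- **Hydrothermal time.** For T_b < T ≤ T_o,
  (Ψ − ψ_b)(T − T_b)·t_g = θ_HT, giving the probit-linear surface
  probit(g) = [Ψ − θ_HT/((T − T_b)t) − Ψ_b(50)]/σ_ψb.
  Above T_o the optional supra-optimal extension shifts the median
  threshold linearly, Ψ_b(50)(T) = Ψ_b(50) + k_T·(T − T_o), and
  accumulates thermal time at the optimum span (T_o − T_b); it is active
  only when both T_o and k_T are supplied.

probit(·) is Φ⁻¹, the standard normal quantile, with no +5 offset (the
modern convention).

Assumptions worth keeping in mind: only ψ_b varies between seeds (no
seed-to-seed variation in θ), thresholds are constant in time (no
dormancy release or priming memory), and germination fraction is always
relative to seeds sown — no viability correction.

## Estimation

**Percentile extraction.** Germination times t(g) are read off each
treatment's cumulative-fraction curve by linear interpolation between
observations (and between (0, 0) and the first observation), with
earliest-time tie-breaking on flat segments.  Replicate dishes are pooled
by summing counts (weighting dishes by seeds sown) before extraction; a
per-dish mode exists for dispersion work.  The default percentile set is
the deciles 0.1–0.9 intersected with what each treatment actually
reached: one demonstrated percentile (the 50th) per treatment is too few
to identify a probit line, and multiple percentiles per treatment is the
standard repeated-probit practice.  Fractions of exactly 0 or 1 never
enter probit space.

**Probit regression.** Ordinary least squares of Φ⁻¹(g) on the threshold
coordinate x, unweighted (a seed-count weighting option exists but is off
by default).  Reported per fit: slope, intercept, R², residual standard
error, F (= t² for one predictor), the slope t statistic, its two-sided
p-value, and the derived Ψ_b(50) = −intercept/slope, σ_ψb = 1/slope.  No
multiple-testing correction is applied: each fit is reported as a single
regression.

**θ search.** Coarse log-spaced grid of 64 candidates spanning 1–10⁵ in
natural units, followed by golden-section refinement in the bracket
around the best candidate to relative tolerance 10⁻⁴; ties break toward
smaller θ.  The refined optimum is kept only if it beats the grid best,
so the winner's R² dominates every grid candidate by construction.  Fits
are fully deterministic: identical data and grid give bit-identical
output.

**Cardinal temperatures.** GR(50) = 1/t(50) per temperature at one Ψ;
temperatures at or below the rate-maximizing temperature form the
sub-optimal branch and those at or above it the supra-optimal branch (the
peak belongs to both).  T_b and T_c are the x-intercepts of the two OLS
lines, T_o their intersection, θ_T1 = 1/slope_sub, θ_T2 = −1/slope_supra.
A branch with fewer than two points is reported absent and flagged rather
than extrapolated.

**HTT fit.** Treatments above T_o are excluded from the core fit (the
model is defined at T ≤ T_o); T_o defaults to the GR50-maximizing
temperature at the least-negative Ψ present.  With T_b fixed the search
is one-dimensional in θ_HT; with T_b free, a 30-point grid of T_b
candidates below the coldest treatment is scanned (each with the inner
θ_HT search) and the best pair refined by golden section on T_b.  k_T is
estimated afterwards, if requested, by back-solving
Ψ_b(50)(T) = Ψ − θ_HT/((T_o−T_b)t_g) − σ_ψb·Φ⁻¹(g) per supra-optimal
observation, averaging per temperature, and regressing on T − T_o.

## Germination indices

From daily incremental counts d_j (seeds newly germinated on day j, from
a daily schedule or a 24 h resampling of the step function), seeds sown
N_t, and assay length D days:

| index | formula | unit |
|---|---|---|
| G% | 100·Σd_j/N_t | % |
| GE | Σ d_j/day_j | seeds/day, summed |
| MGT | Σ d_j·day_j / Σ d_j | days |
| MGR | 1/MGT | day⁻¹ |
| GI | Σ (D − day_j + 1)·d_j | weighted count |
| GRI | Σ (100·d_j/N_t)/day_j | %/day, summed |
| TGI | Σ_j cumG%_j / D | % |
| SVI-I | seedling length (cm) × G% | cm·% |
| SVI-II | seedling dry weight (mg) × G% | mg·% |
| MMC | (FW − DW)/DW | — |

Conventions that were genuinely open and how they were settled:

- **GI weights** generalize the classical 10-day form (10·n1 + 9·n2 + … +
  1·n10) to W_j = D − j + 1 for any assay length.
- **TGI** is ambiguous between cumulative and incremental daily
  percentages; the cumulative reading (mean of the cumulative daily
  germination percentages — the common Timson convention) is the default,
  and the incremental reading, which collapses to G%/D, is available as
  `mode="incremental"`.  Note the cumulative TGI is *not* invariant to
  trailing zero-germination days (each appended day adds another copy of
  the final percentage to the mean); GE and GRI are invariant.
- **MGT/MGR with zero germination** are undefined, reported as absent
  (empty CSV fields), never as 0.
- Reported precision follows the field's tables: percentages to 2
  decimals, rates to 3, θ constants to 2, Ψ_b(50)/σ_ψb to 2.

## Synthetic experiments

`simulate_experiment` draws each seed's ψ_b from
Normal(Ψ_b(50), σ_ψb) and germinates it at
t_g = θ_HT/((Ψ − ψ_b)(T − T_b)) when Ψ > ψ_b and T_b < T (supra-optimal
shift applied when T_o and k_T are set); otherwise never.  Observation is
interval-censored by the scoring schedule — the recorded data are counts
at scheduled times only, exactly as in daily radicle scoring; exact event
times exist only in optional truth-record sidecars used for diagnostics
and never read by fitting.  Seeds failing a Bernoulli(viability) draw are
non-viable and never germinate; they are tracked separately from viable
seeds whose ψ_b exceeds the treatment Ψ, although both produce the same
observable.

The default design is 6 temperatures (15–40 °C) × 5 water potentials
(0 to −1.2 MPa) × 3 dishes × 10 seeds with daily scoring for 14 days — the
layout of the lentil osmotic-stress assay this package was built around,
where treatments are imposed with PEG-6000 and scored after 1 mm radicle
emergence.  The default truth parameters used throughout the tests
(θ_HT = 1500 MPa·°C·h, T_b = 10 °C, Ψ_b(50) = −1.2 MPa, σ_ψb = 0.19 MPa)
are of the magnitude such assays report.

What the generator does *not* emulate: spatial or dish effects beyond
independent sampling, seed-to-seed variation in θ_HT, dormancy dynamics,
counting error, or deviations from the normal-threshold law itself.
Passing recovery tests therefore demonstrates that the fitting pipeline
inverts the model correctly under its own assumptions — not that real
seed lots obey the model.

Randomness uses numpy's default PCG64 generator, seeded explicitly; every
CLI run logs and records its seed.  Reproducibility across library
versions is by tolerance, not bit-exactness.

## Numerical choices and verification sizes

- Interval censoring biases t(g) interpolation: with daily scoring the
  cumulative curve rises steeply across single intervals, and the
  resulting Ψ_b(50) bias (~0.05 MPa at the default truth) cannot be
  removed by more seeds.  Noise-free recovery checks therefore use a
  2-hourly schedule, where the interpolation error is negligible, and the
  study-scale checks keep daily scoring deliberately.
- Recovery checks run at 10⁴ seeds/dish (noise-free regime, one dish per
  treatment) and at the study scale (10 seeds × 3 dishes, 20 seeded
  replications); the simulator-law checks use 10⁴ seeds with a
  geometric schedule out to 4×10⁴ h so the germinated fraction approaches
  its asymptote Φ((Ψ−Ψ_b(50))/σ_ψb) even near the threshold.
- Degenerate inputs: zero-germination dishes are legal, retained for
  indices (G% = 0), and excluded from probit fitting with a logged
  reason.  σ_ψb → 0 makes the simulator a point mass (all seeds in one
  scoring interval).  A design entirely below threshold yields all-zero
  counts and a warning, not an error.
- Time is hours everywhere internally; readers accept a `time_unit`
  declaration (`hours`|`days`) and convert days → hours ×24 on ingest.

## Known limitations

- The HT/HTT fits assume the percentile observations are independent in
  the probit OLS, which interval censoring and shared dishes violate;
  reported standard errors are therefore descriptive, as is conventional
  for repeated-probit germination analysis, not strictly inferential.
- The supra-optimal k_T extension is linear by assumption and estimated
  only from back-solved medians; with one supra-optimal temperature it is
  reported absent.
- Cardinal-temperature estimates extrapolate regression lines to their
  x-intercepts; with few temperatures per branch the intercepts inherit
  the full leverage of the extreme points.
- No dormancy, after-ripening, or priming extensions; no survival-model
  alternatives to the probit link.
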