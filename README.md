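# germtime

Population-threshold modelling of seed germination time courses: the
thermal-time (TT), hydrotime (HT) and hydrothermal-time (HTT) models with
probit-based parameter estimation, the standard suite of germination and
seedling-vigor indices, and a Monte-Carlo generator of germination
experiments for validating the whole fitting pipeline by parameter
recovery.

It is written for seed ecophysiologists analysing dish-level germination
assays — cumulative counts of germinated seeds scored over time across
temperature (T, °C) and osmotic water potential (Ψ, MPa, e.g. imposed with
PEG-6000) treatments.

## The models

Threshold models assume each seed *i* in a lot carries a base water
potential ψ<sub>b,i</sub> ~ Normal(Ψ<sub>b</sub>(50), σ<sub>ψb</sub>)
below which it cannot germinate, while the time constants are shared by
the lot.  Seed *i* germinates when its accumulated driving time reaches
the lot constant:

- sub-optimal thermal time: θ<sub>T1</sub> = (T − T<sub>b</sub>)·t
- supra-optimal thermal time: θ<sub>T2</sub> = (T<sub>c</sub> − T)·t
- hydrotime (fixed T): θ<sub>H</sub> = (Ψ − ψ<sub>b</sub>)·t
- hydrothermal time (T<sub>b</sub> < T ≤ T<sub>o</sub>):
  θ<sub>HT</sub> = (Ψ − ψ<sub>b</sub>)(T − T<sub>b</sub>)·t

With a normal ψ<sub>b</sub> distribution the germinated fraction g at time
t is probit-linear:

    probit(g) = [ Ψ − θ_HT / ((T − T_b)·t) − Ψ_b(50) ] / σ_ψb

Fitting inverts this by *repeated probit regression*: germination times
t(g) for a set of percentiles are extracted from each treatment by linear
interpolation of the cumulative fraction; for each candidate θ the
observations are mapped onto the threshold axis x = Ψ − θ/((T−T<sub>b</sub>)t)
and probit(g) is regressed on x; the θ maximizing R² wins (coarse
log-spaced grid, then golden-section refinement).  Ψ<sub>b</sub>(50) and
σ<sub>ψb</sub> follow from the winning line (−intercept/slope and
1/slope).  Cardinal temperatures (T<sub>b</sub>, T<sub>o</sub>,
T<sub>c</sub>) come from the classical two-branch regression of
GR(50) = 1/t(50) on temperature.

The germination indices (G%, GE, MGT, MGR, GI, GRI, TGI, SVI-I, SVI-II,
MMC) are the standard closed forms from daily counts and seedling
measurements; see `docs/methods.md` for each formula and convention.

## Worked example

Simulate an experiment under a known hydrothermal law, then refit it:

```python
import germtime as gt

truth = gt.HydrothermalParams(theta_HT=1500.0, Tb=10.0,
                              psi_b50=-1.2, sigma_psib=0.19)
design = gt.SimulationDesign(rng_seed=1)   # 6 T × 5 Ψ × 3 dishes × 10 seeds, daily
data = gt.simulate_experiment(truth, design)

params, fit = gt.fit_htt(data, Tb=10.0)
print(f"theta_HT = {params.theta_HT:.1f} MPa·°C·h")
print(f"psi_b50  = {params.psi_b50:.3f} MPa")
print(f"sigma    = {params.sigma_psib:.3f} MPa   R2 = {fit.r2:.3f}")
```

Output:

```
theta_HT = 1422.6 MPa·°C·h
psi_b50  = -1.167 MPa
sigma    = 0.260 MPa   R2 = 0.831
```

With only 30 seeds per treatment the estimates scatter around the truth
(θ<sub>HT</sub> = 1500, Ψ<sub>b</sub>(50) = −1.2, σ = 0.19); at 10⁴ seeds
per dish the same pipeline recovers them to three figures (see the
acceptance script below).  The same analysis runs from the shell:

```sh
germtime simulate --params truth.json --seed 1 --out data.csv
germtime fit-htt  --input data.csv --tb 10 --out fit.json
germtime indices  --input data.csv --out indices.csv
germtime report   --input data.csv --tb 10 --out-dir results/
```

`report` writes the three standard tables: per-treatment time constants,
per-temperature hydrotime fits (Ψ<sub>b</sub>(50), σ<sub>ψb</sub>, R², SE,
F, t, significance), and the global HTT parameter set with cardinal
temperatures.  Every run logs skipped dishes and unreachable percentiles
to stderr and writes a manifest (inputs, hashes, seed, versions)
sufficient to re-execute it.

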