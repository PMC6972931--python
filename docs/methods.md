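# Methods

## The kinetic model

The package models a closed spectrophotometric assay of an amidohydrolase
acting on N4-acylated cytosine/cytidine substrates under the scheme

```
S + E <-> ES -> E + P
    E + P <-> E_inh
```

i.e. classical Michaelis–Menten turnover with *competitive* product
inhibition: the co-product binds free enzyme and sequesters it as an
inactive complex. The scheme is implemented literally — the product binds
only free enzyme (competitive), not the ES complex (which would be mixed
inhibition). Under the quasi-steady-state approximation (QSSA) the rate is

```
v = kcat · E0 · S / (Km · (1 + P/Ki) + S)
```

with `Ki = None` meaning no product inhibition (`Ki → ∞`, the P-term
vanishes). The QSSA requires `E0 ≪ S0`; a warning fires when
`E0 > 0.01·S0`. Free-substrate depletion by ES binding is neglected, which
is appropriate for catalytic assay conditions (nanomolar enzyme, 0.1–0.5 mM
substrate).

For a closed assay (`P = S0 − S`) the rate law integrates to

```
alpha·ln(S0/S) + beta·(S0 − S) = Vmax·t
alpha = Km·(1 + S0/Ki),  beta = 1 − Km/Ki,  Vmax = kcat·E0
```

whose explicit solution is `S(t) = (alpha/beta)·W0(x)` with
`x = (beta·S0/alpha)·exp((beta·S0 − Vmax·t)/alpha)` on the principal
Lambert-W branch (the Schnell–Mendoza solution when `beta = 1`), and exact
exponential decay `S0·exp(−Vmax·t/(Km+S0))` at the degenerate point
`Ki = Km` (`beta = 0`).

### Numerical choices

- **Lambert-W branch handling.** Only the principal branch `W0` is used.
  For `beta > 0` the W argument can overflow `exp`; the implementation then
  solves `w + ln w = ln x` by Newton iteration in log space. For `beta < 0`
  the argument is analytically confined to `(−1/e, 0]` for `t ≥ 0`; a
  floating-point undershoot below `−1/e` raises an explicit
  `BranchDomainError` rather than returning a wrong number, and
  `substrate_timecourse` then falls back to monotone bisection (Brent) on
  the integrated law, which is valid everywhere.
- **ODE path.** `simulate_progress_qssa` integrates `dS/dt = −v` with
  adaptive LSODA at `rtol 1e-10`, `atol 1e-14·S0` by default. The closed
  form and the ODE are two independent routes to the same trajectory and
  the test suite holds them to `1e-9·S0` agreement (at `rtol 1e-12` for the
  sweep); the fitting objective uses the closed form with the bisection
  fallback because it is exact, branch-safe, and orders of magnitude
  faster than per-iteration ODE solves.
- **Mass-action variant.** The full five-species ODE system is provided as
  a validation mode. The macroscopic constants determine only the ratios
  `Km = (k₋₁+k₂)/k₁`, `kcat = k₂`, `Ki = k₋₃/k₃`; absolute binding
  constants are user-supplied (a diffusion-limited placeholder
  `k₁ = k₃ = 1e7 M⁻¹s⁻¹` is used in the tests). Note that the conserved
  substrate moiety is `S + P + ES + E_inh` — the inhibited complex carries
  a product molecule.

## Signal model and inversion

A single-wavelength trace obeys Beer–Lambert:
`A = (eps_S·S + eps_P·P)·path + baseline`. With the closed-assay balance
`S + P = S0` this inverts linearly; it requires `eps_S ≠ eps_P` (otherwise
the reaction is optically invisible). Because the source assays never
publish their extinction coefficients, `eps_S`/`eps_P` are mandatory
metadata, not built-in constants. Recovered concentrations outside
`[0, S0]` are clipped only when the violation is within
`(3 + sqrt(2·ln n))·sigma` of the estimated noise (the extreme-value term
keeps honest Gaussian noise at the boundaries from being mistaken for a
metadata error); larger violations raise an error naming the likely
metadata culprit. The Ellman (DTNB) free-thiol computation uses the
standard `eps(412 nm) = 13,600 M⁻¹cm⁻¹` of 5-thio-2-nitrobenzoate.

## Global fitting

`ProgressCurveFitter` minimizes the unweighted sum of squared residuals in
the *measured* signal space (absorbance when optics are present) over all
curves of one enzyme–substrate pair jointly, sharing `(Km, kcat[, Ki])`.
Unweighted least squares is the default because the emulated assay reports
no weighting scheme; fitting pre-converted concentrations instead gives
identical estimates on clean data (tested).

- **Parameterization.** Optimization runs on `log(Km), log(kcat), log(Ki)`
  (positivity for free; conditions the ~6 decades of dynamic range across
  substrate panels) inside generous log-space boxes, with a trust-region
  reflective solver at `xtol = ftol = gtol = 1e-15`.
- **Start.** Early-window slopes give per-curve initial rates; a
  Hanes–Woolf line (`S0/v0 = S0/Vmax + Km/Vmax`) yields `(Km, Vmax)`;
  `Ki` starts at `Km`. Degenerate slopes fall back to
  `Km = median(S0)` with a warning. Tested to land within 10× of truth
  across the fast/slow regimes, which is inside the optimizer's basin.
- **Multi-start.** Default 5 starts (the guess plus 4 jitters of sd 0.5 in
  log space, seeded by `random_state`) guard against local minima; the
  large simulation loops in the tests use single starts since the guess is
  reliable there.
- **Model selection.** `model="auto"` fits both nested models and retains
  `Ki` only when the extra-sum-of-squares F-test on RSS is significant at
  `alpha = 0.05` *and* the estimate is identifiable (not at the bound, not
  `> 1e3·max(S0)`, finite uncertainty). This F-test is this package's
  concrete reading of a bare "significance level 0.05" model-selection
  rule. Because the null (`Ki → ∞`) sits on the parameter-space boundary,
  the realized false-detection rate is below the nominal level (about
  α/2; the suite measures ~2% at α = 5% over 200 null datasets) — the
  test is conservative, never anti-conservative — while power against
  `Ki = Km/2` at 0.002 AU noise exceeds 90%.
- **Unidentifiable Ki** is reported as absent ("N.D." in tables), never
  clamped; published panels show exactly this pathology (inhibition-constant
  errors dwarfing the estimate for weakly inhibited substrates).
- **Uncertainty.** Asymptotic SEs come from the log-space Jacobian by the
  delta method with t-based 95% intervals; `bootstrap_uncertainty` offers
  residual-resampling percentile intervals (seeded, `n_boot ≥ 50`).
  Whether published ± values are asymptotic or resampled is generally
  unstated, so both are available and neither is claimed to replicate a
  specific table's error model.
- **Specificity-only regime.** `PseudoFirstOrderRateFitter` handles
  substrates where saturation is unreachable: at `S0 ≪ Km` the trace is
  exponential with `k_obs = (kcat/Km)·E0`, so `kcat/Km = k_obs/E0` is the
  only measurable constant. A nested F-test against the saturating model
  warns when the trace shows curvature (i.e. `S0 ≪ Km` fails).
- **Reporting.** `report_table` renders a substrate-panel table at two
  significant figures with "N.D." for absent entries. The specificity cell
  is always the ratio of the *estimates* (or the direct low-S0 estimate);
  published tables occasionally disagree internally between that ratio and
  their printed specificity, and no attempt is made to reconcile such
  rows.

## Synthetic data: what it emulates and what it does not

`generate_trace_set` reproduces the study design of the emulated assay:
three initial substrate concentrations (0.1, 0.25, 0.5 mM by default),
absorbance decay at a single wavelength, pH 8.0 / 22 °C metadata, and
additive i.i.d. Gaussian noise on absorbance with `sigma = 0.002 AU` by
default — a realistic bench-spectrophotometer figure, chosen once. The
default extinction coefficients (`eps_S = 1e4`, `eps_P = 1e3 M⁻¹cm⁻¹`) are
synthetic order-of-magnitude nucleoside UV values. Time grids are uniform
with duration `5·(Km+S0)/Vmax`, reaching ≥ 99% conversion. The generator
does **not** model instrument drift, photon (shot) noise, enzyme
inactivation, temperature fluctuations, or mixing dead time — so passing
recovery tests demonstrate correctness of the estimation machinery under
the stated noise model, not robustness to every real-world artefact.

`generate_alignment` plants invariant columns in an otherwise randomized
alignment (per-row substitution and gap rates); it emulates the *structure*
of a family alignment, not real phylogenetic correlation between rows.
`generate_shift_pair` plants i.i.d. Gaussian *relative* error between
experimental and predicted chemical shifts, for which the deviation
statistic has the closed-form expectation `sigma·sqrt(2/pi)` used as its
Monte-Carlo oracle.

## Conservation stage

Columns are mapped to reference numbering by counting non-gap reference
characters (gap columns of the reference are unmapped), then each mapped
column's residue frequencies are counted. At threshold 1.0 with the default
gap policy, a single gap or mismatch disqualifies a column — a residue
absent from any family member is not 100% conserved; `ignore_gaps=True` is
offered because gap handling in such procedures is often unstated.
Comparison is case-insensitive and 'X' never counts toward a consensus.
The stage is tested against an exhaustive brute-force column scan and is
invariant under row reordering and duplication.

## Chemical-shift statistic

`D = mean |δ_pred − δ_exp| / |δ_exp|` over shared (residue, atom) keys,
reported per nucleus and pooled; lower is better. "Normalized and averaged"
admits variants, so a signed mean (`signed=True`) and
per-nucleus-then-pooled averaging (`pool_by_nucleus=True`) are provided;
the default — absolute values, pooled over atoms — is this package's
documented choice, not a claim about any particular prior analysis.
Zero experimental shifts are excluded with a warning (division guard);
atom names match after uppercasing, with no pseudo-atom expansion.

## Problem sizes in the test and acceptance runs

Recovery checks use 3 curves × 600 points (noiseless) — recovery there is
at machine precision, far inside the 0.1% assertion. The selection
calibration uses 200 null and 20 alternative datasets at 3 × 60 points with
single-start fits; the dual-route kinetics sweep uses 1000 random parameter
draws × 25 grid points; bootstrap coverage uses 25 datasets × 60
replicates. These sizes give sharp binomial/Monte-Carlo checks while
keeping the whole suite fast on a single CPU.

## Known limitations

- Competitive product inhibition only; mixed or uncompetitive schemes,
  multi-substrate competition, and enzyme inactivation are out of scope.
- Assay conditions (pH, temperature, buffer) are carried as metadata only;
  no condition-dependent rate laws.
- The F-test is conservative near the `Ki → ∞` boundary (see above); a
  boundary-corrected mixture test would sharpen calibration at the cost of
  the plain "F-test at 0.05" contract.
- Trace I/O supports the package's own plain-text dialect, not vendor
  spectrophotometer formats.
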