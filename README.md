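# enzkin

Progress-curve enzyme kinetics with competitive product inhibition —
simulation, global fitting, and two companion analyses from the same
enzyme-characterization workflow.

## The problem

Characterizing an amidohydrolase (here modelled on a bacterial
N4-acylcytosine/cytidine deacylase of the ASCH family, whose preferred
substrate is the modified nucleoside ac4C) means extracting the Michaelis
constant K_m, the turnover number k_cat, a product-inhibition constant K_i,
and the specificity constant k_cat/K_m from spectrophotometric assays: the
substrate and its deacylated product absorb differently in the UV, so a
full reaction time course is one absorbance decay trace. Instead of
initial-rate titrations, the whole progress curve at ≥ 3 initial substrate
concentrations is fit *globally* under the scheme

```
S + E <-> ES -> E + P          v = kcat·E0·S / (Km·(1 + P/Ki) + S)
    E + P <-> E_inh
```

where the product competitively inhibits by binding free enzyme. For a
closed assay (P = S0 − S) the rate law has the closed-form solution
S(t) = (α/β)·W₀((β·S0/α)·e^{(β·S0 − Vmax·t)/α}) with
α = Km(1 + S0/Ki), β = 1 − Km/Ki, Vmax = kcat·E0 (the Schnell–Mendoza
Lambert-W form when β = 1), which the fitter exploits. Whether K_i is
supported by the data is decided by a nested F-test at α = 0.05; an
unidentifiable K_i is reported as "N.D.".

The package also covers two auxiliary computations from such a workflow:

- **conservation** — find 100%-conserved columns of a family alignment and
  report them in reference numbering (how candidate catalytic residues such
  as a Lys21/Thr24/Glu74 triad get nominated for mutagenesis);
- **shifts** — rank structure models by the normalized deviation
  D = mean |δ_pred − δ_exp|/|δ_exp| between predicted and experimental NMR
  chemical shifts.

No raw traces ship with the package; a seeded synthetic-data module
(`enzkin.synthetic`) generates every input the pipeline consumes, with the
generating truth recorded for recovery testing.

## Worked example

Simulate a noisy three-concentration assay of a fast enzyme with product
inhibition (K_m = 62 µM, k_cat = 157 s⁻¹, K_i = 130 µM, σ = 0.002 AU),
then refit it with automatic model selection and a residual bootstrap:

```python
from enzkin import (KineticParameters, TraceSetSpec, generate_trace_set,
                    ProgressCurveFitter, report_table)

truth = KineticParameters(km=6.2e-5, kcat=157.0, ki=1.3e-4)
spec = TraceSetSpec(params=truth, seed=42, noise_sd_au=0.002, n_points=200)
curves = list(generate_trace_set(spec, label="ac4C"))

fitter = ProgressCurveFitter(model="auto", n_boot=200, random_state=42).fit(curves)
res = fitter.result_
```

This prints (via the snippet in `docs/methods.md` conventions):

```
model: with_inhibition  F-test p = 0
Km   = 6.201e-05 M   95% CI [6.18e-05, 6.22e-05]
kcat = 157.1 /s  95% CI [156.9, 157.2]
Ki   = 1.298e-04 M   95% CI [1.29e-04, 1.30e-04]
kcat/Km = 2.533e+06 /M/s
```

The F-test kept the product-inhibition term, and all three generating
constants are recovered within their bootstrap intervals.
`report_table({"ac4C": res})` renders the two-significant-figure panel row:

```
Substrate     Km (M)      kcat (s^-1)   Ki (M)      kcat/Km (M^-1 s^-1)
------------------------------------------------------------------------
ac4C          6.2e-05     160           1.3e-04     2.5e+06
```

The estimators follow the scikit-learn protocol (`fit`, `predict`,
`get_params`/`set_params`, trailing-underscore attributes), so they clone
and compose with sklearn tooling. The same stages are scriptable from the
shell:

```bash
enzkin simulate --km 6.2e-5 --kcat 157 --ki 1.3e-4 --seed 42 --out sim/
enzkin fit --traces 'sim/*.csv' --model auto --out fit/
enzkin conserve --aln family.afa --ref REF --threshold 1.0
enzkin shiftcmp --exp exp.csv --pred model1.csv --pred model2.csv
enzkin demo --seed 1 --out demo/        # all four stages end to end
```

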