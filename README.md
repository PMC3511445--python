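# erkensemble

Ensemble kinetic modeling of MEK-driven ERK phosphorylation dynamics.

## The problem

Proteasome inhibitors such as MG132 blunt growth-factor-stimulated ERK
signaling through two superimposed effects: activation of the upstream
kinase MEK is reduced, and ERK-directed phosphatases (short-lived
DUSPs/MKPs, stabilized when their degradation is blocked) are
upregulated. Immunoblot time courses of phospho-MEK and phospho-ERK
alone cannot separate the two by inspection. This package implements a
kinetic-modeling pipeline that parses them quantitatively and estimates
the **fold-upregulation of ERK phosphatase activity** (`phi`) in
inhibitor-treated cells, for experimentalists with quantified
time-course data from a dose × treatment design.

## The method

1. **Phenomenological MEK input.** Each measured pMEK course is fit
   independently to `u(t) = M0 + A(1 − e^(−t/τr))e^(−t/τd)`, giving a
   continuous condition-specific input — nothing upstream of MEK is
   modeled mechanistically.
2. **Two-site ERK model.** ERK fractions (x0, x1, x2) = (un-, mono-,
   dual-phosphorylated), with total conserved, follow distributive
   Michaelis–Menten (de)phosphorylation in which the kinase Vmax is
   proportional to u(t) and both phosphatase Vmax terms carry the factor
   `phi` (= 1 in control arms, one shared free value in inhibited arms):

       dx0/dt = −kc1·u·x0/(K1+x0) + φ·Vp1·x1/(P1+x1)
       dx2/dt =  kc2·u·x1/(K2+x1) − φ·Vp2·x2/(P2+x2)
       dx1/dt = −(dx0/dt + dx2/dt)

   The observable compared with pERK data is `scale·x2(t)`.
3. **Ensemble fit.** A simulated-annealing Metropolis sampler followed
   by a fixed-temperature harvest compiles an ensemble (default 10⁴) of
   parameter sets whose SEM-weighted χ² lies within a chi-square
   quantile increment of the best fit. `phi` is reported as ensemble
   mean ± SD; each parameter's ensemble CV diagnoses how tightly the
   data constrain it.

Because the motivating study's quantified data exist only as figures,
the package ships a synthetic-data generator that emulates the
experimental design (2 PDGF doses × {DMSO, MG132} × 6 times × 3
replicates, multiplicative noise) with known ground truth, and the test
suite validates the pipeline by parameter recovery. See
`docs/methods.md` for the full model description and assumptions.

## Worked example

```python
from erkensemble import SamplerConfig, generate_dataset, run_analysis
from erkensemble.synthetic import paper_like_config

dataset, truth = generate_dataset(paper_like_config(seed=1))   # phi_true = 3.61
report = run_analysis(dataset, SamplerConfig(n_ensemble=1000), seed=2001)
print(report.summary_text())
```

prints

```
ERK phosphatase fold-upregulation (ensemble estimate):
  phi = 3.67 +/- 0.20 (mean +/- s.d.), CV = 5.5%
  best chi-square: 11.062

Parameter summary (ensemble mean, SD, CV):
parameter        mean         sd       cv
      kc1    1.075676   0.598658 0.556541
      kc2    1.096450   0.441554 0.402712
       K1    0.103788   0.116353 1.121061
       K2    0.054037   0.033731 0.624218
      Vp1    0.342745   0.167975 0.490086
      Vp2  306.198350 144.890498 0.473192
       P1    0.046750   0.038504 0.823632
       P2 1747.191451 987.972364 0.565463
    scale    1.156033   0.034730 0.030043
      phi    3.667612   0.200542 0.054679
```

The recovered fold-factor (3.67 ± 0.20) matches the generating value
3.61 within its ensemble spread, and its small CV (5.5%) — smaller than
that of every kinetic constant — shows the study design constrains
`phi` tightly even though individual rate constants are sloppy (e.g.
Vp2 and P2 drift to large values together; only their ratio is
identified). The best χ² (~11 for 24 points and 10 parameters) indicates
a fit within measurement noise.

The same analysis is available from the shell:

```sh
erkensemble synth --seed 1 --out data.csv --truth truth.json
erkensemble run --data data.csv --seed 2001 --out results/
```

which writes `report.json`, `ensemble.csv`, `param_summary.csv`,
`trajectory_summary.csv` and a plain-text summary. `fit-mek`,
`simulate` and `fit-ensemble` expose the individual stages.

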