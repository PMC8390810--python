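# thzhdx

Hydrogen–deuterium exchange (HDX) kinetics and intensity-ratio statistics for
NMR experiments that perturb a protein with sub-terahertz irradiation or mild
heating.

## The problem

Backbone amide hydrogens of a folded protein exchange with solvent deuterons
through transient structural openings (the Linderstrøm-Lang scheme):

```
NH(closed)  <==[K_op]==>  NH(open)  --[k_ch]-->  ND (exchanged)
```

In the EX2 limit (closing much faster than chemistry, typical for native
proteins) the observed rate is `k_ex = K_op · k_ch`, where `K_op` is the
opening equilibrium constant and `k_ch` the intrinsic chemical rate of the
exposed amide (base-catalyzed: tenfold per pH unit; Arrhenius in temperature).
A perturbation applied during a short window of the exchange reaction leaves a
fingerprint in the per-residue peak intensities `I` of a ¹H-¹⁵N spectrum.
With a matched unperturbed control (GC), the effect is quantified as

```
R_t      = I_pert,t / I_GC,t                 (perturbation window t = 3, 6, 12 min)
ΔR_t     = R_t − R_3                         (3 min = temperature-equilibration reference)
Error(R) = R · sqrt(SNR_pert⁻² + SNR_GC⁻²)
```

and a residue is called **accelerated** when `ΔR + Error(ΔR) < 0`,
**decelerated** when `ΔR − Error(ΔR) > 0`, else unchanged.  For ubiquitin,
sub-THz irradiation accelerates exchange at interior-helix and hydrophobic
β-sheet amides while decelerating it at hydrophilic loop/3₁₀-helix amides —
the *opposite* of a 5 °C temperature rise.  The package models both
perturbations as class-wise multipliers on `K_op` and `k_ch`.

The package provides, as importable modules and a `thzhdx` CLI:

* `thzhdx.kinetics` — the two-state rate, EX1/EX2 limits, pH/temperature
  scaling, and protonated-fraction evolution over piecewise protocols;
* `thzhdx.experiment` — a synthetic-experiment generator: the 14-minute
  dissolution/perturbation/storage protocol, a 15-residue ubiquitin fixture,
  methyl internal standards, SNR-controlled noise with three-spectrum
  summation, and the sub-THz / heat perturbation scenarios;
* `thzhdx.statistics` — normalization, ratios, error propagation,
  classification, residue selection (SNR < 33.3, overlap, fast exchangers)
  and exponential rate fitting;
* `thzhdx.dosimetry` — reflective loss, Beer–Lambert absorption, delivered dose;
* `thzhdx.report` — per-residue scores written into PDB temperature factors;
* `thzhdx.pipeline` / `thzhdx.cli` — config-driven, seeded end-to-end runs.

## Worked example

```python
from thzhdx import RunConfig, run

config = RunConfig.model_validate({
    "mode": "simulate",
    "out_dir": "demo",
    "seed": 1,
    "condition": "THz_low",          # 18 mW/cm², +0.3 °C plateau
    "nominal_snr": 100.0,
    "beam": {"reflection_loss": 0.40},
})
artifacts = run(config)
print(open(artifacts["results"]).read())
```

The results table (abridged) reads:

```
residue  R3      R6      R12     dR12     errdR12  label        onset
3        0.9107  0.8717  0.7269  -0.1838  0.0124   accelerated  at_6_and_12
21       1.0144  1.0577  1.1069  +0.0925  0.0141   decelerated  at_6_and_12
26       0.9025  0.8543  0.7488  -0.1537  0.0122   accelerated  at_6_and_12
59       1.0134  1.0772  1.1153  +0.1020  0.0143   decelerated  at_6_and_12
61       1.0335  1.0324  1.1027  +0.0692  0.0141   decelerated  only_12
...
```

`R_t < 1` and falling with exposure time marks accelerated exchange at the
hydrophobic/interior residues (3, 26, …); `R_t > 1` and rising marks
deceleration at the hydrophilic residues (21, 59, 61).  `summary.json`
records the label counts (12 accelerated, 3 decelerated here), the config
hash and seed, and the dosimetry: 60% of the beam transmitted past the
silicon window (40% reflective loss), 96.1% absorbed over the 390 µm path
(α = 83 cm⁻¹), and 3.24/6.48/12.96 J/cm² delivered at 3/6/12 min of
18 mW/cm².

The same run from the shell:

```sh
thzhdx simulate --config config.yaml --seed 1 --out demo
thzhdx dose --power-density 150 --duration 12        # → 64.8 J/cm² at the sample
```

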