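# Methods

## Kinetic model

Exchange of a backbone amide hydrogen follows the two-state opening scheme:
closed and open states interconvert with rates `k_op`, `k_cl`
(`K_op = k_op/k_cl`), and the open state exchanges irreversibly with excess
D₂O at the intrinsic rate `k_ch`.  The steady-state observed rate is

```
k_ex = k_op · k_ch / (k_op + k_cl + k_ch)
```

which reduces to `K_op·k_ch` in the EX2 limit and `k_op` in the EX1 limit.
The tests cross-check this approximation against the slow eigenvalue of the
exact 2×2 linear system; note the approximation's relative deviation from
the eigenvalue is `k_op·k_ch/(k_op+k_cl+k_ch)²`, so "within 1%" holds only
where that term is small, not everywhere `k_op ≤ 0.1(k_cl+k_ch)`.

The intrinsic rate is modeled as purely base-catalyzed
(`k_ch ∝ 10^pH`, i.e. exactly tenfold per pH unit) with Arrhenius
temperature dependence.  Acid- and water-catalyzed terms are omitted: above
pH ~4 the base term dominates, and the analysis only relies on ratios and
small temperature offsets.  Protonated fractions over a protocol are exact
products of per-phase exponentials, `∏ exp(−k_ex,i Δt_i)`; a piecewise-ODE
integration oracle in the tests confirms them to 1e-6.

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `ea_kj_mol` | 60 | kJ/mol | activation energy of `k_ch`; a configurable knob, not a constant |
| reference pH | 6.4 | – | buffer pH at which `k_ch_ref` is quoted |
| reference T | 25 | °C | dissolution/hold temperature |
| quench multiplier | 0.05 | – | extra suppression of `k_ch` during 4 °C storage |
| storage | U(6, 10) | h | per-sample transport/storage interval |
| `nominal_snr` | 100 | – | per-spectrum SNR of a full-intensity amide |
| concentration jitter | 2% | – | per-sample scale factor on all signals |

With `Ea = 60 kJ/mol`, cooling from 25 °C to 4 °C slows `k_ch` by ×0.160 and
a +5 °C rise speeds it by ×1.49.

## Protocol and generator

Each simulated sample follows: 1 min handling at room temperature → X ∈
{0, 3, 6, 12} min perturbation → room-temperature hold to 14 min total →
quenched storage at 4 °C.  The temperature-control ramp (~3 min to plateau
in the real apparatus) is modeled as a step at the phase start; the 3-min
reference ratio absorbs most of the difference, which is why `ΔR` is defined
against `R_3`.

Readout: each of three spectra carries signal plus independent Gaussian
noise of rms `C/nominal_snr` (homoscedastic thermal noise); spectra are
summed, so summed SNR gains √3.  Amides report
`C·(1+ε)·protonated_fraction`; 37 methyl resonances report `C·(1+ε)` and act
as concentration internal standards — the per-sample jitter ε cancels
exactly after normalization by the methyl mean.  All randomness derives from
a single integer seed; fixed seeds give bit-identical tables.

### Residue fixture

The fixture carries the 15 residues named in the low-power irradiation map:
interior helix {V26, I30}, hydrophobic β-surface {I3, F4, L15, V17, I44,
V70, Q41, R42, L43, L69}, hydrophilic loop/3₁₀ helix {D21, Y59, I61}.  The
six further selected-but-unnamed residues are deliberately not invented; the
generator accepts arbitrary residue sets.  Control exchange rates were
placed just below the selection cut-off of ~0.1 h⁻¹ *at the 4 °C
measurement temperature* (the condition under which control rates are
estimated by real-time NMR), i.e. 0.45–0.62 h⁻¹ at 25 °C.  Opening
equilibria (`K_op` 1.5e-4–1e-3, protection factors ~1e3–7e3) keep `k_ch`
within the physically plausible few-hundred-to-few-thousand h⁻¹ range at
pH 6.4; the hydrophilic class is least protected.

### Perturbation scenarios

* **Sub-THz ("solvent effect")**: `K_op × 4` for interior/hydrophobic
  classes (hydrogen-bond-network destabilization), `k_ch × 0.1` for the
  hydrophilic class (solvent shielding), plus the measured bulk temperature
  plateau (+0.3 °C low power, +5 °C high power).
* **Heat conduction**: Arrhenius acceleration for every class via the +5 °C
  phase temperature, plus `K_op × 0.1` for interior/hydrophobic classes
  (conformational rigidification).  Any factor below 1/1.49 ≈ 0.67 inverts
  the hydrophobic direction relative to pure heating.

The multiplier magnitudes are design choices: the qualitative directions are
given (larger `K_op` hydrophobic / smaller `k_ch` hydrophilic under
irradiation, and the inverse pattern under heating), and the factors are
sized so the resulting `ΔR` values clear the SNR-propagated error at the
reported SNR regime — i.e. so the generator reproduces *detected* calls, as
observed, not sub-threshold trends.  The weakest effect in the whole design
is the heat-induced hydrophilic acceleration: it has no free factor (pure
Arrhenius on capped rates) and yields |ΔR₁₂| ≤ ~0.046, close to the
detection threshold at per-spectrum SNR 100, so its single-run detection
probability is ≈0.93 rather than ~1.

## Statistics

`R_t` uses methyl-normalized intensities; `Error(R_t) =
R·sqrt(SNR_p⁻² + SNR_g⁻²)` (validated against a Monte-Carlo
ratio-of-noisy-signals oracle in the small-noise regime); `ΔR = R_t − R_3`.
The two time-point errors combine in quadrature by default — the published
combiner's rendering is ambiguous, so literal `sum` and `half_sum` readings
are selectable (`errdr_method`).  Classification is strict:
`ΔR + Error < 0` → accelerated, `ΔR − Error > 0` → decelerated, ties are
unchanged.  Calls at 6 and 12 min merge into an onset tier; conflicting
directions collapse conservatively to unchanged with a warning.

Residue selection excludes: intensity below 3× noise rms in the first
control table (operationalizing "exchanged during storage"), SNR < 33.3
(>3% noise) in any table, and flagged overlaps.  SNR is height over rms
noise.  Rate fitting is nonlinear least squares of `A·exp(−kt)` on the
linear scale (additive noise; a log transform would distort errors at low
intensity); when the noise level is known, passing it as `sigma` makes the
reported standard error absolute — with few points, the default
residual-scaled error gives Student-t rather than Gaussian ±2σ coverage.

## Numerical and interface choices

* Durations are minutes at protocol granularity, rates per hour; conversion
  happens once inside `protonated_fraction`.
* Peak tables are plain TSV with `#` metadata lines (design as JSON) and
  lossless float round trips; parse errors name the offending line.
* Structure annotation overwrites PDB temperature factors (accelerated −1,
  decelerated +1, halved for 12-min-only onsets), so any viewer can render
  the map without extra tooling.
* Configs are validated strictly (unknown keys rejected); a run's summary
  records a SHA-256 of the canonical config JSON plus the seed, and
  identical config+seed reproduce artifacts byte for byte.
* Problem sizes in the test suite: Monte-Carlo oracles use 1e5 draws
  (error propagation) and 5e3 replicates (noise summation); pattern and
  recovery suites use 50 and 100 seeded end-to-end replicates.

## What the generator does and does not emulate

It reproduces first-order EX2 decay under the piecewise protocol,
class-dependent perturbation responses, concentration jitter with internal
standards, homoscedastic Gaussian spectral noise with √3 summation gain, and
storage-interval variation.  It does not simulate chemical shifts,
lineshapes or 2D overlap structure (overlap is an input flag), dipolar
broadening-induced intensity drift, residue-specific intrinsic-rate
prediction from sequence, EX1/EX2 regime inference, or heat transport (the
temperature plateaus are inputs).  Passing tests therefore show the
statistics behave correctly under the stated noise model, not that the model
captures every systematic effect of a real spectrometer.
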