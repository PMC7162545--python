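# dlgradient

Robustness analysis of the Dorsal (Dl) morphogen gradient with respect to
maternal *dorsal* dosage in the early *Drosophila* embryo.

The Dl/NF-κB nuclear gradient patterns the dorsoventral (DV) axis: borders
of target genes such as *snail* (*sna*) and *short gastrulation* (*sog*)
form where nuclear Dl crosses gene-specific concentration thresholds θ.
Measured borders in embryos with 1, 2 or 4 maternal *dl* copies shift by
only ~10%, yet a gradient that simply scales with dosage,

    c(x) = α [exp(−x²/2σ²) + m|x| + b],     φ ≡ (∂ ln x_g / ∂ ln α)_θ,

predicts border sensitivities φ near 1 (and still ≈ 0.4 in the best case
where basal nuclear signal is attributed to Dl/Cact complex).  This package
implements, for modellers and quantitative developmental biologists:

* the empirical dosage-scaling model with analytic sensitivity
  coefficients φ = −c(x_g)/(x_g c′(x_g)) and border predictions;
* a 51-compartment Dl/Cact/Toll reaction–transport model over nuclear
  cycle 14, with a saturable ventral Toll sink
  β(x) w/(κ+w), β(x) = β₀ e^−(x/φ_toll)², and the length-scale ratio
  ρ = λ_dc(Ṽ_nuc K_eq,dc + Ṽ_cyt) / λ_d(Ṽ_nuc K_eq,d + Ṽ_cyt);
* a random robustness screen: five free parameters drawn log-uniformly on
  [10⁻³, 10³], per-border thresholds fitted by least squares
  e(θ) = Σ_g ((x_model,g − x_exp,g)/σ_exp,g)², robust ⇔ e < 1.5 for all
  three borders, plus ensemble analytics (ρ, κ, amplitude ratios);
* profile quantification (Gaussian-plus-tail fits, gof filtering,
  normalization X = (I − B − 0.7M)/A, 301-point cohort averaging,
  half-max gene borders), dosage statistics (log-log sensitivity slopes,
  weighted qPCR ΔCT statistics, bootstrap amplitude ratios), and a
  synthetic-data generator with planted ground truth.

See `docs/methods.md` for model details, defaults and limitations.

## Worked example

Predict *sna* borders and sensitivity for the deconvolved gradient
(b = 0.11, σ = 0.15, m = −0.1), threshold calibrated at the wildtype
border x = 0.2:

```sh
$ dorsal-robustness empirical --basal 0.11 --dosages 0.5,1,2
gene  alpha    theta  x_border  expressed  saturated  multiple
 sna    0.5 0.501112  0.069168       True      False     False
 sna    1.0 0.501112  0.200000       True      False     False
 sna    2.0 0.501112  0.282920       True      False     False
{
  "min_phi_interior": 0.35687296629167486,
  "argmin_interior": 0.3397225594036694,
  "min_phi_range": 0.2222210705028519,
  "argmin_range": 0.8999999758261411
}
```

Reading this: a half-dose (1x) embryo expresses *sna* in under 7% of the
DV axis (versus the observed 0.17 — near-total loss of the mesoderm
domain), a double dose expands it to 0.28, and the best-case border
sensitivity on the Gaussian shoulder is φ ≈ 0.36 at x_g ≈ 0.34 — still
above the ~0.3 engineering rule of thumb, so dosage scaling alone cannot
explain the observed robustness (`min_phi_range` is the minimum over the
whole search range, which is dominated by the degenerate dorsal tail where
the gradient itself vanishes; see `docs/methods.md`).

The same conclusion from the mechanistic side, scaled down to 5000 random
parameter sets (about 5 minutes):

```sh
$ dorsal-robustness screen --n 5000 --seed 1 --out scratch/screen
```

prints, among other fields, `"n_robust": 16` (0.32% of draws), a robust-set
κ range of 0.001–0.46 (Toll saturation required) and 4x:2x amplitude
ratios all below 1.2 (amplitudes must not scale with dosage).  A Python
session gives the same through `dlgradient.screen.run_screen` /
`summarize_ensemble`.

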