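# morphomech

Single-cell **morpho-mechanobiology** analysis: does a cell's shape tell you
its mechanosensitive state, and when does it stop doing so?

Cells on engineered fiber networks adopt heterogeneous shapes, and their
mechanoactivation — indexed by the nuclear/cytoplasmic ratio of the
transcriptional co-activators YAP/TAZ — largely tracks that morphology.
`morphomech` implements the full analysis chain around this idea, exercisable
end-to-end on seeded synthetic data:

- **morphometry** — 14 cell/nuclear shape descriptors (area, perimeter,
  best-fit-ellipse axes, bounding extents, aspect ratio, solidity, roundness,
  circularity 4πA/P², orientation; nuclear area/aspect/angle) and YAP/TAZ
  nuclear/cytoplasmic intensity ratios from label masks.
- **som** — an unsupervised 2×2 self-organizing map over the z-scored
  descriptors that partitions a population into four morphologic states by
  batch competitive learning.
- **yapnet** — a 14(15)-input, 4-hidden-sigmoid-neuron regression network
  predicting the YAP/TAZ ratio, trained by Levenberg–Marquardt with Bayesian
  regularization: F = λ_d·ΣE² + λ_w·Σw², with λ's re-estimated each step by
  the evidence approximation (γ = N_w − 2λ_w·tr(H⁻¹)). The optional 15th
  input encodes a contractility cue (+1 agonist, 0 control, −1 inhibitor).
- **aberrance** — prediction-error statistics per group (μ, σ), Grubbs
  outlier screening of training targets, Kruskal–Wallis + Dunn post-hoc
  comparisons, and per-cell *decoupling* flags (|measured − predicted| >
  z·σ_ref) that pick out cells whose mechanosensing has departed from the
  morphology rule set.
- **classifier** — a 10-hidden-neuron softmax network (scaled conjugate
  gradient, 50/15/35 split with validation early stopping) that classifies
  cells as invasive vs non-invasive from morphology, YAP/TAZ, or both.
- **mechanics** — a strain-dependent fibrous-network constitutive model:
  fiber-angle density R(θ,ε) is a (renormalized) Gaussian whose spread
  σ(ε) = σ₀e^(−αε) + σ∞ tightens with strain, and axial stress is

      S₁₁(ε₁₁) = ∫₀^ε₁₁ ∫_{−π/2}^{π/2} R(θ,ε) cos²θ · A·B·e^{Bε} dθ dε + k_matrix·ε₁₁

  plus histogram/curve fitting and FFT-based fiber-orientation extraction
  from images.
- **synthetic** — seeded generators for everything above: archetype-based
  morphology populations, rasterized cell/nucleus masks, a morphology→YAP
  coupling with controlled explainable variance, cue shifts, planted
  decoupled subpopulations, and forward-simulated mechanics data.

## Worked example

```python
import numpy as np
from morphomech import synthetic, som, yapnet, aberrance

# 1. A heterogeneous population from four morphologic archetypes, with
#    YAP/TAZ coupled to aspect ratio, cell area, and nuclear area, and the
#    coupling noise calibrated so 65% of the YAP variance is explainable.
pop = synthetic.generate_population(n_per_archetype=261, seed=1)
coupling = synthetic.CouplingSpec(
    noise_sd=synthetic.noise_sd_for_explainable_variance(
        pop, synthetic.CouplingSpec(), 0.65))
table, info = synthetic.assign_yap(pop, coupling, seed=2)
print(round(info["explainable_variance"], 3))   # 0.65

# 2. Four shape clusters from a 2x2 SOM.
model = som.train_som(table, seed=3)
clusters = som.assign_clusters(model, table)
print(np.bincount(clusters)[1:])                # [261 257 265 261]

# 3. Predict YAP/TAZ from morphology; held-out R^2.
tr, te = yapnet.split_data(len(table), 0.75, seed=4)
X, y = table[synthetic.FEATURE_COLUMNS], table["yap_ratio"].to_numpy()
net = yapnet.train_bayesian_mlp(X.iloc[tr], y[tr], seed=5)
res = yapnet.evaluate(net, X.iloc[te], y[te])
print(round(res.r2, 3))                         # 0.611

# 4. Flag cells whose mechanosensing decouples from morphology.
dec, _ = synthetic.assign_yap(pop, coupling, decoupled=True, seed=6)
errs = dec["yap_ratio"].to_numpy() - yapnet.predict_yap(net, X)
flags, frac = aberrance.flag_decoupled(errs, reference_sigma=0.42)
print(round(frac, 3))                           # 0.771
```

The printed numbers mean: 65% of the YAP variance is morphology-driven by
construction; the SOM recovers four roughly equal shape groups; the trained
network explains 0.61 of held-out variance (most of the explainable part);
and when an offset population (mean shift +1.52) is planted, 77% of its
cells are flagged as decoupled at the 2σ threshold.

A command-line interface mirrors the library
(`morphomech extract | cluster | train-yap | predict-yap | evaluate |
classify | fit-mechanics | run`); `morphomech run --config run.yaml` executes
the whole synthetic study and writes a hashed artifact manifest.

## Documentation

`docs/methods.md` describes the models, the synthetic-data assumptions, the
numerical choices, and known limitations.
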