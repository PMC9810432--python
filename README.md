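# proteodyn

A multi-scale computational model of Alzheimer's disease on a brain
connectome, for computational neuroscientists studying how protein pathology
reshapes large-scale brain rhythms.  The package couples three processes that
live on the same network but on wildly different time scales:

1. **Prion-like protein spreading (years).**  A two-protein heterodimer
   model: healthy/toxic amyloid-beta (u, ũ) and healthy/toxic tau (v, ṽ)
   react locally and diffuse along the graph Laplacian L(t) of the evolving
   connectome,

   ```
   u̇  = -ρ L u  + k₀ - k₁ u - k₂ u ũ           ũ̇ = -ρ L ũ - k̃₁ ũ + k₂ u ũ
   v̇  = -ρ L v  + k₃ - k₄ v - k₅ v ṽ - k₆ ũ v ṽ  ṽ̇ = -ρ L ṽ - k̃₄ ṽ + k₅ v ṽ + k₆ ũ v ṽ
   ```

   with k₆ the amyloid→tau synergy.  Toxic load drives damage variables
   q^β, q^τ ∈ [0,1] per node, which degrade edge weights
   (ẇᵢⱼ = -γ(qᵢ^τ + qⱼ^τ)), push the excitatory activity parameter *a*
   through a transcritical bifurcation
   (ȧ = [c_β q^β (a_max - a) - c_τ q^τ](a - a_min), threshold
   R_crit = (a_max - a_min) c_β / c_τ for the damage ratio R = q^τ/q^β),
   and relax the inhibitory parameter *b* to b_min.

2. **Delay-coupled neural-mass dynamics (seconds).**  Each region is a
   rescaled Hopf normal form z = x + iy with elliptical limit cycle
   (semiaxes a√λ, b√λ), coupled through delayed excitatory activity:
   ż = F(z) + κ tanh(Σⱼ wᵢⱼ xⱼ(t - τᵢⱼ)), τᵢⱼ = lᵢⱼ/v_ax.  Probed every 3
   years on the frozen degraded network, the retained signals yield
   periodogram power spectra, alpha-band (8–12 Hz) power and peak frequency.

3. **Phase reduction of a self-coupled node.**  The mechanism of frequency
   slowing: θ̇ = ω + κ f(θ(t), θ(t-τ)) with
   f(p,q) = -sin(p)/(a√λ) · tanh(c a√λ cos(q)), and a closed small-c
   expansion of the period T(κ) whose leading term shows that
   sign(sin ωτ) decides slowing vs acceleration and that lowering the
   excitatory parameter *a* lengthens the period even without delay.

Because the reference tractography network is not redistributable, a
synthetic connectome generator builds structurally analogous bilateral,
lobe-labelled networks (default 83 nodes / 579 edges, 12 amyloid-seeded
nodes, bilateral entorhinal tau seeds).

## Worked example

A scaled-down in-silico study (40 nodes, 279 edges, 3 realizations per
probe, axonal-decay sweep γ ∈ {0.2, 0}):

```python
import proteodyn as P
from proteodyn.pipeline import ExperimentConfig, run_pipeline, global_alpha_curve

cfg = ExperimentConfig(
    n_nodes=40, n_edges=279, connectome_seed=1, master_seed=1,
    gamma_values=(0.2, 0.0), freeze_frequencies=True,
    dynamics=P.NeuralMassParams(n_realizations=3),
)
bundle = run_pipeline(cfg)
for gamma in cfg.gamma_values:
    print(f"gamma = {gamma}")
    print(global_alpha_curve(bundle, gamma).round(3).to_string())
```

prints (about two minutes on one core; abridged):

```
gamma = 0.2
         power_mean  power_std  peak_mean  peak_std
time_yr
0.0           0.359      0.026      9.921     0.111
9.0           0.382      0.027      9.974     0.090
18.0          0.583      0.062      9.967     0.155
24.0          0.221      0.055      9.966     0.112
30.0          0.003      0.000     10.021     0.118
gamma = 0.0
0.0           0.357      0.030      9.922     0.087
18.0          0.579      0.052      9.911     0.139
30.0          0.020      0.003      9.665     0.162
```

Reading the numbers: global alpha power is biphasic — it rises from 0.36 to
0.58 during the amyloid-driven hyperexcitable phase (years ~9–18) and then
collapses far below baseline as tau damage drags the excitatory parameter
to its floor.  The peak frequency separates the two regimes: with axonal
decay disabled (γ = 0) the dominant rhythm slows by ~0.26 Hz by year 30
(local neurodegeneration alone produces slowing), whereas with γ = 0.2 the
network gradually decouples and the peak drifts *up* toward the 10 Hz
intrinsic mean.  Columns `*_std` are standard deviations over the three
frequency realizations.

A shell interface mirrors the library:

```bash
proteodyn generate-connectome --nodes 83 --edges 579 --seed 1 --out-prefix net
proteodyn run-pipeline --out results --quick --seed 1
proteodyn phase-analysis --out results
```

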