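# Methods

## Model overview

The package simulates Alzheimer-like disease progression as three coupled
processes on a weighted brain network ("connectome"): slow prion-like
spreading of amyloid-beta and tau with accumulating damage (years), fast
delay-coupled neural-mass dynamics probed on frozen snapshots (seconds), and
a phase-reduction analysis of a single self-coupled node that isolates the
mechanism of frequency slowing.  The separation of time scales is the core
modelling assumption: within one dynamics probe the activity parameters
a_i, b_i, the weights w_ij and the delays tau_ij are constants.

## Slow system (proteopathy module)

State per node: healthy/toxic amyloid (u, ut), healthy/toxic tau (v, vt),
damages (q_beta, q_tau in [0,1]), activity parameters (a, b); plus one
weight per surviving edge.  Transport is graph-Laplacian diffusion with the
Laplacian rebuilt from the *current* clamped-nonnegative weights at every
right-hand-side evaluation, so spreading always sees the degraded network.
Units: concentrations in an arbitrary unit "M", time in years, lengths in
cm.  Defaults (all overridable):

| parameter | default | meaning |
|---|---|---|
| rho | 1e-3 | diffusion constant |
| k0, k3 | 2 M/yr | production of healthy amyloid / tau |
| k1, k4 | 2 /yr | clearance of healthy amyloid / tau |
| k1t, k4t | 1.5, 2.66 /yr | clearance of toxic amyloid / tau |
| k2, k5 | 2 /(M yr) | healthy-to-toxic conversion |
| k6 | 12 /(M^2 yr) | amyloid-to-tau synergy |
| k_beta, k_tau | 1 /(M yr) | damage accrual rates |
| gamma | 0.2 | edge decay rate (weight units/yr) |
| c_beta, c_tau, c_beta2 | 0.8, 1.8, 0.4 /yr | activity-parameter rates |
| delta | 0.95 | a in [1-delta, 1+delta], b_min = 1-delta |

Toxic-tau clearance exceeds its conversion rate (k4t > k5 at v = 1), so a
tau outbreak is subcritical on its own and ignites only where the synergy
term k6*ut*v*vt supplies extra production — tau follows amyloid, which is
the secondary-tauopathy regime the defaults encode.  delta is treated as
dimensionless (a and b are dimensionless); gamma is applied
to dimensionless damages exactly as the weight equation is written, making
its effective unit weight-units-per-year.

Seeding: u = v = 1 M, q = 0, a = b = 1 everywhere; total toxic masses of
1e-2 M are split equally over 12 amyloid-seeded nodes (six bilateral pairs:
precuneus, isthmus cingulate, insula, medial and lateral orbitofrontal, plus
superior frontal as the sixth neocortical pair) and over the 2 bilateral
entorhinal tau seeds.  Seed lists are configurable by region name.

The excitatory parameter obeys
da/dt = [c_beta q_beta (a_max - a) - c_tau q_tau](a - a_min): for frozen
damages there are two stationary points, a_min and
a2* = a_max - c_tau q_tau / (c_beta q_beta), exchanging stability at the
transcritical point R = R_crit = (a_max - a_min) c_beta / c_tau of the
damage ratio R = q_tau/q_beta (0.844 at defaults).  With k_beta = k_tau
both damages saturate at 1, so R -> 1 > R_crit and every node's excitation
ultimately collapses to a_min, after a transient hyperexcitable phase while
q_beta leads q_tau.

Numerics: adaptive explicit Runge-Kutta (scipy `solve_ivp`, RK45) with
rtol 1e-8 / atol 1e-11 and interpolation onto the exact probe grid
{0, 3, ..., 30} years.  The tolerances are set so that halving them moves
every snapshot field by < 1e-6 — the system is nonstiff at these rates (an
implicit multistep method was slower by two orders of magnitude because of
dense Jacobian estimation on the ~1200-dimensional coupled system).  Edge
weights are clamped at zero: the decay term is switched off for a
non-positive weight, and dead edges stay in the graph with zero weight so
matrix dimensions never change.

## Fast system (neural_dynamics module)

Each region is one complex variable z = x + iy near a Hopf bifurcation,
with elliptical orbits scaled by the excitatory/inhibitory semiaxes a, b;
coupling enters through the delayed excitatory signal passed through tanh.
Intrinsic frequencies are stored in Hz (drawn from N(10, 1) Hz per node)
and multiplied by 2*pi in the equations, so an uncoupled node's spectral
peak sits at its drawn frequency inside the alpha band.  Defaults: lam =
-0.01 (just below onset: isolated nodes are damped spirals and sustained
rhythms require network input), kappa = 5, v_ax = 130 cm/s, 20 s windows
with the first 10 s discarded, 500 Hz output sampling, 10 realizations.

Delays tau_ij = l_ij / v_ax are quantized to at most 40 distinct values by
uniform-width binning to bin midpoints (quantization error at most half a
bin), then rounded to whole integrator steps (minimum one step).

The delay system is integrated by fixed-step classical Runge-Kutta
(dt = 5e-4 s) on the method of steps: past excitatory values live in a
history buffer sampled at dt; delayed values needed at half-steps are
interpolated with a backward-biased 4-point cubic Lagrange stencil (the
forward point of a centred stencil does not exist yet when the delay equals
one step).  Initial states are uniform in the complex unit disc with
constant history.  Halving dt moves retained trajectories by < 1e-3
relative sup-norm at default settings.  The kernels are jitted with numba;
one network probe (40 nodes, 20 s) runs in well under a second after
compilation.

## Spectral read-outs (spectra module)

One-sided periodogram with rectangular window and density scaling (no
detrending), so the grid spacing is 1/(retained duration) = 0.1 Hz and the
integrated PSD satisfies Parseval against the mean-square signal power.
Alpha metrics: band power is the trapezoidal integral of the PSD over grid
points in [8, 12] Hz inclusive; the peak frequency is the grid argmax in
that band with ties broken toward the lowest frequency (for a near-zero
spectral floor the argmax is reported as-is — a documented degenerate
case).  Reporting follows the node -> lobe -> realization order: lobe means
first, then mean/std across realizations; the single-node brain-stem region
is excluded from lobe rows; a bandwidth-normalized "average density"
(band power / 4 Hz) is exported alongside the raw integral because either
convention may be wanted downstream.

## Phase reduction (phase_reduction module)

For the single self-coupled node (omega here is the literal angular rate,
so T = 2*pi/omega at kappa = 0 — a deliberate convention split from the
network module's Hz storage), the phase-sensitivity function of the
elliptical cycle gives

    f(p, q) = -sin(p)/(a sqrt(lam)) * tanh(c a sqrt(lam) cos(q)).

Periods are measured three ways: (i) "full" — simulate the delay equation,
discard 50 cycles, average >= 20 intervals between upward zero crossings of
x refined by linear interpolation; (ii) "phase" — simulate the phase
equation and average the time per 2*pi of accumulated phase, verifying
theta' > 0 throughout; (iii) analytic — the closed expansion obtained from
the free-running delay approximation theta(t - tau) ~ theta - omega*tau and
a cubic truncation of tanh, truncated at terms through kappa^2 with O(c^5) dropped.  Two single-term forms are
exposed because the compact leading-order coefficient commonly quoted,
c*pi*sin(omega*tau)/(4*omega^2) differs by a factor 4 from the c^1
truncation of the full expansion (c*pi*sin(omega*tau)/omega^2); both have
the same sign, and the numeric period adjudicates magnitudes.

Accuracy note: at the comparison point a = b = c = lam = 1 the cubic tanh
truncation is *not* a small-c limit, so the expansion's kappa^2 coefficient
(pi/6 at tau = 0) differs from the exact phase-system coefficient
(integral of sin^2 tanh^2(cos) = 0.5916) by ~0.068.  The
analytic-vs-phase error therefore scales as kappa^2 with that constant —
verified against direct quadrature in the tests — rather than kappa^3; only
for genuinely small c does the next-order scaling appear.

## Synthetic connectome (connectome module)

The generator emulates the structure of a tractography-derived reference
network that cannot be redistributed: bilateral mirror-paired regions
labelled with seven lobes (frontal, parietal, temporal, occipital, limbic,
subcortical, brain-stem), one midline brain-stem node (plus a second
midline subcortical node when the node count is even), all disease seed
regions present by name, a uniform random spanning tree plus uniformly
random extra edges, fibre lengths Uniform(1, 17) cm, fibre counts
LogNormal(1.0, 0.6).  The count scale puts typical weights n/l at O(0.3),
which is commensurate with the default axonal-decay rate: tau-driven
degradation (|dw/dt| <= 2*gamma) can sever a typical edge within the
30-year horizon — the regime in which the gamma sweep distinguishes local
from connectivity-driven slowing — while row sums (~5) still saturate the
tanh coupling at baseline so the healthy network sustains oscillations.

What the generator does *not* emulate: geometric embedding (lengths are
edge attributes, uncorrelated with topology), hub/rich-club organization,
hemispheric homotopy of edges, and any subject-level variability.  Passing
tests on synthetic networks therefore demonstrate the mechanisms (biphasic
excitation, slowing vs decoupling) and not quantitative agreement with any
measured connectome.

## Experiment orchestration and problem sizes

The pipeline integrates the slow system once per gamma and reuses snapshots
(gamma only enters the weight equation), then runs the oscillator probes.
Randomness is counter-based (`SeedSequence([master_seed, stream, ...])`):
every realization is individually reproducible, and frequency draws omit
the gamma index so gamma runs are paired.  By default intrinsic frequencies
are redrawn per (probe, realization); the `freeze_frequencies` switch
instead treats a realization as one "subject" whose frequencies and initial
state persist across probes, which removes probe-to-probe sampling noise
from trend estimates and is used for the scaled-down study.

The scaled-down study conditions used by the test-suite and the acceptance
script are 40 nodes / 279 edges (the reference edge density), 3
realizations per probe, gammas {0.2, 0} — sizes chosen so the full
experiment completes in a couple of minutes on one core.  At that size the
probe-to-probe peak-frequency trajectory under gamma = 0.2 is flat before
tau damage exists and shows a genuine dip while partial decoupling competes
with the excitatory collapse, so its step-wise monotonicity is weaker than
the endpoint trend (the endpoint contrast — slowing at gamma = 0, recovery
toward the intrinsic mean at gamma = 0.2 — is robust across seeds).

## Known limitations

- Single-frequency (alpha) repertoire; no cross-frequency structure, no
  stochastic input noise, no biophysical interpretation of kappa or lam.
- The damage model saturates both q at 1, so every parameterization with
  both proteins present ends in full collapse; only the timing varies.
- The weight equation can only decrease edges; clamping at zero is the sole
  nonsmoothness seen by the integrator.
- Delay quantization and step rounding bias delays by up to half a bin plus
  half a step; at 40 levels and dt = 0.5 ms this is below 2 ms.
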