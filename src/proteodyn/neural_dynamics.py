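"""Fast dynamics: delay-coupled Hopf neural masses on a frozen connectome.

Each region is a neural mass written as one complex variable
``z_i = x_i + i y_i`` (excitatory + i * inhibitory activity) evolving as

    dz_i/dt = F(z_i) + kappa * tanh( sum_j w_ij x_j(t - tau_ij) ),
    F(z)    = z (lam - x^2/a^2 - y^2/b^2) - omega y (a/b) + i omega x (b/a),

a rescaled Hopf normal form whose uncoupled limit cycle (lam > 0) is the
origin-centred ellipse with semiaxes a*sqrt(lam), b*sqrt(lam) traversed at
constant angular rate omega; for lam < 0 the origin is a stable spiral and
oscillations are sustained only by the delayed input from neighbours.
Intrinsic frequencies are stored in Hz and multiplied by 2*pi inside the
equations, so an uncoupled node peaks at omega_i Hz in the spectrum.

Integration is fixed-step classical Runge-Kutta on the method of steps:
the excitatory signal is kept in a history buffer sampled at the step size,
delays are rounded to whole steps (>= 1), and delayed values at half-steps
come from a backward-biased 4-point cubic Lagrange stencil.  The jitted
kernels below also serve the single self-coupled node used by the
phase-reduction analysis (there omega is the literal angular rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numba as nb
import numpy as np

from .errors import ConfigurationError, ParameterError, ValidationError


@dataclass
class NeuralMassParams:
    """Simulation parameters of the oscillator network probe."""

    lam: float = -0.01          # Hopf parameter (just below onset)
    kappa: float = 5.0          # global coupling strength
    v_ax: float = 130.0         # axonal speed (cm/s)
    omega_mean: float = 10.0    # intrinsic frequency mean (Hz)
    omega_std: float = 1.0      # intrinsic frequency std (Hz)
    duration_s: float = 20.0    # total simulated window (s)
    burn_in_s: float = 10.0     # discarded transient (s)
    fs: float = 500.0           # output sampling rate (Hz)
    n_realizations: int = 10
    master_seed: int = 0
    n_delay_levels: int = 40
    dt: float = 5e-4            # integrator step (s)

    def __post_init__(self) -> None:
        if self.duration_s <= self.burn_in_s:
            raise ParameterError("duration_s must exceed burn_in_s")
        if self.fs <= 2.0 * (self.omega_mean + 4.0 * self.omega_std):
            raise ParameterError("fs must exceed twice the top of the frequency range")
        if self.n_realizations < 1:
            raise ParameterError("n_realizations must be >= 1")
        steps = 1.0 / (self.fs * self.dt)
        if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
            raise ParameterError("1/(fs*dt) must be a whole number of steps")


@dataclass
class OscillatorSnapshot:
    """Frozen per-probe inputs: activity parameters, frequencies, weights, delays."""

    a: np.ndarray           # excitatory semiaxis per node (> 0)
    b: np.ndarray           # inhibitory semiaxis per node (> 0)
    omega_hz: np.ndarray    # intrinsic frequency per node (Hz)
    w: np.ndarray           # symmetric nonnegative coupling weights
    tau: np.ndarray         # symmetric delays (s), zero where no edge

    def __post_init__(self) -> None:
        n = self.a.size
        if not (self.b.size == self.omega_hz.size == n and self.w.shape == (n, n) == self.tau.shape):
            raise ValidationError("snapshot arrays have inconsistent shapes")
        if np.any(self.a <= 0) or np.any(self.b <= 0):
            raise ValidationError("activity parameters must be positive")
        if np.any(self.w < 0) or not np.allclose(self.w, self.w.T):
            raise ValidationError("weights must be symmetric and nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.a.size


@dataclass
class TimeSeriesSet:
    """Uniformly sampled excitatory signals x_i(t) over the retained window."""

    t: np.ndarray       # absolute times (s)
    x: np.ndarray       # (n_samples, n_nodes)
    fs: float

    def __post_init__(self) -> None:
        if self.t.size != self.x.shape[0]:
            raise ValidationError("time grid and samples disagree")
        if self.t.size > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.fs, rtol=1e-9, atol=1e-12):
                raise ValidationError("time grid must be uniform at 1/fs")
        if not np.all(np.isfinite(self.x)):
            raise ValidationError("non-finite samples")


def draw_frequencies(
    n: int, mean_hz: float, std_hz: float, stream: np.random.Generator
) -> np.ndarray:
    """Draw n intrinsic frequencies (Hz) from N(mean, std) on the given stream."""
    if std_hz < 0:
        raise ParameterError("std_hz must be nonnegative")
    return stream.normal(mean_hz, std_hz, size=n)


def hopf_drift(
    z: np.ndarray | complex, a, b, omega_rad, lam
) -> np.ndarray | complex:
    """Local drift F(z) of the rescaled Hopf normal form (omega in rad/s)."""
    x, y = np.real(z), np.imag(z)
    s = lam - x**2 / a**2 - y**2 / b**2
    return z * s - omega_rad * y * (a / b) + 1j * omega_rad * x * (b / a)


# --------------------------------------------------------------------------
# jitted kernels
# --------------------------------------------------------------------------

# delayed-value lookup: mode 0 -> grid row h - d; mode 1 -> row h + 1 - d;
# mode 2 -> cubic Lagrange at h + 1/2 - d using rows (h-d-2 .. h-d+1)
_C0, _C1, _C2, _C3 = 0.0625, -0.3125, 0.9375, 0.3125


@nb.njit(cache=True)
def _coupling(xh, h, mode, wdata, indices, indptr, dsteps, kappa, out):
    n = out.shape[0]
    for i in range(n):
        acc = 0.0
        for p in range(indptr[i], indptr[i + 1]):
            j = indices[p]
            d = dsteps[p]
            if mode == 0:
                xd = xh[h - d, j]
            elif mode == 1:
                xd = xh[h + 1 - d, j]
            else:
                base = h - d
                xd = (
                    _C0 * xh[base - 2, j]
                    + _C1 * xh[base - 1, j]
                    + _C2 * xh[base, j]
                    + _C3 * xh[base + 1, j]
                )
            acc += wdata[p] * xd
        out[i] = kappa * math.tanh(acc)


@nb.njit(cache=True)
def _network_kernel(x0, y0, a, b, om, lam, kappa, wdata, indices, indptr, dsteps, dt, n_steps, pad):
    n = x0.shape[0]
    xh = np.empty((pad + n_steps + 1, n))
    for r in range(pad + 1):
        xh[r] = x0
    x = x0.copy()
    y = y0.copy()
    c0 = np.empty(n)
    ch = np.empty(n)
    c1 = np.empty(n)
    k1x = np.empty(n); k1y = np.empty(n)
    k2x = np.empty(n); k2y = np.empty(n)
    k3x = np.empty(n); k3y = np.empty(n)
    k4x = np.empty(n); k4y = np.empty(n)
    for s in range(n_steps):
        h = pad + s
        _coupling(xh, h, 0, wdata, indices, indptr, dsteps, kappa, c0)
        _coupling(xh, h, 2, wdata, indices, indptr, dsteps, kappa, ch)
        _coupling(xh, h, 1, wdata, indices, indptr, dsteps, kappa, c1)
        for i in range(n):
            xi = x[i]; yi = y[i]
            sq = lam - xi * xi / (a[i] * a[i]) - yi * yi / (b[i] * b[i])
            k1x[i] = xi * sq - om[i] * yi * (a[i] / b[i]) + c0[i]
            k1y[i] = yi * sq + om[i] * xi * (b[i] / a[i])
        for i in range(n):
            xi = x[i] + 0.5 * dt * k1x[i]; yi = y[i] + 0.5 * dt * k1y[i]
            sq = lam - xi * xi / (a[i] * a[i]) - yi * yi / (b[i] * b[i])
            k2x[i] = xi * sq - om[i] * yi * (a[i] / b[i]) + ch[i]
            k2y[i] = yi * sq + om[i] * xi * (b[i] / a[i])
        for i in range(n):
            xi = x[i] + 0.5 * dt * k2x[i]; yi = y[i] + 0.5 * dt * k2y[i]
            sq = lam - xi * xi / (a[i] * a[i]) - yi * yi / (b[i] * b[i])
            k3x[i] = xi * sq - om[i] * yi * (a[i] / b[i]) + ch[i]
            k3y[i] = yi * sq + om[i] * xi * (b[i] / a[i])
        for i in range(n):
            xi = x[i] + dt * k3x[i]; yi = y[i] + dt * k3y[i]
            sq = lam - xi * xi / (a[i] * a[i]) - yi * yi / (b[i] * b[i])
            k4x[i] = xi * sq - om[i] * yi * (a[i] / b[i]) + c1[i]
            k4y[i] = yi * sq + om[i] * xi * (b[i] / a[i])
        for i in range(n):
            x[i] += dt / 6.0 * (k1x[i] + 2.0 * k2x[i] + 2.0 * k3x[i] + k4x[i])
            y[i] += dt / 6.0 * (k1y[i] + 2.0 * k2y[i] + 2.0 * k3y[i] + k4y[i])
            xh[h + 1, i] = x[i]
    return xh[pad:]


@nb.njit(cache=True)
def _self_kernel(x0, y0, a, b, om, lam, cw, kappa, tau_steps, dt, n_steps):
    """Single self-coupled node dz/dt = F(z) + kappa tanh(c x(t - tau)).

    tau_steps == 0 reduces to an ODE (stage-consistent coupling input).
    """
    pad = tau_steps + 3
    xh = np.empty(pad + n_steps + 1)
    for r in range(pad + 1):
        xh[r] = x0
    x = x0
    y = y0
    for s in range(n_steps):
        h = pad + s
        if tau_steps == 0:
            # stage coupling evaluated on the stage state itself
            sq = lam - x * x / (a * a) - y * y / (b * b)
            k1x = x * sq - om * y * (a / b) + kappa * math.tanh(cw * x)
            k1y = y * sq + om * x * (b / a)
            xi = x + 0.5 * dt * k1x; yi = y + 0.5 * dt * k1y
            sq = lam - xi * xi / (a * a) - yi * yi / (b * b)
            k2x = xi * sq - om * yi * (a / b) + kappa * math.tanh(cw * xi)
            k2y = yi * sq + om * xi * (b / a)
            xi = x + 0.5 * dt * k2x; yi = y + 0.5 * dt * k2y
            sq = lam - xi * xi / (a * a) - yi * yi / (b * b)
            k3x = xi * sq - om * yi * (a / b) + kappa * math.tanh(cw * xi)
            k3y = yi * sq + om * xi * (b / a)
            xi = x + dt * k3x; yi = y + dt * k3y
            sq = lam - xi * xi / (a * a) - yi * yi / (b * b)
            k4x = xi * sq - om * yi * (a / b) + kappa * math.tanh(cw * xi)
            k4y = yi * sq + om * xi * (b / a)
        else:
            d = tau_steps
            base = h - d
            x_del0 = xh[h - d]
            x_delh = (
                _C0 * xh[base - 2] + _C1 * xh[base - 1] + _C2 * xh[base] + _C3 * xh[base + 1]
            )
            x_del1 = xh[h + 1 - d]
            in0 = kappa * math.tanh(cw * x_del0)
            inh = kappa * math.tanh(cw * x_delh)
            in1 = kappa * math.tanh(cw * x_del1)
            sq = lam - x * x / (a * a) - y * y / (b * b)
            k1x = x * sq - om * y * (a / b) + in0
            k1y = y * sq + om * x * (b / a)
            xi = x + 0.5 * dt * k1x; yi = y + 0.5 * dt * k1y
            sq = lam - xi * xi / (a * a) - yi * yi / (b * b)
            k2x = xi * sq - om * yi * (a / b) + inh
            k2y = yi * sq + om * xi * (b / a)
            xi = x + 0.5 * dt * k2x; yi = y + 0.5 * dt * k2y
            sq = lam - xi * xi / (a * a) - yi * yi / (b * b)
            k3x = xi * sq - om * yi * (a / b) + inh
            k3y = yi * sq + om * xi * (b / a)
            xi = x + dt * k3x; yi = y + dt * k3y
            sq = lam - xi * xi / (a * a) - yi * yi / (b * b)
            k4x = xi * sq - om * yi * (a / b) + in1
            k4y = yi * sq + om * xi * (b / a)
        x += dt / 6.0 * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
        y += dt / 6.0 * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
        xh[h + 1] = x
    return xh[pad:]


@nb.njit(cache=True)
def _phase_kernel(theta0, om, kappa, asl, cw, tau_steps, dt, n_steps):
    """Phase DDE dtheta/dt = om + kappa f(theta(t), theta(t - tau)).

    f(p, q) = -sin(p)/asl * tanh(cw * asl * cos(q)) with asl = a*sqrt(lam).
    History before t = 0 is the free-running phase theta0 + om*t.
    """
    pad = tau_steps + 3
    th = np.empty(pad + n_steps + 1)
    for r in range(pad + 1):
        th[r] = theta0 + (r - pad) * dt * om
    t = theta0
    for s in range(n_steps):
        h = pad + s
        if tau_steps == 0:
            k1 = om + kappa * (-math.sin(t) / asl * math.tanh(cw * asl * math.cos(t)))
            ti = t + 0.5 * dt * k1
            k2 = om + kappa * (-math.sin(ti) / asl * math.tanh(cw * asl * math.cos(ti)))
            ti = t + 0.5 * dt * k2
            k3 = om + kappa * (-math.sin(ti) / asl * math.tanh(cw * asl * math.cos(ti)))
            ti = t + dt * k3
            k4 = om + kappa * (-math.sin(ti) / asl * math.tanh(cw * asl * math.cos(ti)))
        else:
            d = tau_steps
            base = h - d
            q0 = th[h - d]
            qh = _C0 * th[base - 2] + _C1 * th[base - 1] + _C2 * th[base] + _C3 * th[base + 1]
            q1 = th[h + 1 - d]
            k1 = om + kappa * (-math.sin(t) / asl * math.tanh(cw * asl * math.cos(q0)))
            ti = t + 0.5 * dt * k1
            k2 = om + kappa * (-math.sin(ti) / asl * math.tanh(cw * asl * math.cos(qh)))
            ti = t + 0.5 * dt * k2
            k3 = om + kappa * (-math.sin(ti) / asl * math.tanh(cw * asl * math.cos(qh)))
            ti = t + dt * k3
            k4 = om + kappa * (-math.sin(ti) / asl * math.tanh(cw * asl * math.cos(q1)))
        t += dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        th[h + 1] = t
    return th[pad:]


# --------------------------------------------------------------------------
# public simulation drivers
# --------------------------------------------------------------------------


def _delay_steps_csr(snap: OscillatorSnapshot, dt: float):
    """CSR arrays of weights and integer delay steps (>= 1) for w > 0 entries."""
    n = snap.n_nodes
    indptr = np.zeros(n + 1, dtype=np.int64)
    indices = []
    wdata = []
    dsteps = []
    for i in range(n):
        cols = np.nonzero(snap.w[i] > 0)[0]
        indptr[i + 1] = indptr[i] + cols.size
        for j in cols:
            indices.append(j)
            wdata.append(snap.w[i, j])
            dsteps.append(max(1, int(round(snap.tau[i, j] / dt))))
    return (
        np.asarray(wdata, dtype=float),
        np.asarray(indices, dtype=np.int64),
        indptr,
        np.asarray(dsteps, dtype=np.int64),
    )


def simulate_network(
    snap: OscillatorSnapshot, p: NeuralMassParams, stream: np.random.Generator
) -> TimeSeriesSet:
    """Simulate the delay-coupled network; return the retained window at fs.

    Each node starts at a uniformly random point inside the complex unit
    disc, with constant history equal to that point.
    """
    n = snap.n_nodes
    dt = p.dt
    pos_tau = snap.tau[snap.w > 0]
    if pos_tau.size and dt > pos_tau.min():
        raise ConfigurationError("integrator step exceeds the smallest positive delay")
    n_steps = int(round(p.duration_s / dt))
    wdata, indices, indptr, dsteps = _delay_steps_csr(snap, dt)
    pad = int(dsteps.max()) + 3 if dsteps.size else 3

    r = np.sqrt(stream.random(n))
    ang = stream.random(n) * 2.0 * np.pi
    x0 = r * np.cos(ang)
    y0 = r * np.sin(ang)

    om_rad = 2.0 * np.pi * snap.omega_hz
    xs = _network_kernel(
        x0, y0, snap.a.astype(float), snap.b.astype(float), om_rad.astype(float),
        float(p.lam), float(p.kappa), wdata, indices, indptr, dsteps, dt, n_steps, pad
    )
    sps = int(round(1.0 / (p.fs * dt)))
    idx = np.arange(0, n_steps + 1, sps)
    t = idx * dt
    keep = t > p.burn_in_s + 1e-12
    return TimeSeriesSet(t[keep], xs[idx[keep]], p.fs)


def simulate_selfcoupled(params, duration: float, dt: float, x0=None, y0=0.0):
    """Simulate the single self-coupled node of the phase-reduction analysis.

    ``params`` needs attributes omega (rad/s, literal angular rate), a, b, c,
    lam, kappa, tau.  Returns ``(t, x)`` sampled at every integrator step.
    A zero delay is integrated as a plain ODE; otherwise the delay is rounded
    to a whole number of steps (>= 1).
    """
    tau = float(params.tau)
    if tau > 0 and dt > tau:
        raise ConfigurationError("dt must not exceed the delay tau")
    tau_steps = 0 if tau == 0 else max(1, int(round(tau / dt)))
    n_steps = int(round(duration / dt))
    if x0 is None:
        x0 = params.a * math.sqrt(params.lam) if params.lam > 0 else 0.5
    xs = _self_kernel(
        float(x0), float(y0), float(params.a), float(params.b), float(params.omega),
        float(params.lam), float(params.c), float(params.kappa), tau_steps, dt, n_steps
    )
    return np.arange(n_steps + 1) * dt, xs
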