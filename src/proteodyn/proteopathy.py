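"""Slow disease dynamics: heterodimer spreading, damage, and activity decay.

Four protein species live on each node — healthy/toxic amyloid-beta
(``u``, ``u_toxic``) and healthy/toxic tau (``v``, ``v_toxic``) — and diffuse
along the (evolving) graph Laplacian while reacting locally:

    du/dt  = -rho L u  + k0 - k1 u - k2 u u~
    du~/dt = -rho L u~ - k1t u~ + k2 u u~
    dv/dt  = -rho L v  + k3 - k4 v - k5 v v~ - k6 u~ v v~
    dv~/dt = -rho L v~ - k4t v~ + k5 v v~ + k6 u~ v v~

The ``k6`` term is the synergy by which toxic amyloid catalyses toxic-tau
production.  Toxic load drives two per-node damage variables in [0, 1],

    dq_beta/dt = k_beta u~ (1 - q_beta),     dq_tau/dt = k_tau v~ (1 - q_tau),

which in turn (i) degrade edge weights, dw_ij/dt = -gamma (q_tau_i + q_tau_j),
(ii) move the excitatory activity parameter ``a`` through a transcritical
bifurcation,

    da/dt = [c_beta q_beta (a_max - a) - c_tau q_tau] (a - a_min),

and (iii) monotonically relax the inhibitory parameter ``b`` to ``b_min``,
db/dt = -c_beta2 q_beta (b - b_min).  Amyloid damage therefore pushes nodes
toward hyperexcitability (a up, b down) while tau damage ultimately wins and
drags ``a`` to ``a_min``: the biphasic disease course.

The Laplacian is rebuilt from the current (clamped-nonnegative) weights at
every right-hand-side evaluation, so spreading always runs on the degraded
network.  All concentrations use the arbitrary unit "M"; time is in years.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .connectome import BRAIN_STEM_LOBE, AMYLOID_SEED_REGIONS, TAU_SEED_REGIONS, Connectome, weight_matrix
from .errors import ConfigurationError, NumericalError, ParameterError, ValidationError


@dataclass
class SpreadingParams:
    """Rates of the two-protein heterodimer spreading model (per year, M units)."""

    rho: float = 1e-3   # diffusion constant
    k0: float = 2.0     # amyloid production
    k1: float = 2.0     # healthy-amyloid clearance
    k1t: float = 1.5    # toxic-amyloid clearance
    k2: float = 2.0     # amyloid conversion
    k3: float = 2.0     # tau production
    k4: float = 2.0     # healthy-tau clearance
    k4t: float = 2.66   # toxic-tau clearance
    k5: float = 2.0     # tau conversion
    k6: float = 12.0    # amyloid->tau synergy

    def __post_init__(self) -> None:
        for name in ("rho", "k0", "k1", "k1t", "k2", "k3", "k4", "k4t", "k5", "k6"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")


@dataclass
class DamageParams:
    """Damage, axonal-decay and activity-parameter rates."""

    k_beta: float = 1.0    # amyloid damage rate (1/(M yr))
    k_tau: float = 1.0     # tau damage rate (1/(M yr))
    gamma: float = 0.2     # edge decay rate
    c_beta: float = 0.8    # amyloid push on a (1/yr)
    c_tau: float = 1.8     # tau pull on a (1/yr)
    c_beta2: float = 0.4   # amyloid pull on b (1/yr)
    delta: float = 0.95    # activity excursion; a in [1-delta, 1+delta]

    def __post_init__(self) -> None:
        for name in ("k_beta", "k_tau", "gamma", "c_beta", "c_tau", "c_beta2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        if not 0.0 < self.delta < 1.0:
            raise ParameterError("delta must be in (0, 1) so a_min, b_min > 0")

    @property
    def a_max(self) -> float:
        return 1.0 + self.delta

    @property
    def a_min(self) -> float:
        return 1.0 - self.delta

    @property
    def b_min(self) -> float:
        return 1.0 - self.delta


@dataclass
class SeedConfig:
    """Toxic-protein seeding: total mass split equally over named regions."""

    amyloid_total: float = 1e-2
    tau_total: float = 1e-2
    amyloid_regions: Sequence[str] = AMYLOID_SEED_REGIONS
    tau_regions: Sequence[str] = TAU_SEED_REGIONS


@dataclass
class BrainState:
    """Full per-node slow state plus the current edge-weight matrix."""

    u: np.ndarray
    ut: np.ndarray
    v: np.ndarray
    vt: np.ndarray
    qb: np.ndarray
    qt: np.ndarray
    a: np.ndarray
    b: np.ndarray
    w: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.u.size

    def copy(self) -> "BrainState":
        return BrainState(*(getattr(self, f).copy() for f in _STATE_FIELDS), self.w.copy())


_STATE_FIELDS = ("u", "ut", "v", "vt", "qb", "qt", "a", "b")

#: external (column) names for the node fields, in export order
FIELD_NAMES = {
    "u": "u",
    "u_toxic": "ut",
    "v": "v",
    "v_toxic": "vt",
    "q_beta": "qb",
    "q_tau": "qt",
    "a": "a",
    "b": "b",
}


@dataclass
class SnapshotSeries:
    """Brain states sampled at strictly increasing probe times (years)."""

    times: np.ndarray
    states: list[BrainState]
    edge_i: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    edge_j: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size != len(self.states):
            raise ValidationError("one state per probe time required")
        if t.size and (t[0] != 0.0 or np.any(np.diff(t) <= 0)):
            raise ValidationError("probe times must start at 0 and strictly increase")
        self.times = t

    def field_array(self, name: str) -> np.ndarray:
        """(n_times, n_nodes) array of a node field; external or attr name."""
        attr = FIELD_NAMES.get(name, name)
        if attr not in _STATE_FIELDS:
            raise ValidationError(f"unknown state field {name!r}")
        return np.stack([getattr(s, attr) for s in self.states])

    def node_frame(self) -> pd.DataFrame:
        rows = []
        for t, s in zip(self.times, self.states):
            df = pd.DataFrame({ext: getattr(s, attr) for ext, attr in FIELD_NAMES.items()})
            df.insert(0, "node", np.arange(s.n_nodes))
            df.insert(0, "time_yr", t)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def edge_frame(self) -> pd.DataFrame:
        rows = []
        for t, s in zip(self.times, self.states):
            rows.append(
                pd.DataFrame(
                    {
                        "time_yr": t,
                        "i": self.edge_i,
                        "j": self.edge_j,
                        "w": s.w[self.edge_i, self.edge_j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class BifurcationReport:
    """Stationary points and stability of the excitatory activity parameter."""

    R: float            # damage ratio q_tau / q_beta (nan when undefined)
    R_defined: bool
    R_crit: float       # (a_max - a_min) c_beta / c_tau
    a1_star: float      # = a_min, stable iff R > R_crit
    a2_star: float      # = a_max - c_tau q_tau / (c_beta q_beta), stable iff R < R_crit
    a1_stable: bool
    a2_stable: bool


def initialize_state(c: Connectome, seeds: SeedConfig | None = None) -> BrainState:
    """Healthy baseline state with toxic seeds split equally over seed nodes.

    All nodes start with healthy concentrations u = v = 1 M, no damage and
    unit activity parameters; the total toxic masses are divided equally
    among the nodes resolved from the seed region names.
    """
    seeds = seeds or SeedConfig()
    n = c.n_nodes
    state = BrainState(
        u=np.ones(n),
        ut=np.zeros(n),
        v=np.ones(n),
        vt=np.zeros(n),
        qb=np.zeros(n),
        qt=np.zeros(n),
        a=np.ones(n),
        b=np.ones(n),
        w=weight_matrix(c),
    )
    for regions, total, arr in (
        (seeds.amyloid_regions, seeds.amyloid_total, state.ut),
        (seeds.tau_regions, seeds.tau_total, state.vt),
    ):
        if not regions:
            continue
        names = set(regions)
        found = {nd.name for nd in c.nodes if nd.name in names}
        missing = names - found
        if missing:
            raise ConfigurationError(f"seed regions not in connectome: {sorted(missing)}")
        idx = c.seed_indices(regions)
        arr[idx] = total / idx.size
    return state


def _edges_of(state: BrainState) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(state.n_nodes, k=1)
    mask = state.w[iu, ju] > 0
    return iu[mask], ju[mask]


def _pack(state: BrainState, ei: np.ndarray, ej: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [getattr(state, f) for f in _STATE_FIELDS] + [state.w[ei, ej]]
    )


def _unpack(y: np.ndarray, n: int, ei: np.ndarray, ej: np.ndarray) -> BrainState:
    parts = [y[k * n : (k + 1) * n].copy() for k in range(len(_STATE_FIELDS))]
    w = np.zeros((n, n))
    wvals = np.maximum(y[len(_STATE_FIELDS) * n :], 0.0)
    w[ei, ej] = wvals
    w[ej, ei] = wvals
    return BrainState(*parts, w)


def _rhs(
    y: np.ndarray,
    n: int,
    ei: np.ndarray,
    ej: np.ndarray,
    sp: SpreadingParams,
    dp: DamageParams,
) -> np.ndarray:
    m = len(_STATE_FIELDS)
    u, ut, v, vt, qb, qt, a, b = (y[k * n : (k + 1) * n] for k in range(m))
    wvals = np.maximum(y[m * n :], 0.0)

    w = np.zeros((n, n))
    w[ei, ej] = wvals
    w[ej, ei] = wvals
    deg = w.sum(axis=1)

    def lap(x: np.ndarray) -> np.ndarray:  # L x with L = diag(deg) - W
        return deg * x - w @ x

    conv_u = sp.k2 * u * ut
    conv_v = sp.k5 * v * vt + sp.k6 * ut * v * vt
    du = -sp.rho * lap(u) + sp.k0 - sp.k1 * u - conv_u
    dut = -sp.rho * lap(ut) - sp.k1t * ut + conv_u
    dv = -sp.rho * lap(v) + sp.k3 - sp.k4 * v - conv_v
    dvt = -sp.rho * lap(vt) - sp.k4t * vt + conv_v

    dqb = dp.k_beta * ut * (1.0 - qb)
    dqt = dp.k_tau * vt * (1.0 - qt)
    da = (dp.c_beta * qb * (dp.a_max - a) - dp.c_tau * qt) * (a - dp.a_min)
    db = -dp.c_beta2 * qb * (b - dp.b_min)

    dw = -dp.gamma * (qt[ei] + qt[ej])
    dw = np.where(y[m * n :] > 0.0, dw, np.maximum(dw, 0.0))
    return np.concatenate([du, dut, dv, dvt, dqb, dqt, da, db, dw])


def proteopathy_rhs(
    state: BrainState, sp: SpreadingParams, dp: DamageParams
) -> BrainState:
    """Time derivative of every node field and surviving edge weight.

    Returned as a :class:`BrainState` whose entries hold derivatives (the
    ``w`` matrix holds dw/dt on surviving edges, zero elsewhere).
    """
    ei, ej = _edges_of(state)
    dy = _rhs(_pack(state, ei, ej), state.n_nodes, ei, ej, sp, dp)
    n = state.n_nodes
    out = _unpack(np.concatenate([dy[: 8 * n], np.zeros(ei.size)]), n, ei, ej)
    dw = dy[8 * n :]
    out.w[ei, ej] = dw
    out.w[ej, ei] = dw
    return out


def integrate_proteopathy(
    state0: BrainState,
    sp: SpreadingParams,
    dp: DamageParams,
    horizon: float = 30.0,
    probe_interval: float = 3.0,
    rtol: float = 1e-8,
    atol: float = 1e-11,
) -> SnapshotSeries:
    """Integrate the coupled node+edge system; snapshot every ``probe_interval`` years.

    Adaptive explicit integration (the system is nonstiff at default rates);
    snapshots are interpolated onto the exact probe grid.  Edge weights are
    clamped at zero from below.
    """
    if horizon <= 0:
        raise ParameterError("horizon must be positive")
    n_int = horizon / probe_interval
    if abs(n_int - round(n_int)) > 1e-9:
        raise ParameterError("probe_interval must divide horizon")
    times = np.linspace(0.0, horizon, int(round(n_int)) + 1)

    n = state0.n_nodes
    ei, ej = _edges_of(state0)
    sol = solve_ivp(
        lambda t, y: _rhs(y, n, ei, ej, sp, dp),
        (0.0, horizon),
        _pack(state0, ei, ej),
        method="RK45",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise NumericalError(f"proteopathy integration failed: {sol.message}")

    states = []
    for k in range(times.size):
        s = _unpack(sol.y[:, k], n, ei, ej)
        # wash out integrator-level noise at the invariant boundaries
        np.clip(s.qb, 0.0, 1.0, out=s.qb)
        np.clip(s.qt, 0.0, 1.0, out=s.qt)
        np.clip(s.a, dp.a_min, dp.a_max, out=s.a)
        np.clip(s.b, dp.b_min, 1.0, out=s.b)
        states.append(s)
    return SnapshotSeries(times, states, ei, ej)


def critical_ratio(dp: DamageParams, qb: float, qt: float) -> BifurcationReport:
    """Transcritical-bifurcation report for frozen damages ``(q_beta, q_tau)``.

    The damage ratio R = q_tau/q_beta is compared with
    R_crit = (a_max - a_min) c_beta / c_tau: the degenerate branch a_min is
    stable for R > R_crit, the interior branch a2* = a_max - c_tau q_tau /
    (c_beta q_beta) for R < R_crit.  ``qb = 0`` is flagged, not raised.
    """
    if qb < 0 or qt < 0:
        raise ParameterError("damages must be nonnegative")
    r_crit = (dp.a_max - dp.a_min) * dp.c_beta / dp.c_tau
    defined = qb > 0
    r = qt / qb if defined else float("nan")
    a2 = dp.a_max - dp.c_tau * qt / (dp.c_beta * qb) if defined else float("nan")
    return BifurcationReport(
        R=r,
        R_defined=defined,
        R_crit=r_crit,
        a1_star=dp.a_min,
        a2_star=a2,
        a1_stable=bool(defined and r > r_crit),
        a2_stable=bool(defined and r < r_crit),
    )


def lobe_average(series: SnapshotSeries, c: Connectome, field_name: str) -> pd.DataFrame:
    """Per-probe lobe means of a node field, plus a global mean over all nodes.

    The brain-stem lobe is excluded from the lobe columns (single node);
    the ``global`` column averages every node.
    """
    arr = series.field_array(field_name)
    lobes = c.lobes
    out = {"time_yr": series.times}
    for lobe in sorted(set(lobes) - {BRAIN_STEM_LOBE}):
        out[lobe] = arr[:, lobes == lobe].mean(axis=1)
    out["global"] = arr.mean(axis=1)
    return pd.DataFrame(out).set_index("time_yr")


def with_gamma(dp: DamageParams, gamma: float) -> DamageParams:
    """Copy of ``dp`` with the axonal-decay rate replaced."""
    return replace(dp, gamma=gamma)
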