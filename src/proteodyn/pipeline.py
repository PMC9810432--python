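"""End-to-end experiment: connectome -> 30-year proteopathy -> probed dynamics.

For each value of the axonal-decay rate gamma, the slow spreading/damage
system is integrated once over the disease horizon; at every probe time the
frozen snapshot (activity parameters a_i, b_i and degraded weights w_ij)
parameterizes the delay-coupled oscillator network, which is simulated for
``n_realizations`` independent draws of intrinsic frequencies and initial
conditions.  Retained signals are reduced to alpha-band power and peak
frequency and aggregated by lobe.

Randomness is counter-based: every stream is spawned from
``SeedSequence([master_seed, stream_kind, ...indices])`` so each realization
is individually reproducible and frequency draws are shared across gamma
values (paired comparisons).  By default frequencies are redrawn per
(probe, realization); ``freeze_frequencies`` holds them fixed per
realization across probes, removing probe-to-probe sampling noise from
trend read-outs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import Connectome, delay_matrix, generate_synthetic_connectome, load_connectome
from .errors import ParameterError
from .neural_dynamics import (
    NeuralMassParams,
    OscillatorSnapshot,
    TimeSeriesSet,
    draw_frequencies,
    simulate_network,
)
from .proteopathy import (
    BrainState,
    DamageParams,
    SeedConfig,
    SnapshotSeries,
    SpreadingParams,
    initialize_state,
    integrate_proteopathy,
    lobe_average,
    with_gamma,
)
from .spectra import aggregate_by_lobe, alpha_metrics, periodogram_psd

log = logging.getLogger("proteodyn")

# stream-kind tags of the counter-based seeding scheme
_FREQ_STREAM = 1
_INIT_STREAM = 2


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one full in-silico experiment."""

    n_nodes: int = 83
    n_edges: int = 579
    connectome_seed: int = 0
    node_table: str | None = None   # CSV paths override the synthetic generator
    edge_table: str | None = None
    spreading: SpreadingParams = field(default_factory=SpreadingParams)
    damage: DamageParams = field(default_factory=DamageParams)
    dynamics: NeuralMassParams = field(default_factory=NeuralMassParams)
    seeds: SeedConfig = field(default_factory=SeedConfig)
    gamma_values: tuple[float, ...] = (0.2, 0.1, 0.0)
    horizon: float = 30.0
    probe_interval: float = 3.0
    freeze_frequencies: bool = False
    master_seed: int = 0

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.gamma_values):
            raise ParameterError("gamma values must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for section, klass in (
            ("spreading", SpreadingParams),
            ("damage", DamageParams),
            ("dynamics", NeuralMassParams),
            ("seeds", SeedConfig),
        ):
            if section in raw:
                kwargs[section] = klass(**raw.pop(section))
        if "connectome" in raw:
            conn = raw.pop("connectome")
            kwargs["n_nodes"] = conn.get("n_nodes", 83)
            kwargs["n_edges"] = conn.get("n_edges", 579)
            kwargs["connectome_seed"] = conn.get("seed", 0)
            kwargs["node_table"] = conn.get("node_table")
            kwargs["edge_table"] = conn.get("edge_table")
        if "sweep" in raw:
            sweep = raw.pop("sweep")
            kwargs["gamma_values"] = tuple(sweep.get("gamma_values", (0.2, 0.1, 0.0)))
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class OutputBundle:
    """In-memory results plus the directory the CSV/JSON artifacts went to."""

    config: ExperimentConfig
    connectome: Connectome
    snapshot_series: dict[float, SnapshotSeries]
    metrics: dict[float, pd.DataFrame]       # per gamma: realization/node table
    summaries: dict[float, pd.DataFrame]     # per gamma: lobe summary per probe
    manifest: dict
    output_dir: Path | None = None


def frequency_stream(cfg: ExperimentConfig, probe_idx: int, realization: int) -> np.random.Generator:
    """Intrinsic-frequency stream: shared across gamma, optionally probe-frozen."""
    p = 0 if cfg.freeze_frequencies else probe_idx
    return np.random.default_rng(
        np.random.SeedSequence([cfg.master_seed, _FREQ_STREAM, p, realization])
    )


def _init_stream(cfg: ExperimentConfig, g_idx: int, probe_idx: int, realization: int) -> np.random.Generator:
    # a frozen realization is one "subject": same initial state at every probe
    p = 0 if cfg.freeze_frequencies else probe_idx
    return np.random.default_rng(
        np.random.SeedSequence([cfg.master_seed, _INIT_STREAM, g_idx, p, realization])
    )


def _build_connectome(cfg: ExperimentConfig) -> Connectome:
    if cfg.node_table and cfg.edge_table:
        return load_connectome(cfg.node_table, cfg.edge_table)
    return generate_synthetic_connectome(cfg.n_nodes, cfg.n_edges, cfg.connectome_seed)


def probe_snapshot(
    state: BrainState, omega_hz: np.ndarray, tau: np.ndarray
) -> OscillatorSnapshot:
    """Freeze a slow-state snapshot into oscillator-network inputs."""
    return OscillatorSnapshot(
        a=state.a.copy(), b=state.b.copy(), omega_hz=omega_hz,
        w=np.maximum(state.w, 0.0), tau=tau,
    )


def run_pipeline(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> OutputBundle:
    """Run the full experiment for every gamma in ``cfg.gamma_values``."""
    t_start = time.time()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    c = _build_connectome(cfg)
    tau = delay_matrix(c, cfg.dynamics.v_ax, cfg.dynamics.n_delay_levels)
    state0 = initialize_state(c, cfg.seeds)
    log.info("connectome: %d nodes, %d edges", c.n_nodes, c.n_edges)

    snapshot_series: dict[float, SnapshotSeries] = {}
    metrics_frames: dict[float, pd.DataFrame] = {}
    summary_frames: dict[float, pd.DataFrame] = {}
    timings: dict[str, float] = {}

    for g_idx, gamma in enumerate(cfg.gamma_values):
        t_gamma = time.time()
        series = integrate_proteopathy(
            state0.copy(), cfg.spreading, with_gamma(cfg.damage, gamma),
            cfg.horizon, cfg.probe_interval,
        )
        snapshot_series[gamma] = series
        timings[f"spreading_gamma_{gamma}"] = time.time() - t_gamma

        rows = []
        summaries = []
        for p_idx, t_probe in enumerate(series.times):
            state = series.states[p_idx]
            per_real = []
            for r in range(cfg.dynamics.n_realizations):
                omega = draw_frequencies(
                    c.n_nodes, cfg.dynamics.omega_mean, cfg.dynamics.omega_std,
                    frequency_stream(cfg, p_idx, r),
                )
                snap = probe_snapshot(state, omega, tau)
                ts = simulate_network(snap, cfg.dynamics, _init_stream(cfg, g_idx, p_idx, r))
                am = alpha_metrics(periodogram_psd(ts))
                per_real.append(am)
                rows.append(
                    pd.DataFrame(
                        {
                            "time_yr": t_probe,
                            "realization": r,
                            "node": np.arange(c.n_nodes),
                            "alpha_power": am.band_power,
                            "peak_freq_hz": am.peak_freq,
                        }
                    )
                )
            summary = aggregate_by_lobe(per_real, c)
            summary.insert(0, "time_yr", t_probe)
            summaries.append(summary)
        metrics_frames[gamma] = pd.concat(rows, ignore_index=True)
        summary_frames[gamma] = pd.concat(summaries, ignore_index=True)
        timings[f"dynamics_gamma_{gamma}"] = time.time() - t_gamma
        log.info("gamma=%g done in %.1f s", gamma, time.time() - t_gamma)

    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "seed_scheme": "SeedSequence([master_seed, stream, (probe), realization])",
        "wall_time_s": time.time() - t_start,
        "timings_s": timings,
    }

    bundle = OutputBundle(cfg, c, snapshot_series, metrics_frames, summary_frames, manifest, out)
    if out is not None:
        _write_bundle(bundle, out)
    return bundle


def _write_bundle(bundle: OutputBundle, out: Path) -> None:
    bundle.connectome.write(out / "connectome")
    for gamma, series in bundle.snapshot_series.items():
        tag = f"gamma_{gamma:g}"
        series.node_frame().to_csv(out / f"snapshots_{tag}.csv", index=False)
        series.edge_frame().to_csv(out / f"edge_weights_{tag}.csv", index=False)
        bundle.metrics[gamma].to_csv(out / f"alpha_metrics_{tag}.csv", index=False)
        bundle.summaries[gamma].to_csv(out / f"alpha_summary_{tag}.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, default=float))


def global_activity_curve(bundle: OutputBundle, gamma: float) -> pd.DataFrame:
    """Global (all-node) mean of the activity parameters across probes."""
    series = bundle.snapshot_series[gamma]
    a = lobe_average(series, bundle.connectome, "a")["global"]
    b = lobe_average(series, bundle.connectome, "b")["global"]
    return pd.DataFrame({"a": a, "b": b})


def global_alpha_curve(bundle: OutputBundle, gamma: float) -> pd.DataFrame:
    """Global alpha power and peak frequency (mean over realizations) per probe."""
    s = bundle.summaries[gamma]
    g = s[s["lobe"] == "global"].set_index("time_yr")
    return g[["power_mean", "power_std", "peak_mean", "peak_std"]]
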