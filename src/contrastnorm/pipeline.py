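"""End-to-end analysis pipeline: simulate -> preprocess -> QC -> RF-map ->
measure -> test -> report.

Experiments mirror the study's figure-level analyses on synthetic data:

* ``fig2_surround_sweep``  — one ON cell type, all four surround conditions;
* ``fig3_cell_types``      — four normalizing cell types, gray vs moving
  grating surround;
* ``fig5_amplitude_sweep`` — step amplitudes 50/75/100% under both
  surrounds;
* ``s2_l1_control``        — the L1-like cell without contrast
  normalization, same protocol as the amplitude sweep;
* ``fig4_model_only``      — the cascade model alone: static-nonlinearity
  equivalence and dynamic-nonlinearity non-equivalence panels (no
  simulation of recordings).

All stages are deterministic given the run seed; re-running a stage with
the same configuration reproduces its outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, synthetic
from .errors import ConfigurationError
from .model import ModelParams, make_pulse, run_cascade
from .preprocess import compute_dff, snr_filter
from .rf_mapping import reverse_correlate, rf_center_and_fwhm
from .stimulus import (
    DYNAMICS_ONSET,
    STEP_OFFSET,
    STEP_ONSET,
    SURROUND_CONDITIONS,
    ScreenGeometry,
    StepProtocolSpec,
    make_step_protocol,
)
from .synthetic import (
    ACQUISITION_RATE,
    CellArchetype,
    SimConfig,
    TrialRecording,
    default_archetypes,
    model_response,
    simulate_recording,
)

__all__ = [
    "RunConfig",
    "ExperimentResult",
    "EXPERIMENTS",
    "run_experiment",
    "simulate_experiment",
    "analyze_recordings",
    "model_only_panels",
]

log = logging.getLogger(__name__)

REFERENCE_CONDITION = "gray"

# (cell types, surround conditions, step amplitudes) per experiment
EXPERIMENTS: dict[str, dict] = {
    "fig2_surround_sweep": {
        "cell_types": ("Tm3-like",),
        "conditions": SURROUND_CONDITIONS,
        "amplitudes": (1.0,),
    },
    "fig3_cell_types": {
        "cell_types": ("Mi1-like", "Tm1-like", "Tm2-like", "Tm3-like"),
        "conditions": ("gray", "moving_grating"),
        "amplitudes": (1.0,),
    },
    "fig5_amplitude_sweep": {
        "cell_types": ("Tm3-like", "Mi1-like"),
        "conditions": ("gray", "moving_grating"),
        "amplitudes": (0.5, 0.75, 1.0),
    },
    "s2_l1_control": {
        "cell_types": ("L1-like",),
        "conditions": ("gray", "moving_grating"),
        "amplitudes": (0.5, 0.75, 1.0),
    },
    "fig4_model_only": {},
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    experiment: str = "fig3_cell_types"
    sim: SimConfig = field(default_factory=SimConfig)
    model_overrides: dict = field(default_factory=dict)
    output_dir: str | Path = "results"
    n_mapping_cells: int = 2
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ConfigurationError(
                f"unknown experiment {self.experiment!r}; "
                f"choose from {sorted(EXPERIMENTS)}"
            )
        self.sim = replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        sim = SimConfig(**cfg.pop("sim", {}))
        return cls(sim=sim, **cfg)


@dataclass
class ExperimentResult:
    """Bundle of pipeline outputs."""

    config: RunConfig
    recordings: list[TrialRecording]
    qc: pd.DataFrame
    condition_stats: list[metrics.ConditionStats]
    condition_table: pd.DataFrame
    tests: pd.DataFrame
    rf_table: pd.DataFrame | None = None


# --------------------------------------------------------------------------
# Simulation stage
# --------------------------------------------------------------------------

def simulate_experiment(
    config: RunConfig,
    archetypes: dict[str, CellArchetype] | None = None,
    geometry: ScreenGeometry | None = None,
) -> list[TrialRecording]:
    """Generate all trial recordings for the configured experiment."""
    plan = EXPERIMENTS[config.experiment]
    if not plan:
        return []
    archetypes = archetypes or default_archetypes()
    geometry = geometry or ScreenGeometry()
    sim = config.sim
    recordings: list[TrialRecording] = []
    for ct in plan["cell_types"]:
        archetype = archetypes[ct]
        for cond in plan["conditions"]:
            for amp in plan["amplitudes"]:
                spec = StepProtocolSpec(
                    center=archetype.rf_center,
                    surround_condition=cond,
                    step_amplitude=amp,
                    polarity=archetype.polarity,
                )
                movie = make_step_protocol(
                    spec, geometry, seed=sim.seed & 0x7FFFFFFF
                )
                for cell in range(sim.n_cells):
                    # One noiseless response per cell, shared by its trials.
                    response = synthetic.cell_response(movie, archetype, sim, cell)
                    for trial in range(sim.trials_per_condition):
                        recordings.append(
                            simulate_recording(
                                movie, archetype, sim, trial,
                                cell_id=cell, response=response,
                            )
                        )
    return recordings


# --------------------------------------------------------------------------
# Analysis stage
# --------------------------------------------------------------------------

def _group_key(rec: TrialRecording) -> tuple:
    return (rec.cell_type, rec.condition, rec.step_amplitude)


def analyze_recordings(
    recordings: list[TrialRecording],
    reference_condition: str = REFERENCE_CONDITION,
    reference_amplitude: float | None = None,
    seed: int = 0,
    step_onset: float = STEP_ONSET,
    step_offset: float = STEP_OFFSET,
    baseline_end: float = DYNAMICS_ONSET,
    measure_smooth_fwhm: float = 0.3,
) -> tuple[pd.DataFrame, list[metrics.ConditionStats], pd.DataFrame]:
    """ΔF/F conversion, SNR screening, metrics and statistics.

    Each cell's trials are converted to ΔF/F, screened with the SNR
    criterion, and trial-averaged.  Before metric extraction the
    trial-averaged trace is lightly smoothed (Gaussian,
    ``measure_smooth_fwhm`` seconds FWHM): the peak is a maximum statistic
    and would otherwise carry an upward bias from recording noise.
    Per-condition summaries use the cells that passed in both the
    condition and the reference (gray surround at the reference
    amplitude); relative peaks are computed per cell against that
    reference and Mann-Whitney tests compare each condition with it.
    """
    from .preprocess import _smooth

    # (cell_type, condition, amplitude) -> cell_id -> list of dff traces
    groups: dict[tuple, dict[int, list[np.ndarray]]] = {}
    fly_of: dict[tuple[str, int], int] = {}
    for rec in recordings:
        dff = compute_dff(rec.trace, rec.sample_rate)
        groups.setdefault(_group_key(rec), {}).setdefault(
            rec.cell_id, []
        ).append(dff.values)
        fly_of[(rec.cell_type, rec.cell_id)] = rec.fly_id

    qc_rows = []
    averaged: dict[tuple, dict[int, np.ndarray]] = {}
    for key, cells in sorted(groups.items()):
        ct, cond, amp = key
        averaged[key] = {}
        for cid, trials in sorted(cells.items()):
            mat = np.array(trials)
            decision = snr_filter(mat)
            qc_rows.append(
                {
                    "cell_type": ct,
                    "condition": cond,
                    "step_amplitude": amp,
                    "cell_id": cid,
                    "fly_id": fly_of[(ct, cid)],
                    "n_trials": mat.shape[0],
                    "signal_sd": decision.signal_sd,
                    "noise_sd": decision.noise_sd,
                    "snr_ratio": decision.ratio,
                    "snr_passed": decision.passed,
                }
            )
            if decision.passed:
                averaged[key][cid] = _smooth(
                    mat.mean(axis=0), measure_smooth_fwhm, ACQUISITION_RATE
                )
    qc = pd.DataFrame(qc_rows)

    amplitudes = sorted({k[2] for k in averaged})
    ref_amp = (
        reference_amplitude if reference_amplitude is not None
        else max(amplitudes, default=1.0)
    )
    # Reference (gray-surround) summaries per cell type, computed first so
    # every other condition can be measured and tested against them.
    ref_summaries: dict[str, metrics.ConditionStats] = {}
    for key in sorted(averaged):
        ct, cond, amp = key
        if cond == reference_condition and amp == ref_amp and averaged[key]:
            cells = averaged[key]
            ref_summaries[ct] = metrics.summarize_condition(
                cells, cells, ACQUISITION_RATE, step_onset, step_offset,
                baseline_end=baseline_end, cell_type=ct, condition=cond,
                step_amplitude=amp,
                fly_by_cell={cid: fly_of[(ct, cid)] for cid in cells},
                seed=seed,
            )

    stats_list: list[metrics.ConditionStats] = []
    test_rows: list[tuple] = []
    for key in sorted(averaged):
        ct, cond, amp = key
        ref_key = (ct, reference_condition, ref_amp)
        if ct not in ref_summaries:
            raise ConfigurationError(
                f"reference condition {ref_key} missing for {key}"
            )
        if key == ref_key:
            stats_list.append(ref_summaries[ct])
            continue
        ref_cells = averaged[ref_key]
        shared = {
            cid: tr for cid, tr in averaged[key].items() if cid in ref_cells
        }
        if not shared:
            log.warning("no cells passed QC for %s; skipping", key)
            continue
        this = metrics.summarize_condition(
            shared,
            {cid: ref_cells[cid] for cid in shared},
            ACQUISITION_RATE,
            step_onset,
            step_offset,
            baseline_end=baseline_end,
            cell_type=ct,
            condition=cond,
            step_amplitude=amp,
            fly_by_cell={cid: fly_of[(ct, cid)] for cid in shared},
            seed=seed,
        )
        stats_list.append(this)
        ref = ref_summaries[ct]
        test_rows.append(
            (ct, "peak_amplitude", cond_label(key), cond_label(ref_key),
             metrics.mann_whitney(this.per_cell_peaks, ref.per_cell_peaks))
        )
        test_rows.append(
            (ct, "decay_level", cond_label(key), cond_label(ref_key),
             metrics.mann_whitney(this.per_cell_decay, ref.per_cell_decay))
        )
    return qc, stats_list, metrics.tests_frame(test_rows)


def cond_label(key: tuple) -> str:
    _, cond, amp = key
    return f"{cond}@{int(round(100 * amp))}%"


def run_population(
    cell_type: str = "Tm3-like",
    conditions: tuple[str, ...] = ("gray", "moving_grating"),
    seed: int = 0,
    n_cells: int = 20,
    trials: int = 3,
    sim: SimConfig | None = None,
    archetypes: dict[str, CellArchetype] | None = None,
    geometry: ScreenGeometry | None = None,
) -> tuple[list[metrics.ConditionStats], pd.DataFrame]:
    """Simulate and analyze one cell type's population for a condition set.

    Convenience wrapper over :func:`simulate_experiment` and
    :func:`analyze_recordings` used for replicate studies (e.g. checking
    how often the dynamic-surround suppression and speed-up are recovered
    from noisy populations).  Returns the per-condition summaries and the
    Mann-Whitney test table.
    """
    archetypes = archetypes or default_archetypes()
    geometry = geometry or ScreenGeometry()
    if sim is None:
        sim = SimConfig(seed=seed, n_cells=n_cells, trials_per_condition=trials)
    else:
        sim = replace(sim, seed=seed, n_cells=n_cells, trials_per_condition=trials)
    archetype = archetypes[cell_type]
    recordings: list[TrialRecording] = []
    for cond in conditions:
        spec = StepProtocolSpec(
            center=archetype.rf_center,
            surround_condition=cond,
            polarity=archetype.polarity,
        )
        movie = make_step_protocol(spec, geometry, seed=sim.seed & 0x7FFFFFFF)
        for cell in range(sim.n_cells):
            response = synthetic.cell_response(movie, archetype, sim, cell)
            for trial in range(sim.trials_per_condition):
                recordings.append(
                    simulate_recording(
                        movie, archetype, sim, trial,
                        cell_id=cell, response=response,
                    )
                )
    _, stats_list, tests = analyze_recordings(recordings, seed=seed)
    return stats_list, tests


def population_ground_truth(
    cell_type: str = "Tm3-like",
    conditions: tuple[str, ...] = ("gray", "moving_grating"),
    seed: int = 0,
    n_cells: int = 20,
    archetypes: dict[str, CellArchetype] | None = None,
    geometry: ScreenGeometry | None = None,
) -> dict[str, metrics.ConditionStats]:
    """Noise-free condition summaries for the *same* heterogeneous cells a
    noisy run with this seed simulates.

    Cell-level model parameters derive only from the seed, so stripping
    the recording noise (and drift/corruption) regenerates the identical
    population; its measured metrics are the ground truth the noisy
    pipeline estimates.
    """
    sim = SimConfig(
        seed=seed, n_cells=n_cells, trials_per_condition=2,
        noise_sd=0.0, drift_amplitude=0.0, corrupt_fraction=0.0,
    )
    stats_list, _ = run_population(
        cell_type, conditions, seed=seed, n_cells=n_cells, trials=2, sim=sim,
        archetypes=archetypes, geometry=geometry,
    )
    return {s.condition: s for s in stats_list}


def noiseless_reference(
    cell_type: str = "Tm3-like",
    conditions: tuple[str, ...] = ("gray", "moving_grating"),
    archetypes: dict[str, CellArchetype] | None = None,
    geometry: ScreenGeometry | None = None,
) -> dict[str, metrics.ConditionStats]:
    """Ground-truth condition summaries from a noise-free single cell.

    The noiseless model response is passed through the identical
    measurement chain (resampling, ΔF/F, metrics), so the reference shares
    any attenuation the measurement itself introduces.
    """
    sim = SimConfig(
        seed=0, n_cells=1, n_flies=1, trials_per_condition=2,
        noise_sd=0.0, drift_amplitude=0.0, corrupt_fraction=0.0,
        gain_cv=0.0, k_cv=0.0, tau_cv=0.0,
    )
    stats_list, _ = run_population(
        cell_type, conditions, seed=0, n_cells=1, trials=2, sim=sim,
        archetypes=archetypes, geometry=geometry,
    )
    return {s.condition: s for s in stats_list}


# --------------------------------------------------------------------------
# RF-mapping stage
# --------------------------------------------------------------------------

def map_receptive_fields(
    config: RunConfig,
    archetypes: dict[str, CellArchetype] | None = None,
    geometry: ScreenGeometry | None = None,
) -> pd.DataFrame:
    """Run noise-mapping sessions for a few cells per type and estimate
    their RF centers and widths."""
    plan = EXPERIMENTS[config.experiment]
    if not plan:
        return pd.DataFrame()
    archetypes = archetypes or default_archetypes()
    geometry = geometry or ScreenGeometry()
    rows = []
    for ct in plan["cell_types"]:
        archetype = archetypes[ct]
        for cell in range(config.n_mapping_cells):
            movie, rec = synthetic.simulate_noise_mapping_session(
                archetype, geometry, config.sim, cell_id=cell
            )
            dff = compute_dff(rec.trace, rec.sample_rate)
            rf = reverse_correlate(movie, dff, max_lag=1.0)
            (az, el), fwhm = rf_center_and_fwhm(rf)
            rows.append(
                {
                    "cell_type": ct,
                    "cell_id": cell,
                    "center_azimuth": az,
                    "center_elevation": el,
                    "fwhm": fwhm,
                    "peak_lag": rf.peak_lag,
                    "true_azimuth": archetype.rf_center[0],
                    "true_elevation": archetype.rf_center[1],
                    "center_error_deg": float(
                        np.hypot(az - archetype.rf_center[0],
                                 el - archetype.rf_center[1])
                    ),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Model-only (cascade) panels
# --------------------------------------------------------------------------

def model_only_panels(
    overrides: dict | None = None, dt: float = 0.001
) -> dict[str, pd.DataFrame]:
    """Cascade responses for the model-only experiment.

    Returns time-indexed tables of normalized cascade outputs for the
    static and dynamic nonlinearity, at pulse amplitudes 0.2 and 1.0 and
    saturation parameters k = 0.2 (static surround) and k = 1.0 (dynamic
    surround).
    """
    overrides = dict(overrides or {})
    overrides.pop("nl_mode", None)
    overrides.pop("k", None)
    panels = {}
    for mode in ("static", "dynamic"):
        cols = {}
        for amp in (0.2, 1.0):
            for k in (0.2, 1.0):
                params = ModelParams(k=k, nl_mode=mode, dt=dt, **overrides)
                pulse = make_pulse(amp, duration=1.0, total=3.0, dt=dt)
                out = run_cascade(pulse, params, normalize=True)
                cols[f"amp{amp}_k{k}"] = out.values
        t = dt * np.arange(len(next(iter(cols.values()))))
        panels[mode] = pd.DataFrame({"time": t, **cols})
    return panels


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------

def _plot_condition_traces(stats_list, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cell_types = sorted({s.cell_type for s in stats_list})
    fig, axes = plt.subplots(
        len(cell_types), 2, figsize=(9, 3 * len(cell_types)), squeeze=False
    )
    for i, ct in enumerate(cell_types):
        for s in [s for s in stats_list if s.cell_type == ct]:
            t = np.arange(s.mean_trace.size) / s.sample_rate
            label = f"{s.condition}@{int(round(100 * s.step_amplitude))}%"
            axes[i, 0].plot(t, s.mean_trace * s.per_cell_peaks.mean(), label=label)
            peak = np.max(s.mean_trace) or 1.0
            axes[i, 1].plot(t, s.mean_trace / peak, label=label)
        axes[i, 0].set_title(f"{ct}: amplitude")
        axes[i, 1].set_title(f"{ct}: kinetics (condition-normalized)")
        axes[i, 0].set_ylabel("ΔF/F")
        for j in (0, 1):
            axes[i, j].axvspan(STEP_ONSET, STEP_OFFSET, color="0.9", zorder=0)
            axes[i, j].set_xlabel("time (s)")
            axes[i, j].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_model_panels(panels, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, (mode, df) in zip(axes, sorted(panels.items())):
        for col in df.columns:
            if col == "time":
                continue
            ax.plot(df["time"], df[col], label=col)
        ax.set_title(f"{mode} nonlinearity (normalized)")
        ax.set_xlabel("time (s)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Run the configured experiment end to end, writing all artifacts to
    ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    log.info("experiment %s (seed %d) -> %s", config.experiment, config.seed, out)

    if config.experiment == "fig4_model_only":
        panels = model_only_panels(config.model_overrides)
        for mode, df in panels.items():
            df.to_csv(out / f"model_{mode}_nl.csv", index=False)
        if config.make_plots:
            _plot_model_panels(panels, out / "model_panels.png")
        log.info("model-only run finished in %.1f s", time.time() - t_start)
        return ExperimentResult(
            config=config,
            recordings=[],
            qc=pd.DataFrame(),
            condition_stats=[],
            condition_table=pd.DataFrame(),
            tests=pd.DataFrame(),
        )

    recordings = simulate_experiment(config)
    synthetic.save_recordings(out / "recordings.h5", recordings)
    synthetic.manifest(recordings).to_csv(out / "manifest.csv", index=False)
    log.info("simulated %d trial recordings", len(recordings))

    qc, stats_list, tests = analyze_recordings(recordings, seed=config.seed)
    qc.to_csv(out / "qc.csv", index=False)
    table = metrics.condition_frame(stats_list)
    table.to_csv(out / "condition_summary.csv", index=False)
    tests.to_csv(out / "stats_tests.csv", index=False)
    per_cell = pd.concat(
        [
            pd.DataFrame(
                {
                    "cell_type": s.cell_type,
                    "condition": s.condition,
                    "step_amplitude": s.step_amplitude,
                    "cell_index": np.arange(s.n_cells),
                    "peak_dff": s.per_cell_peaks,
                    "relative_peak_pct": s.per_cell_relative,
                    "decay_level_pct": s.per_cell_decay,
                }
            )
            for s in stats_list
        ],
        ignore_index=True,
    )
    per_cell.to_csv(out / "per_cell_metrics.csv", index=False)

    rf_table = None
    if config.n_mapping_cells > 0:
        rf_table = map_receptive_fields(config)
        rf_table.to_csv(out / "rf_mapping.csv", index=False)

    if config.make_plots:
        _plot_condition_traces(stats_list, out / "condition_traces.png")
    log.info(
        "%d cells x condition summaries, %d tests; finished in %.1f s",
        len(stats_list), len(tests), time.time() - t_start,
    )
    return ExperimentResult(
        config=config,
        recordings=recordings,
        qc=qc,
        condition_stats=stats_list,
        condition_table=table,
        tests=tests,
        rf_table=rf_table,
    )
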