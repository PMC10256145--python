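"""Response metrics, per-condition summaries and statistics.

Metrics follow the reporting conventions for center-step responses:

* **peak amplitude** — maximum of the (baseline-subtracted) ΔF/F trace
  inside the stimulation window;
* **relative peak** — a condition's per-cell peak as a percentage of the
  same cell's peak in the reference (gray-surround) condition;
* **decay level** — mean response between 0.9 s and 1.1 s after step
  onset as a percentage of the condition's own peak: the kinetics metric
  (low values = transient/fast responses).

Uncertainty is summarized by bootstrap 68% confidence intervals over
cells (1,000 resamples, percentile method) and condition differences are
compared with two-tailed Mann-Whitney U tests at the 5% level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateResponseError

__all__ = [
    "ConditionStats",
    "TestResult",
    "peak_amplitude",
    "decay_level",
    "summarize_condition",
    "bootstrap_ci",
    "mann_whitney",
    "condition_frame",
    "tests_frame",
]

DECAY_WINDOW = (0.9, 1.1)  # seconds after step onset
BOOTSTRAP_RESAMPLES = 1000
CI_LEVEL = 0.68
ALPHA = 0.05


# --------------------------------------------------------------------------
# Per-trace metrics
# --------------------------------------------------------------------------

def _baseline(values: np.ndarray, times: np.ndarray, baseline_end: float) -> float:
    mask = (times >= baseline_end - 1.0) & (times < baseline_end)
    return float(values[mask].mean()) if mask.any() else 0.0


def peak_amplitude(
    values: np.ndarray,
    sample_rate: float,
    window: tuple[float, float],
    baseline_end: float | None = None,
    t0: float = 0.0,
) -> float:
    """Maximum baseline-subtracted response inside the stimulation window.

    The baseline is the mean over the 1 s preceding ``baseline_end``
    (by default 1 s before step onset, i.e. the dynamics-onset time of the
    step protocol) and is subtracted before taking the maximum.
    """
    values = np.asarray(values, dtype=float)
    times = t0 + np.arange(values.size) / sample_rate
    onset, offset = window
    if offset <= onset:
        raise ValueError("window must have positive extent")
    mask = (times >= onset) & (times <= offset)
    if not mask.any():
        raise ValueError("stimulation window contains no samples")
    if baseline_end is None:
        baseline_end = onset - 1.0
    return float(values[mask].max() - _baseline(values, times, baseline_end))


def decay_level(
    values: np.ndarray,
    sample_rate: float,
    step_onset: float,
    step_offset: float | None = None,
    baseline_end: float | None = None,
    t0: float = 0.0,
) -> float:
    """End-of-step response as a percentage of the trace's own peak.

    Mean of the baseline-subtracted trace over samples whose centers lie in
    the closed interval [step_onset + 0.9 s, step_onset + 1.1 s], divided by
    the peak amplitude over the step window, in percent.
    """
    values = np.asarray(values, dtype=float)
    times = t0 + np.arange(values.size) / sample_rate
    if step_offset is None:
        step_offset = step_onset + 1.0
    lo, hi = step_onset + DECAY_WINDOW[0], step_onset + DECAY_WINDOW[1]
    if times.size == 0 or times[-1] < hi:
        raise ValueError("trace does not cover the decay window")
    if baseline_end is None:
        baseline_end = step_onset - 1.0
    peak = peak_amplitude(
        values, sample_rate, (step_onset, step_offset), baseline_end, t0
    )
    if peak <= 0:
        raise DegenerateResponseError("non-positive peak; decay level undefined")
    base = _baseline(values, times, baseline_end)
    mask = (times >= lo) & (times <= hi)
    return float(100.0 * (values[mask].mean() - base) / peak)


# --------------------------------------------------------------------------
# Bootstrap and rank test
# --------------------------------------------------------------------------

def bootstrap_ci(
    values: Sequence[float],
    n_resamples: int = BOOTSTRAP_RESAMPLES,
    level: float = CI_LEVEL,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean (default 68%: 16th-84th)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    means = values[idx].mean(axis=1)
    lo_q = 100 * (1 - level) / 2
    return (
        float(np.percentile(means, lo_q)),
        float(np.percentile(means, 100 - lo_q)),
    )


@dataclass
class TestResult:
    """Two-tailed Mann-Whitney U comparison."""

    u_statistic: float
    p_value: float
    n1: int
    n2: int
    two_tailed: bool = True
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def stars(self) -> str:
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < self.alpha:
            return "*"
        return "NS"


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    U is computed from rank sums with midranks for ties; the reported U is
    that of the first sample.  The p-value is exact (full null distribution)
    for min(n1, n2) <= 8 without ties, otherwise the normal approximation
    with tie correction and continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=int(a.size),
        n2=int(b.size),
    )


# --------------------------------------------------------------------------
# Condition summaries
# --------------------------------------------------------------------------

@dataclass
class ConditionStats:
    """Per-cell-type, per-condition response summary.

    ``per_cell_*`` arrays are ordered by cell; ``relative_peak`` and
    ``decay_level`` are across-cell means in percent with bootstrap 68%
    CIs.  ``mean_trace`` is the cell average of per-cell peak-normalized
    trial-averaged traces.
    """

    cell_type: str
    condition: str
    step_amplitude: float
    per_cell_peaks: np.ndarray
    per_cell_relative: np.ndarray
    per_cell_decay: np.ndarray
    relative_peak: float
    decay_level: float
    ci68_relative: tuple[float, float]
    ci68_decay: tuple[float, float]
    n_cells: int
    n_flies: int
    mean_trace: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("need at least one cell")
        for name in ("ci68_relative", "ci68_decay"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} bounds out of order")


def summarize_condition(
    traces_by_cell: Mapping[int, np.ndarray],
    reference_by_cell: Mapping[int, np.ndarray],
    sample_rate: float,
    step_onset: float,
    step_offset: float,
    baseline_end: float | None = None,
    cell_type: str = "",
    condition: str = "",
    step_amplitude: float = 1.0,
    n_flies: int | None = None,
    fly_by_cell: Mapping[int, int] | None = None,
    seed: int = 0,
) -> ConditionStats:
    """Summarize one condition of one cell type across cells.

    ``traces_by_cell`` maps cell id to the cell's trial-averaged ΔF/F trace
    for this condition; ``reference_by_cell`` holds the same cells' traces
    for the reference (gray-surround) condition used for relative peaks.
    Every cell must appear in both.
    """
    from .errors import ConfigurationError

    cells = sorted(traces_by_cell)
    missing = [c for c in cells if c not in reference_by_cell]
    if missing:
        raise ConfigurationError(
            f"cells missing the reference condition: {missing}"
        )
    peaks, relatives, decays, normed = [], [], [], []
    for cid in cells:
        tr = np.asarray(traces_by_cell[cid], dtype=float)
        ref = np.asarray(reference_by_cell[cid], dtype=float)
        peak = peak_amplitude(
            tr, sample_rate, (step_onset, step_offset), baseline_end
        )
        ref_peak = peak_amplitude(
            ref, sample_rate, (step_onset, step_offset), baseline_end
        )
        if ref_peak <= 0:
            raise DegenerateResponseError(
                f"cell {cid}: non-positive reference peak"
            )
        peaks.append(peak)
        relatives.append(100.0 * peak / ref_peak)
        decays.append(
            decay_level(tr, sample_rate, step_onset, step_offset, baseline_end)
        )
        normed.append(tr / peak if peak > 0 else tr)
    peaks = np.array(peaks)
    relatives = np.array(relatives)
    decays = np.array(decays)
    if fly_by_cell is not None:
        n_flies_eff = len({fly_by_cell[c] for c in cells})
    else:
        n_flies_eff = n_flies if n_flies is not None else len(cells)
    return ConditionStats(
        cell_type=cell_type,
        condition=condition,
        step_amplitude=step_amplitude,
        per_cell_peaks=peaks,
        per_cell_relative=relatives,
        per_cell_decay=decays,
        relative_peak=float(relatives.mean()),
        decay_level=float(decays.mean()),
        ci68_relative=bootstrap_ci(relatives, seed=seed),
        ci68_decay=bootstrap_ci(decays, seed=seed + 1),
        n_cells=len(cells),
        n_flies=n_flies_eff,
        mean_trace=np.mean(normed, axis=0),
        sample_rate=sample_rate,
    )


# --------------------------------------------------------------------------
# Tidy tables
# --------------------------------------------------------------------------

def condition_frame(stats: Sequence[ConditionStats]) -> pd.DataFrame:
    """One summary row per cell type x condition."""
    return pd.DataFrame(
        [
            {
                "cell_type": s.cell_type,
                "condition": s.condition,
                "step_amplitude": s.step_amplitude,
                "n_cells": s.n_cells,
                "n_flies": s.n_flies,
                "peak_dff_mean": float(s.per_cell_peaks.mean()),
                "relative_peak_pct": s.relative_peak,
                "relative_peak_ci_lo": s.ci68_relative[0],
                "relative_peak_ci_hi": s.ci68_relative[1],
                "decay_level_pct": s.decay_level,
                "decay_ci_lo": s.ci68_decay[0],
                "decay_ci_hi": s.ci68_decay[1],
            }
            for s in stats
        ]
    )


def tests_frame(
    rows: Sequence[tuple[str, str, str, str, TestResult]]
) -> pd.DataFrame:
    """Stats table: (cell_type, metric, condition_a, condition_b, result)."""
    return pd.DataFrame(
        [
            {
                "cell_type": ct,
                "metric": metric,
                "condition_a": ca,
                "condition_b": cb,
                "U": r.u_statistic,
                "p": r.p_value,
                "n1": r.n1,
                "n2": r.n2,
                "significance": r.stars,
            }
            for ct, metric, ca, cb, r in rows
        ]
    )
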