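"""Phosphofructokinase activity from A340 absorbance time series.

In the coupled assay, PFK product flux is converted into an NADH
absorbance change at 340 nm, so enzyme activity is the slope of the
linear portion of the absorbance-vs-time curve.  "Linear portion" is
found by a sliding-window search: every contiguous window spanning the
configured number of minutes is fit by ordinary least squares, and the
window maximizing |slope| among those with r^2 >= 0.95 is reported
(falling back to the best-r^2 window when none qualifies).  Activity is
|slope| — the module is agnostic about whether the cascade consumes or
produces NADH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import KineticTrace, PipelineError

R2_GATE = 0.95
MIN_POINTS = 5


@dataclass
class PfkActivityResult:
    embryo_id: str
    genotype: str
    slope: float
    window: tuple[float, float]
    r_squared: float
    flagged: bool = False
    r2_gate_met: bool = True

    @property
    def activity(self) -> float:
        """Unsigned rate, ΔA340 per minute."""
        return abs(self.slope)


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and r^2 of y ~ t; r^2 is 0 for a flat response."""
    t_c = t - t.mean()
    denom = (t_c**2).sum()
    slope = float((t_c * y).sum() / denom)
    fitted = y.mean() + slope * t_c
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return slope, 0.0
    ss_res = float(((y - fitted) ** 2).sum())
    return slope, 1.0 - ss_res / ss_tot


def candidate_windows(time_min: np.ndarray, window_minutes: float) -> list[tuple[int, int]]:
    """Minimal contiguous index windows [i, j] spanning >= window_minutes."""
    windows = []
    for i in range(len(time_min)):
        span = time_min - time_min[i]
        reach = np.nonzero(span >= window_minutes)[0]
        if len(reach) == 0:
            break
        j = int(reach[0])
        if j - i + 1 >= MIN_POINTS:
            windows.append((i, j))
    return windows


def fit_linear_region(
    trace: KineticTrace, window_minutes: float = 10.0, r2_gate: float = R2_GATE
) -> PfkActivityResult:
    """Slope of the best linear window of the trace.

    Among windows with r^2 >= ``r2_gate`` the one with the largest |slope|
    wins (earliest start breaks ties); if none passes the gate, the window
    with the highest r^2 is reported with ``r2_gate_met`` False.  An
    all-constant trace yields slope 0, r^2 reported as 0, and a flag.
    """
    t, y = trace.time_min, trace.a340
    if np.ptp(y) == 0:
        return PfkActivityResult(
            trace.embryo_id, trace.genotype, 0.0, (float(t[0]), float(t[-1])), 0.0,
            flagged=True, r2_gate_met=False,
        )
    windows = candidate_windows(t, window_minutes)
    if not windows:
        raise PipelineError(
            f"trace {trace.embryo_id}: no window of {window_minutes} min with >= {MIN_POINTS} points"
        )
    fits = [(_ols(t[i : j + 1], y[i : j + 1]), (i, j)) for i, j in windows]
    gated = [((s, r2), w) for (s, r2), w in fits if r2 >= r2_gate]
    if gated:
        (slope, r2), (i, j) = max(gated, key=lambda f: (abs(f[0][0]), -f[1][0]))
        gate_met = True
    else:
        (slope, r2), (i, j) = max(fits, key=lambda f: (f[0][1], -f[1][0]))
        gate_met = False
    return PfkActivityResult(
        trace.embryo_id, trace.genotype, slope, (float(t[i]), float(t[j])), r2,
        flagged=False, r2_gate_met=gate_met,
    )


def activity_fold_change(
    results_wt: list[PfkActivityResult], results_ko: list[PfkActivityResult]
) -> tuple[float, float]:
    """Mean KO activity over mean WT activity plus a two-sided t-test p.

    Activities are |slope| per embryo.  A zero wild-type mean leaves the
    ratio undefined (NaN).
    """
    if len(results_wt) < 2 or len(results_ko) < 2:
        raise PipelineError("need at least 2 embryos per genotype")
    wt = np.array([r.activity for r in results_wt])
    ko = np.array([r.activity for r in results_ko])
    ratio = ko.mean() / wt.mean() if wt.mean() else float("nan")
    if np.ptp(np.concatenate([wt, ko])) == 0:
        return float(ratio), 1.0
    p = float(stats.ttest_ind(ko, wt).pvalue)
    return float(ratio), p
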