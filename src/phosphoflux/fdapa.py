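"""Spindle-microtubule turnover from fluorescence dissipation after
photoactivation (FDAPA).

Photoactivated GFP-tubulin marks within one half-spindle lose fluorescence
as microtubules turn over.  Two microtubule populations co-exist: free
spindle microtubules turn over fast, kinetochore-attached microtubules
(k-MTs) slowly.  After background subtraction, photobleaching correction and
normalization to the first post-activation frame, the intensity decay is fit
with the two-population model

    I(t) = A1 * exp(-k1 * t) + A2 * exp(-k2 * t),   k1 > k2 > 0

where (A1, k1) describe the fast non-k-MT population and (A2, k2) the slow
k-MT population.  Turnover half-lives are ln(2)/k per population, and
conditions are compared by an unpaired two-tailed Welch t-test on per-cell
statistics (by default the k-MT half-life).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    UnusableTraceError,
)

#: optimizer box constraints: amplitudes in [0, 1.5], rates in [1e-5, 1] /s
AMP_BOUNDS = (0.0, 1.5)
RATE_BOUNDS = (1e-5, 1.0)

__all__ = [
    "FluorescenceTrace",
    "DoubleExpFit",
    "TurnoverComparison",
    "read_traces",
    "write_traces",
    "correct_trace",
    "fit_double_exponential",
    "fit_trace",
    "fit_traces",
    "half_life",
    "compare_turnover",
]


@dataclass
class FluorescenceTrace:
    """One cell's photoactivation time course.

    ``t`` is seconds from the first post-activation frame (t0 = 0);
    ``intensity`` is the mean pixel intensity of the activated region,
    ``background`` the mean intensity of an equally sized contralateral
    region on the non-activated half-spindle, and ``bleach_ref`` an optional
    whole-spindle reference used for photobleaching correction.
    """

    cell_id: str
    condition: str
    phase: str
    t: np.ndarray
    intensity: np.ndarray
    background: np.ndarray
    bleach_ref: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.bleach_ref is not None:
            self.bleach_ref = np.asarray(self.bleach_ref, dtype=float)
        if self.t.size < 5:
            raise UnusableTraceError(
                f"trace {self.cell_id}: need >=5 timepoints, got {self.t.size}"
            )
        if np.any(np.diff(self.t) <= 0):
            raise UnusableTraceError(f"trace {self.cell_id}: t must be strictly increasing")


@dataclass
class DoubleExpFit:
    """Fitted two-population decay parameters and derived half-lives."""

    A1: float
    k1: float
    A2: float
    k2: float
    r_squared: float
    converged: bool
    n_starts_used: int
    t_half_fast: float = field(init=False)
    t_half_slow: float = field(init=False)

    def __post_init__(self) -> None:
        if self.converged:
            self.t_half_fast = half_life(self.k1)
            self.t_half_slow = half_life(self.k2)
        else:
            self.t_half_fast = float("nan")
            self.t_half_slow = float("nan")


@dataclass
class TurnoverComparison:
    """Unpaired two-group comparison of a per-cell turnover statistic."""

    group_a: str
    group_b: str
    statistic: str
    values_a: list[float]
    values_b: list[float]
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    p_value: float
    excluded_cells: list[str] = field(default_factory=list)


TRACE_COLUMNS = ["cell_id", "condition", "phase", "t_s", "intensity", "background", "bleach_ref"]


def read_traces(path) -> list[FluorescenceTrace]:
    """Read long-format CSV (cell_id, condition, phase, t_s, intensity,
    background[, bleach_ref]) into per-cell traces."""
    table = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS[:6] if c not in table.columns]
    if missing:
        raise ConfigurationError(f"trace file {path} missing columns {missing}")
    traces = []
    for cell_id, grp in table.groupby("cell_id", sort=False):
        grp = grp.sort_values("t_s")
        bleach = None
        if "bleach_ref" in grp.columns and grp["bleach_ref"].notna().all():
            bleach = grp["bleach_ref"].to_numpy(float)
        traces.append(
            FluorescenceTrace(
                cell_id=str(cell_id),
                condition=str(grp["condition"].iloc[0]),
                phase=str(grp["phase"].iloc[0]),
                t=grp["t_s"].to_numpy(float),
                intensity=grp["intensity"].to_numpy(float),
                background=grp["background"].to_numpy(float),
                bleach_ref=bleach,
            )
        )
    return traces


def write_traces(traces: list[FluorescenceTrace], path) -> None:
    """Write traces back to the long CSV format consumed by read_traces."""
    rows = []
    for tr in traces:
        for i, t in enumerate(tr.t):
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "condition": tr.condition,
                    "phase": tr.phase,
                    "t_s": t,
                    "intensity": tr.intensity[i],
                    "background": tr.background[i],
                    "bleach_ref": tr.bleach_ref[i] if tr.bleach_ref is not None else np.nan,
                }
            )
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


def correct_trace(
    trace: FluorescenceTrace,
    bleach_mode: str = "auto",
    bleach_constant: float | None = None,
) -> np.ndarray:
    """Background-correct, photobleach-correct, and normalize a trace.

    corrected(t) = (intensity(t) - background(t)) / bleach_factor(t),
    then divided by its t0 value so corrected(t0) = 1.  The bleach factor is
    the whole-spindle reference normalized to its own t0 (``reference``),
    an exponential exp(-c t) with user constant c (``exponential_constant``),
    or 1 (``none``).  ``auto`` picks ``reference`` when a bleach reference is
    present, else ``none``.
    """
    if bleach_mode == "auto":
        bleach_mode = "reference" if trace.bleach_ref is not None else "none"
    signal = trace.intensity - trace.background
    if bleach_mode == "reference":
        if trace.bleach_ref is None:
            raise ConfigurationError(
                f"trace {trace.cell_id}: bleach_mode='reference' needs bleach_ref"
            )
        if trace.bleach_ref[0] <= 0:
            raise UnusableTraceError(f"trace {trace.cell_id}: non-positive bleach reference at t0")
        factor = trace.bleach_ref / trace.bleach_ref[0]
    elif bleach_mode == "exponential_constant":
        if bleach_constant is None:
            raise ConfigurationError("bleach_mode='exponential_constant' needs bleach_constant")
        factor = np.exp(-bleach_constant * trace.t)
    elif bleach_mode == "none":
        factor = np.ones_like(trace.t)
    else:
        raise ConfigurationError(f"unknown bleach_mode {bleach_mode!r}")
    corrected = signal / factor
    if corrected[0] <= 0:
        raise UnusableTraceError(
            f"trace {trace.cell_id}: corrected intensity at t0 is {corrected[0]:.3g} <= 0"
        )
    return corrected / corrected[0]


def _model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    a1, k1, a2, k2 = params
    return a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Deterministic initializer: log-linear fit of the tail for the slow
    component, then of the early residual for the fast component."""
    n = t.size
    tail = slice(max(n - max(n // 3, 3), 2), n)
    yt = np.clip(y[tail], 1e-9, None)
    slope, inter = np.polyfit(t[tail], np.log(yt), 1)
    k_slow = float(np.clip(-slope, *RATE_BOUNDS))
    a_slow = float(np.clip(np.exp(inter), *AMP_BOUNDS))
    resid = np.clip(y - a_slow * np.exp(-k_slow * t), 1e-9, None)
    head = slice(0, max(n // 3, 3))
    slope_f, inter_f = np.polyfit(t[head], np.log(resid[head]), 1)
    k_fast = float(np.clip(-slope_f, k_slow * 1.001, RATE_BOUNDS[1]))
    a_fast = float(np.clip(np.exp(inter_f), *AMP_BOUNDS))
    return np.array([a_fast, k_fast, a_slow, k_slow])


def fit_double_exponential(
    t,
    corrected,
    constrain_sum: bool = False,
    n_starts: int = 20,
    seed: int = 0,
) -> DoubleExpFit:
    """Bounded multi-start least-squares fit of the two-population decay.

    Amplitudes are bounded to [0, 1.5] and rates to [1e-5, 1] /s; the
    reported components always satisfy k1 > k2 (labels are swapped post hoc
    if the optimizer converges with the order reversed).  The first start is
    the deterministic tail/residual initializer; the remaining
    ``n_starts - 1`` starts apply seeded log-normal jitter to it, because
    double-exponential least squares is multimodal.  ``constrain_sum``
    enforces A1 + A2 = 1 (fitting A1, k1, k2 only).  r² is 1 - SS_res/SS_tot.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(corrected, dtype=float)
    if t.size != y.size:
        raise ConfigurationError("t and corrected must have equal length")
    if t.size < 5:
        raise InsufficientDataError(f"need >=5 points to fit 4 parameters, got {t.size}")

    rng = np.random.default_rng(seed)
    guess = _initial_guess(t, y)
    lo = np.array([AMP_BOUNDS[0], RATE_BOUNDS[0], AMP_BOUNDS[0], RATE_BOUNDS[0]])
    hi = np.array([AMP_BOUNDS[1], RATE_BOUNDS[1], AMP_BOUNDS[1], RATE_BOUNDS[1]])

    if constrain_sum:
        def residuals(p):
            a1, k1, k2 = p
            return _model(np.array([a1, k1, 1.0 - a1, k2]), t) - y
        lo_c = np.array([0.0, RATE_BOUNDS[0], RATE_BOUNDS[0]])
        hi_c = np.array([1.0, RATE_BOUNDS[1], RATE_BOUNDS[1]])
    else:
        def residuals(p):
            return _model(p, t) - y

    # a later start must beat the incumbent by a real margin, so the
    # deterministic initializer wins cost ties in degenerate (effectively
    # single-exponential) cases instead of an arbitrary amplitude split
    ss_tot_scale = float(np.sum(y**2))
    min_gain = 1e-14 * max(ss_tot_scale, 1.0)

    best = None
    used = 0
    for i in range(max(n_starts, 1)):
        p0 = guess if i == 0 else np.clip(
            guess * rng.lognormal(0.0, 0.6, size=4), lo + 1e-12, hi
        )
        if constrain_sum:
            p0c = np.clip(np.array([p0[0], p0[1], p0[3]]), lo_c + 1e-12, hi_c)
            args = (p0c, lo_c, hi_c)
        else:
            args = (p0, lo, hi)
        try:
            res = optimize.least_squares(
                residuals, args[0], bounds=(args[1], args[2]),
                method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000,
            )
        except Exception:
            continue
        used = i + 1
        if res.success and (best is None or res.cost < best.cost - min_gain):
            best = res

    if best is None:
        return DoubleExpFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, used)

    if constrain_sum:
        a1, k1, k2 = best.x
        params = np.array([a1, k1, 1.0 - a1, k2])
    else:
        params = best.x
    a1, k1, a2, k2 = params
    if k1 < k2:  # enforce fast-first labelling regardless of optimizer path
        a1, k1, a2, k2 = a2, k2, a1, k1
    ss_res = float(np.sum((_model(np.array([a1, k1, a2, k2]), t) - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-20 else 0.0)
    return DoubleExpFit(float(a1), float(k1), float(a2), float(k2), r2, True, used)


def fit_trace(
    trace: FluorescenceTrace,
    bleach_mode: str = "auto",
    bleach_constant: float | None = None,
    **fit_kwargs,
) -> DoubleExpFit:
    """Correct one trace and fit the double-exponential decay."""
    corrected = correct_trace(trace, bleach_mode=bleach_mode, bleach_constant=bleach_constant)
    return fit_double_exponential(trace.t, corrected, **fit_kwargs)


def fit_traces(
    traces: list[FluorescenceTrace],
    bleach_mode: str = "auto",
    bleach_constant: float | None = None,
    constrain_sum: bool = False,
    n_starts: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit every trace; returns one row per cell with parameters, half-lives,
    r² and convergence status.  Uncorrectable traces appear with
    converged=False rather than aborting the batch."""
    rows = []
    for i, tr in enumerate(traces):
        try:
            fit = fit_trace(
                tr,
                bleach_mode=bleach_mode,
                bleach_constant=bleach_constant,
                constrain_sum=constrain_sum,
                n_starts=n_starts,
                seed=seed + i,
            )
        except (UnusableTraceError, InsufficientDataError):
            fit = DoubleExpFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, 0)
        rows.append(
            {
                "cell_id": tr.cell_id,
                "condition": tr.condition,
                "phase": tr.phase,
                "A1": fit.A1,
                "k1": fit.k1,
                "A2": fit.A2,
                "k2": fit.k2,
                "t_half_fast": fit.t_half_fast,
                "t_half_slow": fit.t_half_slow,
                "r_squared": fit.r_squared,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def half_life(k: float) -> float:
    """Turnover half-life ln(2)/k in seconds for decay rate k (per second)."""
    if k <= 0:
        raise ValueError(f"half-life requires k > 0, got {k}")
    return float(np.log(2.0) / k)


def compare_turnover(
    fits: pd.DataFrame,
    group_a: str,
    group_b: str,
    by: str = "condition",
    statistic: str = "t_half_slow",
    r2_min: float = 0.8,
) -> TurnoverComparison:
    """Unpaired two-tailed Welch t-test of a per-cell turnover statistic.

    Cells whose fit did not converge or whose r² falls below ``r2_min`` are
    excluded from the comparison and listed in the result.  Raises
    :class:`InsufficientDataError` if fewer than two usable cells remain in
    either group.
    """
    if statistic not in fits.columns:
        raise ConfigurationError(f"unknown statistic {statistic!r}")
    usable = fits["converged"].astype(bool) & (fits["r_squared"] >= r2_min)
    excluded = fits.loc[~usable, "cell_id"].astype(str).tolist()
    kept = fits[usable]
    a = kept.loc[kept[by] == group_a, statistic].to_numpy(float)
    b = kept.loc[kept[by] == group_b, statistic].to_numpy(float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"need >=2 converged fits per group, got {a.size} ({group_a}) "
            f"and {b.size} ({group_b})"
        )
    res = stats.ttest_ind(a, b, equal_var=False, alternative="two-sided")
    return TurnoverComparison(
        group_a=group_a,
        group_b=group_b,
        statistic=statistic,
        values_a=a.tolist(),
        values_b=b.tolist(),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(stats.sem(a)),
        sem_b=float(stats.sem(b)),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        excluded_cells=excluded,
    )
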