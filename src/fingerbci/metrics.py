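"""Online performance metrics, individuation, and dimensionality.

Definitions follow the standard target-acquisition conventions of the
finger-BCI literature:

* time to target: cue to the first moment every DOF is inside its target;
* acquisition time: cue to the final target entry (the start of the
  successful hold; the hold itself is excluded);
* orbiting time: acquisition time minus time to target — time spent
  re-acquiring after overshoots;
* path-length efficiency: net displacement divided by the path actually
  traversed in joint space (in [0, 1] by the triangle inequality);
* throughput: Fitts-law bits, ``sum over cued DOF of log2(D/W + 1)``,
  divided by acquisition time, averaged over successful trials;
* participation ratio: ``(sum lambda)^2 / sum lambda^2`` over covariance
  eigenvalues of the population activity — an effective dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

from .population import BIN_WIDTH_S
from .tasks import TrialRecord, finger_groups

__all__ = [
    "TrialMetrics",
    "trial_metrics",
    "SessionSummary",
    "session_metrics",
    "individuation",
    "DimensionalityResult",
    "participation_ratio",
    "normalized_cc",
    "two_sample_ttest",
    "GO_WINDOW",
]

GO_WINDOW = (0.2, 0.7)  # s after cue: the reaction-to-movement period


@dataclass(frozen=True)
class TrialMetrics:
    acquisition_time: float | None
    time_to_target: float | None
    orbiting_time: float | None
    path_length_efficiency: float | None
    success: bool
    fitts_bits: float


def _inside_samples(record: TrialRecord) -> np.ndarray:
    pos = np.asarray(record.positions)
    return np.all(record.target_set.inside(pos), axis=1)


def trial_metrics(record: TrialRecord, fitts_variant: str = "shannon") -> TrialMetrics:
    """Per-trial timing, efficiency and Fitts index of difficulty.

    Times are recomputed from the per-bin trajectory.  Entry times are
    credited at the start of the first inside bin so that
    ``acquisition_time = time_to_target + orbiting_time`` holds exactly and
    ``completion - acquisition`` equals the hold requirement.  Failed trials
    get undefined (None) acquisition fields.
    """
    pos = np.asarray(record.positions, dtype=float)
    if pos.ndim != 2 or len(pos) < 2:
        raise ValueError("record must contain a per-bin trajectory")
    ts = record.target_set
    inside = _inside_samples(record)[1:]  # sample k+1 = end of bin k
    hold_bins = int(round(ts.hold_required / BIN_WIDTH_S))

    first_entry = None
    last_entry = None
    streak = 0
    success = False
    for k, ok in enumerate(inside):
        if ok:
            if streak == 0:
                streak_start = k
            if first_entry is None:
                first_entry = k * BIN_WIDTH_S
            streak += 1
            if streak >= hold_bins:
                last_entry = streak_start * BIN_WIDTH_S
                success = True
                break
        else:
            streak = 0

    # Fitts bits use the per-DOF cued distances at the cue
    cued_axes = _cued_axes(record)
    d_axes = np.abs(ts.centers[cued_axes] - pos[0, cued_axes])
    if fitts_variant == "shannon":
        bits = float(np.sum(np.log2(d_axes / ts.width + 1.0)))
    elif fitts_variant == "welford":
        bits = float(np.sum(np.log2(d_axes / ts.width + 0.5)))
    else:
        raise ValueError("fitts_variant must be 'shannon' or 'welford'")

    if not success:
        return TrialMetrics(None, None, None, None, False, bits)

    end_sample = streak_start + hold_bins  # sample index where hold completed
    moved = pos[: end_sample + 1]
    deltas = np.diff(moved, axis=0)
    path_len = float(np.sum(np.linalg.norm(deltas, axis=1)))
    net = float(np.linalg.norm(moved[-1] - moved[0]))
    eff = 1.0 if path_len == 0.0 else min(1.0, net / path_len)

    t2t = first_entry
    orbiting = last_entry - first_entry
    acq = t2t + orbiting  # additive by construction, exact in fp as well
    return TrialMetrics(acq, t2t, orbiting, eff, True, bits)


def _cued_axes(record: TrialRecord) -> list[int]:
    groups = finger_groups(record.dof_labels)
    cued = record.cued_groups or tuple(groups)
    axes: list[int] = []
    for g in cued:
        axes.extend(groups[g])
    return sorted(axes)


@dataclass(frozen=True)
class SessionSummary:
    n_trials: int
    n_success: int
    percent_completed: float
    targets_per_min: float
    throughput_bps: float | None
    acquisition_time: tuple[float, float] | None   # (mean, sem), s
    time_to_target: tuple[float, float] | None
    orbiting_time: tuple[float, float] | None
    path_length_efficiency: tuple[float, float] | None


def _mean_sem(values: np.ndarray) -> tuple[float, float] | None:
    if len(values) == 0:
        return None
    sem = float(np.std(values, ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return float(np.mean(values)), sem


def session_metrics(records: list[TrialRecord], fitts_variant: str = "shannon") -> SessionSummary:
    """Session-level summary: mean +- SEM of each metric over successful
    trials, acquisition rate (targets/min over total task time), percent
    completed, and Fitts throughput in bits/s."""
    if not records:
        raise ValueError("no trial records")
    per_trial = [trial_metrics(r, fitts_variant) for r in records]
    ok = [m for m in per_trial if m.success]
    total_time_s = float(sum(r.duration for r in records))
    bps = [m.fitts_bits / m.acquisition_time for m in ok if m.acquisition_time and m.acquisition_time > 0]
    return SessionSummary(
        n_trials=len(records),
        n_success=len(ok),
        percent_completed=100.0 * len(ok) / len(records),
        targets_per_min=60.0 * len(ok) / total_time_s if total_time_s > 0 else 0.0,
        throughput_bps=None if not bps else float(np.mean(bps)),
        acquisition_time=_mean_sem(np.array([m.acquisition_time for m in ok])),
        time_to_target=_mean_sem(np.array([m.time_to_target for m in ok])),
        orbiting_time=_mean_sem(np.array([m.orbiting_time for m in ok])),
        path_length_efficiency=_mean_sem(np.array([m.path_length_efficiency for m in ok])),
    )


def individuation(records_single_cue: list[TrialRecord]) -> tuple[np.ndarray, list[str]]:
    """Finger-individuation matrix from one-cued-finger blocks.

    Entry (i, j) is the mean speed of group j during the Go period of trials
    cueing group i, each row normalized by its largest entry.  Perfectly
    individuated control gives an identity-like matrix.
    """
    if not records_single_cue:
        raise ValueError("no trial records")
    groups = finger_groups(records_single_cue[0].dof_labels)
    names = list(groups)
    sums = np.zeros((len(names), len(names)))
    counts = np.zeros(len(names))
    lo, hi = GO_WINDOW
    for rec in records_single_cue:
        if len(rec.cued_groups) != 1:
            raise ValueError("individuation requires exactly one cued group per trial")
        i = names.index(rec.cued_groups[0])
        v = np.asarray(rec.decoded_velocities, dtype=float)
        times = np.arange(len(v)) * BIN_WIDTH_S  # start-of-bin times
        sel = (times >= lo) & (times < hi)
        if not np.any(sel):
            continue
        for j, g in enumerate(names):
            speed = np.linalg.norm(v[np.ix_(sel, list(groups[g]))], axis=1)
            sums[i, j] += float(np.mean(speed))
        counts[i] += 1
    mat = sums / np.where(counts > 0, counts, 1.0)[:, None]
    row_max = mat.max(axis=1, keepdims=True)
    mat = np.divide(mat, row_max, out=np.zeros_like(mat), where=row_max > 0)
    return mat, names


@dataclass(frozen=True)
class DimensionalityResult:
    eigenvalues: np.ndarray
    participation_ratio: float


def participation_ratio(activity: np.ndarray) -> DimensionalityResult:
    """Effective dimensionality of (n_bins, n_channels) population activity.

    Mean-centers the data, eigendecomposes the channel covariance, and
    returns PR = (sum lambda)^2 / sum lambda^2, which lies in
    [1, n_channels].
    """
    x = np.asarray(activity, dtype=float)
    if x.ndim != 2 or len(x) < 2:
        raise ValueError("activity must be (n_bins >= 2, n_channels)")
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (len(x) - 1)
    lam = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
    total = lam.sum()
    if total == 0.0:
        raise ValueError("activity has zero variance")
    return DimensionalityResult(lam[::-1], float(total**2 / np.sum(lam**2)))


def normalized_cc(v_a: np.ndarray, v_b: np.ndarray) -> float:
    """Zero-lag normalized cross-correlation, averaged across DOF.

    Per DOF: <a, b> / (||a|| ||b||), without mean removal.  A DOF with a
    zero-norm trace is undefined (NaN) and excluded from the average; the
    result is NaN if every DOF is undefined.
    """
    a = np.atleast_2d(np.asarray(v_a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(v_b, dtype=float).T).T
    if a.shape != b.shape:
        raise ValueError("traces must have equal shapes")
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    denom = na * nb
    cc = np.full(a.shape[1], np.nan)
    good = denom > 0
    cc[good] = np.sum(a * b, axis=0)[good] / denom[good]
    return float(np.nanmean(cc)) if np.any(good) else float("nan")


def two_sample_ttest(a: np.ndarray, b: np.ndarray):
    """Thin wrapper: two-sample, two-tailed t-test (statistic, p-value)."""
    res = _scipy_stats.ttest_ind(np.asarray(a), np.asarray(b))
    return float(res.statistic), float(res.pvalue)
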