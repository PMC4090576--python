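"""Online analysis operators for trajectory ensembles.

Three filter families operate on the stream of time-cuts produced by the
simulation pipeline:

1. **Summary statistics** — per-cut mean, standard deviation and quantiles.
2. **Trajectory clustering** — each trajectory in a sliding window is
   reduced to a Savitzky-Golay-smoothed value ``x̂`` and a forecast
   ``x^E = x̂ + x̂' Δ_S`` one sampling step ahead along the local trend;
   the (x̂, x^E) feature pairs are partitioned with K-means (cluster count
   known in advance) or quality-threshold (QT) clustering (cluster count
   emergent, bounded cluster diameter).
3. **Peak / frequency detection** — local maxima located through sign
   changes of the SG-estimated derivative; successive peak distances give
   per-trajectory oscillation periods and their ensemble moving average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_coeffs, savgol_filter

from .workflow import TimeCut, WindowBlock

__all__ = [
    "SummaryRecord",
    "FilteredPoint",
    "ClusterAssignment",
    "PeakRecord",
    "summary_stats",
    "savgol_coefficients",
    "filter_and_forecast",
    "kmeans_cluster",
    "qt_cluster",
    "detect_peaks",
    "peak_periods",
    "synth_ensemble",
]


# ---------------------------------------------------------------------------
# (1) summary statistics


@dataclass(frozen=True)
class SummaryRecord:
    time: float
    mean: dict[str, float]
    std: dict[str, float]
    quantiles: dict[str, dict[float, float]]  # species -> level -> value


DEFAULT_LEVELS = (0.05, 0.25, 0.5, 0.75, 0.95)


def summary_stats(cut: TimeCut, levels: tuple[float, ...] = DEFAULT_LEVELS) -> SummaryRecord:
    """Per-species mean, sample standard deviation (n-1) and quantiles.

    Quantiles use linear interpolation between order statistics.  With a
    single trajectory the standard deviation is reported as 0.
    """
    if not cut.values:
        raise ValueError("empty time-cut")
    for q in levels:
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"quantile level out of [0, 1]: {q}")
    mean, std, quant = {}, {}, {}
    for sp, arr in cut.values.items():
        a = np.asarray(arr, dtype=float)
        if a.size == 0:
            raise ValueError("empty time-cut")
        mean[sp] = float(a.mean())
        std[sp] = float(a.std(ddof=1)) if a.size > 1 else 0.0
        qs = np.quantile(a, levels, method="linear")
        quant[sp] = {lv: float(v) for lv, v in zip(levels, qs)}
    return SummaryRecord(cut.time, mean, std, quant)


# ---------------------------------------------------------------------------
# (2) Savitzky-Golay filtering, forecast and clustering


def savgol_coefficients(window: int, order: int, deriv: int = 0) -> np.ndarray:
    """Savitzky-Golay convolution coefficients for the window centre.

    Returned in sample order (``x[i-h] .. x[i+h]``, dot product gives the
    smoothed value).  ``deriv=1`` coefficients are for a unit sample step;
    divide the result of the dot product by Δ_S on application.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if order >= window:
        raise ValueError("polynomial order must be < window length")
    return savgol_coeffs(window, order, deriv=deriv, use="dot")


@dataclass(frozen=True)
class FilteredPoint:
    trajectory_id: int
    smoothed: float
    derivative: float
    forecast: float


def filter_and_forecast(
    window: WindowBlock,
    delta_s: float,
    sg_window: int = 9,
    sg_order: int = 3,
    species: str | None = None,
) -> list[FilteredPoint]:
    """Smoothed centre value, derivative and one-step forecast per trajectory.

    The SG stencil (``sg_window <= Δ_W``, both odd) is applied to the
    central samples of the block; the forecast extrapolates one sampling
    step along the local trend: ``x^E = x̂ + x̂' Δ_S``.
    """
    mat = window.matrix(species)  # (n_traj, Δ_W)
    width = mat.shape[1]
    if sg_window > width:
        raise ValueError(f"sg_window {sg_window} exceeds window length {width}")
    c0 = savgol_coefficients(sg_window, sg_order, 0)
    c1 = savgol_coefficients(sg_window, sg_order, 1)
    lo = (width - sg_window) // 2
    central = mat[:, lo:lo + sg_window].astype(float)
    smoothed = central @ c0
    deriv = (central @ c1) / delta_s
    forecast = smoothed + deriv * delta_s
    return [
        FilteredPoint(tid, float(s), float(d), float(f))
        for tid, s, d, f in zip(window.task_ids, smoothed, deriv, forecast)
    ]


@dataclass(frozen=True)
class ClusterAssignment:
    time: float
    method: str
    labels: tuple[int, ...]          # per trajectory; -1 = unclustered (QT only)
    centers: tuple[tuple[float, ...], ...]
    sizes: tuple[int, ...]
    inertia_history: tuple[float, ...] = ()

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    return pts


def features(filtered: list[FilteredPoint]) -> np.ndarray:
    """Clustering feature matrix: (x̂, x^E) per trajectory."""
    return np.array([[fp.smoothed, fp.forecast] for fp in filtered])


def kmeans_cluster(points, k: int, seed: int = 0, time: float = math.nan,
                   tol: float = 1e-6, max_iter: int = 100) -> ClusterAssignment:
    """Lloyd's K-means with deterministic seeding.

    Initial centers are ``k`` distinct points drawn with the given seed;
    iteration stops when no center moves more than ``tol`` (Euclidean) or
    after ``max_iter`` rounds.  An empty cluster is repaired by reassigning
    the point farthest from its current center.
    """
    pts = _as_points(points)
    n = len(pts)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    centers = pts[rng.choice(n, size=k, replace=False)].copy()
    labels = np.zeros(n, dtype=int)
    history: list[float] = []
    for _ in range(max_iter):
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        assigned = d2[np.arange(n), labels]
        for j in range(k):
            if not np.any(labels == j):
                far = int(assigned.argmax())
                labels[far] = j
                assigned[far] = 0.0
        history.append(float(((pts - centers[labels]) ** 2).sum()))
        new_centers = np.vstack([pts[labels == j].mean(axis=0) for j in range(k)])
        shift = np.linalg.norm(new_centers - centers, axis=1).max()
        centers = new_centers
        if shift <= tol:
            break
    sizes = tuple(int((labels == j).sum()) for j in range(k))
    return ClusterAssignment(
        time=time, method="kmeans",
        labels=tuple(int(x) for x in labels),
        centers=tuple(tuple(float(v) for v in c) for c in centers),
        sizes=sizes, inertia_history=tuple(history),
    )


def qt_cluster(points, diameter_threshold: float, min_size: int = 1,
               time: float = math.nan) -> ClusterAssignment:
    """Quality-threshold clustering (bounded cluster diameter).

    For every remaining point a candidate cluster is grown greedily by the
    point whose inclusion least increases the diameter (maximum pairwise
    Euclidean distance), never exceeding ``diameter_threshold``.  The
    largest candidate is committed (ties: lowest seed index), its members
    removed, and the process repeats until the largest candidate is
    smaller than ``min_size``; leftover points are labelled -1.
    """
    if not diameter_threshold > 0:
        raise ValueError("diameter_threshold must be positive")
    pts = _as_points(points)
    n = len(pts)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return ClusterAssignment(time, "qt", (), (), ())
    dist = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    remaining = np.ones(n, dtype=bool)
    clusters: list[np.ndarray] = []
    while remaining.any():
        best: np.ndarray | None = None
        idx_rem = np.flatnonzero(remaining)
        for seed_idx in idx_rem:
            member = np.zeros(n, dtype=bool)
            member[seed_idx] = True
            # farthest-member distance for every candidate point
            dmax = dist[seed_idx].copy()
            dmax[~remaining] = np.inf
            dmax[seed_idx] = np.inf
            while True:
                j = int(dmax.argmin())
                if dmax[j] > diameter_threshold:
                    break
                member[j] = True
                dmax = np.maximum(dmax, dist[j])
                dmax[j] = np.inf
                dmax[member] = np.inf
            cand = np.flatnonzero(member)
            if best is None or len(cand) > len(best):
                best = cand
        assert best is not None
        if len(best) < min_size:
            break
        labels[best] = len(clusters)
        clusters.append(best)
        remaining[best] = False
    centers = tuple(tuple(float(v) for v in pts[c].mean(axis=0)) for c in clusters)
    sizes = tuple(len(c) for c in clusters)
    return ClusterAssignment(time, "qt", tuple(int(x) for x in labels), centers, sizes)


# ---------------------------------------------------------------------------
# (3) peak / frequency detection


@dataclass(frozen=True)
class PeakRecord:
    trajectory_id: int
    peak_times: tuple[float, ...]

    @property
    def local_periods(self) -> tuple[float, ...]:
        return tuple(np.diff(self.peak_times))


def detect_peaks(
    series,
    delta_s: float,
    sg_window: int = 9,
    sg_order: int = 3,
    min_height_frac: float = 0.1,
    min_separation: int = 2,
    t0: float = 0.0,
) -> tuple[float, ...]:
    """Peak times of a sampled trajectory via SG-derivative sign changes.

    The series is smoothed with a Savitzky-Golay filter; candidate peaks
    sit where the smoothed derivative changes sign + → -, refined to the
    local maximum of the smoothed curve.  Peaks standing less than
    ``min_height_frac`` of the series range above the neighbouring minima
    are discarded, and peaks closer than ``min_separation`` samples are
    merged keeping the higher one.
    """
    y = np.asarray(series, dtype=float)
    if len(y) <= sg_window:
        raise ValueError("series must be longer than sg_window")
    smooth = savgol_filter(y, sg_window, sg_order, mode="interp")
    deriv = savgol_filter(y, sg_window, sg_order, deriv=1, delta=delta_s, mode="interp")

    crossings = np.flatnonzero((deriv[:-1] > 0) & (deriv[1:] <= 0))
    half = sg_window // 2
    cand: list[int] = []
    for i in crossings:
        lo, hi = max(0, i - half), min(len(y), i + half + 2)
        j = lo + int(smooth[lo:hi].argmax())
        if 0 < j < len(y) - 1 and (not cand or j != cand[-1]):
            cand.append(j)

    # prominence rule: height above the larger neighbouring minimum
    rng = float(smooth.max() - smooth.min())
    if rng == 0.0:
        return ()
    kept: list[int] = []
    bounds = [0, *cand, len(y) - 1]
    for k, j in enumerate(cand):
        left_min = smooth[bounds[k]:j + 1].min()
        right_min = smooth[j:bounds[k + 2] + 1].min()
        if smooth[j] - max(left_min, right_min) >= min_height_frac * rng:
            kept.append(j)

    merged: list[int] = []
    for j in kept:
        if merged and j - merged[-1] < min_separation:
            if smooth[j] > smooth[merged[-1]]:
                merged[-1] = j
        else:
            merged.append(j)
    return tuple(t0 + j * delta_s for j in merged)


def peak_periods(
    peak_records: list[PeakRecord],
    moving_average_window: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble moving-average period series from per-trajectory peaks.

    Each trajectory contributes its successive peak-time differences
    (local periods) timestamped at the later peak; the pooled periods are
    sorted by time and smoothed with a centred moving average.  Returns
    ``(times, period_ma)``; trajectories with fewer than two peaks
    contribute nothing.
    """
    events: list[tuple[float, float]] = []
    for rec in peak_records:
        pt = rec.peak_times
        for a, b in zip(pt[:-1], pt[1:]):
            events.append((b, b - a))
    if not events:
        return np.array([]), np.array([])
    events.sort()
    times = np.array([t for t, _ in events])
    periods = np.array([p for _, p in events])
    w = max(1, min(moving_average_window, len(periods)))
    kernel = np.ones(w)
    ma = np.convolve(periods, kernel, mode="same") / np.convolve(
        np.ones_like(periods), kernel, mode="same"
    )
    return times, ma


def mean_period(peak_records: list[PeakRecord]) -> float:
    """Mean of all local (inter-peak) periods across the ensemble."""
    periods = [p for rec in peak_records for p in rec.local_periods]
    if not periods:
        return math.nan
    return float(np.mean(periods))


# ---------------------------------------------------------------------------
# synthetic ensembles for exercising the analysis operators


def synth_ensemble(kind: str, params: dict | None = None, seed: int = 0):
    """Deterministic synthetic :class:`TimeCut` stream with known structure.

    Kinds: ``constant`` (flat level + noise), ``sinusoid`` (shared period,
    per-trajectory phase 0) and ``bimodal_switcher`` (each trajectory sits
    at one of two modes, switching with a per-step probability).  Values
    are rounded to integers, floored at zero, to mimic molecule counts.
    """
    p = dict(params or {})
    n = int(p.pop("n", 10))
    length = int(p.pop("length", 100))
    delta_s = float(p.pop("delta_s", 1.0))
    noise_sd = float(p.pop("noise_sd", 0.0))
    species = p.pop("species", "X")
    rng = np.random.default_rng(seed)

    if kind == "constant":
        level = float(p.pop("level", 100.0))
        base = np.full((n, length), level)
    elif kind == "sinusoid":
        period = float(p.pop("period", 20.0))
        amplitude = float(p.pop("amplitude", 50.0))
        offset = float(p.pop("offset", 100.0))
        t = np.arange(length) * delta_s
        base = offset + amplitude * np.sin(2 * np.pi * t / period)[None, :].repeat(n, axis=0)
    elif kind == "bimodal_switcher":
        modes = tuple(p.pop("modes", (0.0, 100.0)))
        p_switch = float(p.pop("p_switch", 0.0))
        state = rng.integers(0, 2, size=n)
        cols = []
        for _ in range(length):
            cols.append(np.take(modes, state))
            flip = rng.random(n) < p_switch
            state = np.where(flip, 1 - state, state)
        base = np.array(cols).T
    else:
        raise ValueError(f"unknown synthetic ensemble kind {kind!r}")
    if p:
        raise ValueError(f"unknown parameters for {kind!r}: {sorted(p)}")

    values = base + rng.normal(0.0, noise_sd, size=base.shape) if noise_sd else base
    values = np.maximum(np.rint(values), 0.0).astype(int)
    for i in range(length):
        yield TimeCut(
            index=i, time=i * delta_s,
            values={species: values[:, i].copy()},
            task_ids=tuple(range(n)),
        )
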