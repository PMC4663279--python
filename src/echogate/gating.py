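"""Respiratory gating of list-mode PET data and point-source FWHM analysis.

The workflow mirrors gated 4D PET with a retrospectively merged motion
signal: inhale peaks are detected in the tracking (or surrogate) signal and
refined by Gaussian fitting; the clock offset between the tracking computer
and the scanner is estimated from corresponding peak pairs; the peaks then
replace the gate tags inside the list-mode stream; events between
consecutive tags are phase-sorted into equal time bins; each phase is
reconstructed, registered axially to a reference phase, and the registered
phases are averaged; finally the axial activity profile at the transverse
maximum is fitted by a Gaussian and reported as an FWHM.

Reconstruction here is a direct 3D histogram of event positions.  The
scanner's point-spread function is applied at event-generation time
(isotropic Gaussian, static resolution 5.2 mm FWHM by default), so the
histogram is the desk-scale equivalent of the filtered-back-projection
image for the axial-profile question this module answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import shift as ndi_shift
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

__all__ = [
    "TrackingSignal",
    "ListModeStream",
    "GridSpec",
    "PhaseImage",
    "GaussianFitResult",
    "GatingError",
    "detect_inhale_peaks",
    "estimate_time_offset",
    "OffsetEstimate",
    "replace_gate_tags",
    "phase_sort",
    "reconstruct_phase",
    "register_and_average",
    "fit_axial_profile",
    "fit_gaussian_1d",
    "gated_fwhm_pipeline",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.35482...


class GatingError(ValueError):
    """Raised when the gating machinery cannot proceed (no peaks, no tags...)."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class TrackingSignal:
    """Timestamped 1D motion samples (mm or arbitrary units).

    ``extras`` may hold the remaining contour-state columns (tx, ty, theta,
    sx, sy) when the signal comes from the image tracker.
    """

    times_ms: np.ndarray
    values: np.ndarray
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, float).reshape(-1)
        self.values = np.asarray(self.values, float).reshape(-1)
        if len(self.times_ms) != len(self.values):
            raise ValueError("times and values must match")
        if len(self.times_ms) < 3:
            raise ValueError("signal needs at least 3 samples")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal values must be finite")
        self.extras = {k: np.asarray(v, float) for k, v in self.extras.items()}


@dataclass
class ListModeStream:
    """Simplified list-mode model: timestamped 3D events plus gate tags."""

    times_ms: np.ndarray
    positions_mm: np.ndarray
    gate_tags_ms: np.ndarray

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, float).reshape(-1)
        self.positions_mm = np.asarray(self.positions_mm, float).reshape(-1, 3)
        self.gate_tags_ms = np.asarray(self.gate_tags_ms, float).reshape(-1)
        if len(self.times_ms) != len(self.positions_mm):
            raise ValueError("one position per event time")
        if np.any(np.diff(self.times_ms) < 0):
            raise ValueError("event times must be non-decreasing")
        if np.any(np.diff(self.gate_tags_ms) <= 0):
            raise ValueError("gate tags must be strictly increasing")

    @property
    def n_events(self) -> int:
        return len(self.times_ms)

    @property
    def span_ms(self) -> tuple:
        return float(self.times_ms[0]), float(self.times_ms[-1])


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned voxel grid: origin (mm, corner), isotropic voxel, shape."""

    origin_mm: tuple = (-60.0, -60.0, -60.0)
    voxel_mm: float = 2.0
    shape: tuple = (60, 60, 60)

    def __post_init__(self) -> None:
        if self.voxel_mm <= 0 or any(s < 1 for s in self.shape):
            raise ValueError("grid must have positive voxel size and shape")

    def edges(self):
        o = np.asarray(self.origin_mm, float)
        return [o[k] + self.voxel_mm * np.arange(self.shape[k] + 1)
                for k in range(3)]

    def centers(self, axis: int) -> np.ndarray:
        o = self.origin_mm[axis]
        return o + self.voxel_mm * (np.arange(self.shape[axis]) + 0.5)


@dataclass
class PhaseImage:
    """Event-count voxel grid of one respiratory phase."""

    counts: np.ndarray
    grid: GridSpec
    phase_index: int = 0
    n_discarded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, float)
        if self.counts.shape != tuple(self.grid.shape):
            raise ValueError("counts shape must match grid")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class GaussianFitResult:
    amplitude: float
    mean_mm: float
    sigma_mm: float
    residual: float

    def __post_init__(self) -> None:
        if self.sigma_mm <= 0:
            raise ValueError("sigma must be positive")

    @property
    def fwhm_mm(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_mm


# ---------------------------------------------------------------------------
# peak detection & clock offset


def _gauss(x, a, mu, sigma, c):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + c


def detect_inhale_peaks(
    signal: TrackingSignal,
    min_prominence: float | None = None,
    window_fraction: float = 0.25,
) -> np.ndarray:
    """Locate inhale peaks and refine each by a local Gaussian fit.

    Candidate maxima come from prominence-based peak picking
    (``min_prominence`` defaults to 25% of the signal range); each candidate
    is then refined by fitting a Gaussian-plus-baseline to the samples
    within +/- ``window_fraction`` x (median cycle length) and taking the
    fitted mean, which gives sub-sample peak times robust to sampling and
    noise.  Peaks closer than half the median cycle are merged.
    """
    v = signal.values
    t = signal.times_ms
    rng_v = float(v.max() - v.min())
    if rng_v <= 0:
        raise GatingError("signal is constant; no inhale peaks")
    prom = min_prominence if min_prominence is not None else 0.25 * rng_v
    idx, _ = find_peaks(v, prominence=prom)
    if len(idx) == 0:
        raise GatingError("no peaks above the prominence threshold")
    if len(idx) >= 2:
        cycle = float(np.median(np.diff(t[idx])))
        dt = float(np.median(np.diff(t)))
        min_dist = max(1, int(round(0.5 * cycle / dt)))
        idx, _ = find_peaks(v, prominence=prom, distance=min_dist)
    else:
        cycle = t[-1] - t[0]

    half_win = window_fraction * cycle
    peaks = []
    for i in idx:
        m = (t >= t[i] - half_win) & (t <= t[i] + half_win)
        ti, vi = t[m], v[m]
        if m.sum() < 5:
            peaks.append(float(t[i]))
            continue
        a0 = vi.max() - vi.min()
        p0 = [a0, float(t[i]), max(half_win / 2.0, 1e-6), float(vi.min())]
        try:
            popt, _ = curve_fit(_gauss, ti, vi, p0=p0, maxfev=2000)
            mu = float(popt[1])
            # reject a fit that wandered out of its own window
            peaks.append(mu if abs(mu - t[i]) <= half_win else float(t[i]))
        except RuntimeError:
            peaks.append(float(t[i]))
    return np.asarray(sorted(peaks))


@dataclass(frozen=True)
class OffsetEstimate:
    offset_ms: float
    sd_ms: float
    n_pairs: int

    def __float__(self) -> float:
        return self.offset_ms


def estimate_time_offset(peaks_a, peaks_b) -> OffsetEstimate:
    """Mean clock offset (a - b) over nearest-neighbour-matched peak pairs.

    Pairs are matched greedily by nearest neighbour within half the median
    inter-peak period; raises when nothing matches.
    """
    a = np.asarray(peaks_a, float)
    b = np.asarray(peaks_b, float)
    if len(a) == 0 or len(b) == 0:
        raise GatingError("need at least one peak in each list")
    ref = b if len(b) >= 2 else a
    half_period = (0.5 * np.median(np.diff(np.sort(ref)))
                   if len(ref) >= 2 else np.inf)
    diffs = []
    for ai in a:
        j = int(np.argmin(np.abs(b - ai)))
        if abs(b[j] - ai) <= half_period:
            diffs.append(ai - b[j])
    if not diffs:
        raise GatingError("no peak pairs matched within half a period")
    diffs = np.asarray(diffs)
    return OffsetEstimate(float(diffs.mean()), float(diffs.std(ddof=0)),
                          len(diffs))


def replace_gate_tags(lm: ListModeStream, peaks_ms, offset_ms: float = 0.0
                      ) -> ListModeStream:
    """Return a stream whose gate tags are the (offset-corrected) peaks.

    Tags are the peak times shifted by ``offset_ms`` and clipped to the
    event span; the events themselves are untouched.
    """
    tags = np.sort(np.asarray(peaks_ms, float)) + offset_ms
    lo, hi = lm.span_ms
    tags = tags[(tags >= lo) & (tags <= hi)]
    if len(tags) == 0:
        raise GatingError("no shifted peaks fall inside the event span")
    return ListModeStream(times_ms=lm.times_ms, positions_mm=lm.positions_mm,
                          gate_tags_ms=tags)


# ---------------------------------------------------------------------------
# phase sorting & reconstruction


def phase_sort(lm: ListModeStream, n_phases: int = 8):
    """Split events between consecutive gate tags into equal time bins.

    Within each cycle (g_i, g_{i+1}) phase k collects events with
    t in [g_i + k*D, g_i + (k+1)*D), D = (g_{i+1} - g_i) / n_phases.  Events
    before the first or at/after the last tag are discarded (never wrapped)
    and counted.

    Returns ``(subsets, n_discarded)`` where subsets is a list of index
    arrays into the event stream, one per phase.
    """
    if n_phases < 1:
        raise ValueError("n_phases must be >= 1")
    tags = lm.gate_tags_ms
    if len(tags) < 2:
        raise GatingError("phase sorting needs at least 2 gate tags")
    t = lm.times_ms
    inside = (t >= tags[0]) & (t < tags[-1])
    cyc = np.searchsorted(tags, t[inside], side="right") - 1
    g0 = tags[cyc]
    delta = (tags[cyc + 1] - g0) / n_phases
    k = np.floor((t[inside] - g0) / delta).astype(int)
    k = np.clip(k, 0, n_phases - 1)  # guard float edge at cycle end
    idx_inside = np.flatnonzero(inside)
    subsets = [idx_inside[k == p] for p in range(n_phases)]
    return subsets, int((~inside).sum())


def reconstruct_phase(positions_mm: np.ndarray, grid: GridSpec,
                      phase_index: int = 0) -> PhaseImage:
    """Histogram event positions onto the voxel grid.

    Events outside the grid are dropped and counted in ``n_discarded``.
    """
    pos = np.asarray(positions_mm, float).reshape(-1, 3)
    h, _ = np.histogramdd(pos, bins=grid.edges())
    return PhaseImage(counts=h, grid=grid, phase_index=phase_index,
                      n_discarded=int(len(pos) - h.sum()))


def fit_gaussian_1d(x: np.ndarray, y: np.ndarray, tol: float = 1e-10
                    ) -> GaussianFitResult:
    """Unweighted least-squares Gaussian fit, moment-initialized."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if y.sum() <= 0:
        raise GatingError("profile has no counts to fit")
    w = np.clip(y, 0, None)
    mu0 = float((x * w).sum() / w.sum())
    var0 = float((w * (x - mu0) ** 2).sum() / w.sum())
    s0 = max(np.sqrt(var0), (x[1] - x[0]) / 2 if len(x) > 1 else 1e-3)
    p0 = [float(y.max()), mu0, s0, 0.0]
    try:
        popt, _ = curve_fit(_gauss, x, y, p0=p0, maxfev=5000,
                            xtol=tol, ftol=tol)
    except RuntimeError as e:
        raise GatingError(f"Gaussian fit did not converge: {e}") from e
    a, mu, sigma, c = popt
    resid = float(np.sqrt(np.mean((_gauss(x, *popt) - y) ** 2)))
    return GaussianFitResult(amplitude=float(a), mean_mm=float(mu),
                             sigma_mm=float(abs(sigma)), residual=resid)


def _axial_centroid(image: PhaseImage) -> float:
    z = image.grid.centers(2)
    prof = image.counts.sum(axis=(0, 1))
    return fit_gaussian_1d(z, prof).mean_mm


def register_and_average(phases, reference_index: int = 0) -> PhaseImage:
    """Register phase images axially to a reference phase and average.

    Each phase's axial (z) profile is fitted by a Gaussian; the phase is
    shifted along z by (reference mean - phase mean) with sub-voxel linear
    interpolation, then all phases are summed and divided by the phase
    count.  (The pipeline's default path applies the same shifts to event
    coordinates before histogramming, which is sub-voxel exact; this
    image-space variant serves already-reconstructed grids.)
    """
    phases = list(phases)
    if not phases:
        raise GatingError("need at least one phase")
    grid = phases[0].grid
    if any(p.grid != grid for p in phases):
        raise ValueError("phases must share a common grid")
    mus = [_axial_centroid(p) for p in phases]
    ref = mus[reference_index]
    acc = np.zeros(grid.shape)
    for p, mu in zip(phases, mus):
        shift_vox = (ref - mu) / grid.voxel_mm
        acc += ndi_shift(p.counts, (0.0, 0.0, shift_vox), order=1,
                         mode="constant", cval=0.0)
    return PhaseImage(counts=np.clip(acc / len(phases), 0, None), grid=grid,
                      phase_index=-1)


def fit_axial_profile(image: PhaseImage) -> GaussianFitResult:
    """Gaussian fit of the z-profile at the transverse maximum.

    The transverse (x, y) voxel with the largest summed activity is located
    and the 1D profile along z through it is fitted.
    """
    if image.total <= 0:
        raise GatingError("image is empty")
    trans = image.counts.sum(axis=2)
    ix, iy = np.unravel_index(np.argmax(trans), trans.shape)
    prof = image.counts[ix, iy, :]
    return fit_gaussian_1d(image.grid.centers(2), prof)


def full_width_at_fraction(image: PhaseImage, fraction: float = 0.1) -> float:
    """Full width (mm) of the summed axial profile at ``fraction`` of max,
    with linear interpolation across the threshold crossings."""
    z = image.grid.centers(2)
    prof = image.counts.sum(axis=(0, 1)).astype(float)
    thr = fraction * prof.max()
    above = np.flatnonzero(prof >= thr)
    if len(above) == 0:
        return 0.0
    i0, i1 = above[0], above[-1]
    lo = z[i0]
    if i0 > 0:
        lo = np.interp(thr, [prof[i0 - 1], prof[i0]], [z[i0 - 1], z[i0]])
    hi = z[i1]
    if i1 < len(z) - 1:
        hi = np.interp(thr, [prof[i1 + 1], prof[i1]], [z[i1 + 1], z[i1]])
    return float(hi - lo)


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _reference_phase_index(signal, tags) -> int:
    """The reference is the first phase after the maximum inhale peak, i.e.
    phase 0 anchored at the tag whose signal value is largest.  With pooled
    per-phase statistics this is pooled phase 0."""
    return 0


def gated_fwhm_pipeline(
    lm: ListModeStream,
    signal: TrackingSignal,
    n_phases: int = 8,
    grid: GridSpec = GridSpec(),
    min_prominence: float | None = None,
    window_fraction: float = 0.25,
    reference_peaks_ms=None,
    register_events: bool = True,
):
    """Full gated analysis of a point-source acquisition.

    Steps: inhale-peak detection on ``signal`` -> clock-offset estimation
    against ``reference_peaks_ms`` (e.g. the tags already in the stream or a
    second monitoring system; offset 0 when absent) -> gate-tag replacement
    -> phase sorting -> per-phase reconstruction -> axial registration to
    the reference phase (event-space by default) -> averaging -> Gaussian
    fit of the axial profile.

    Returns ``(GaussianFitResult, report)`` where the report carries the
    per-phase counts and centroids, the ungated FWHM and axial extent
    (full width at 10% of maximum), discard counters and the offset used.
    """
    peaks = detect_inhale_peaks(signal, min_prominence=min_prominence,
                                window_fraction=window_fraction)
    if reference_peaks_ms is not None:
        off = estimate_time_offset(reference_peaks_ms, peaks)
        offset = off.offset_ms
    elif len(lm.gate_tags_ms) >= 1:
        off = estimate_time_offset(lm.gate_tags_ms, peaks)
        offset = off.offset_ms
    else:
        off = OffsetEstimate(0.0, 0.0, 0)
        offset = 0.0

    lm2 = replace_gate_tags(lm, peaks, offset)
    subsets, n_disc = phase_sort(lm2, n_phases)
    if any(len(s) == 0 for s in subsets):
        raise GatingError("empty respiratory phase; acquisition too short?")

    phases = [reconstruct_phase(lm2.positions_mm[s], grid, k)
              for k, s in enumerate(subsets)]
    ref_idx = _reference_phase_index(signal, lm2.gate_tags_ms)
    mus = [_axial_centroid(p) for p in phases]

    if register_events:
        ref = mus[ref_idx]
        pos = []
        for s, mu in zip(subsets, mus):
            p = lm2.positions_mm[s].copy()
            p[:, 2] += ref - mu
            pos.append(p)
        summed = reconstruct_phase(np.concatenate(pos), grid, -1)
        averaged = PhaseImage(summed.counts / n_phases, grid, -1,
                              summed.n_discarded)
    else:
        averaged = register_and_average(phases, ref_idx)

    fit = fit_axial_profile(averaged)

    inside = (lm2.times_ms >= lm2.gate_tags_ms[0]) & \
             (lm2.times_ms < lm2.gate_tags_ms[-1])
    ungated = reconstruct_phase(lm2.positions_mm[inside], grid, -2)
    try:
        ungated_fit = fit_axial_profile(ungated)
        ungated_fwhm = ungated_fit.fwhm_mm
    except GatingError:
        ungated_fwhm = float("nan")

    report = {
        "n_events": lm.n_events,
        "n_phases": n_phases,
        "n_peaks": len(peaks),
        "offset_ms": offset,
        "offset_sd_ms": off.sd_ms,
        "phase_counts": [int(len(s)) for s in subsets],
        "phase_centroids_mm": [float(m) for m in mus],
        "reference_phase": ref_idx,
        "n_discarded_outside_tags": n_disc,
        "n_discarded_off_grid": int(averaged.n_discarded),
        "fwhm_mm": fit.fwhm_mm,
        "ungated_fwhm_mm": ungated_fwhm,
        "ungated_extent_10pct_mm": full_width_at_fraction(ungated, 0.1),
        "gated_total": averaged.total,
        "ungated_total": ungated.total,
    }
    return fit, report
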