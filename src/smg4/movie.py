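"""Spot detection, trace extraction and trajectory selection.

Replaces the conventional IDL spot finder + MATLAB trace picker used for
prism-TIRF data: detect diffraction-limited spots on a band-pass-filtered
average image, pull out background-subtracted intensity trajectories, and
apply the selection criteria used for G4 binding experiments — a clean
pre-injection baseline, a consistent baseline throughout, and at least two
binding events persisting above the baseline.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians

from .trajectory import MovieStack, Trajectory


@dataclass
class Spot:
    """Sub-pixel spot center with its extraction window radius (px)."""

    center: tuple[float, float]  # (y, x)
    window_radius: int = 3


@dataclass
class QcReport:
    """Outcome of trajectory selection for one molecule.

    ``passed`` is true iff ``reasons`` is empty. The thresholds that were
    applied are recorded so selection is auditable.
    """

    passed: bool
    reasons: list[str]
    n_events_detected: int
    baseline_mean: float
    baseline_sd: float
    post_baseline_median: float
    molecule_id: str = ""
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.passed == (len(self.reasons) == 0)


def detect_spots(
    stack: MovieStack,
    detect_frames: slice | None = None,
    threshold_sigmas: float = 5.0,
    window_radius: int = 3,
    low_sigma: float = 1.0,
    high_sigma: float = 4.0,
) -> list[Spot]:
    """Find diffraction-limited spots on the averaged detection frames.

    The mean of ``detect_frames`` is band-pass filtered (difference of
    Gaussians), candidate maxima above ``threshold_sigmas`` robust SDs of
    the filtered image are refined to sub-pixel centers by local
    intensity-weighted centroid, and spots closer than twice the window
    radius are both discarded (their extraction windows would overlap).
    Spots whose window would clip the frame edge are dropped.
    """
    if stack.n_frames < 1:
        raise ValueError("empty movie stack")
    frames = stack.frames if detect_frames is None else stack.frames[detect_frames]
    if frames.shape[0] < 1:
        raise ValueError("detect_frames selects no frames")

    mean_img = frames.mean(axis=0)
    filtered = difference_of_gaussians(mean_img, low_sigma, high_sigma)

    # robust noise scale: median absolute deviation
    mad = np.median(np.abs(filtered - np.median(filtered)))
    sd = 1.4826 * mad if mad > 0 else filtered.std()
    if sd == 0:
        return []
    threshold = np.median(filtered) + threshold_sigmas * sd

    peaks = peak_local_max(
        filtered, min_distance=window_radius, threshold_abs=threshold
    )

    h, w = mean_img.shape
    refined = []
    for py, px in peaks:
        r = window_radius
        if not (r <= py < h - r and r <= px < w - r):
            continue  # window would clip the edge
        win = mean_img[py - r : py + r + 1, px - r : px + r + 1]
        win = win - win.min()
        total = win.sum()
        if total <= 0:
            continue
        dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
        cy = py + (dy * win).sum() / total
        cx = px + (dx * win).sum() / total
        refined.append((cy, cx))

    if not refined:
        return []

    # ambiguous-extraction rule: discard both members of any close pair
    pts = np.array(refined)
    tree = cKDTree(pts)
    close = tree.query_pairs(2.0 * window_radius)
    bad = {i for pair in close for i in pair}
    return [
        Spot(center=(float(y), float(x)), window_radius=window_radius)
        for i, (y, x) in enumerate(refined)
        if i not in bad
    ]


def extract_trace(
    stack: MovieStack,
    spot: Spot,
    annulus_width: int = 2,
    gap: int = 1,
    molecule_id: str | None = None,
) -> Trajectory:
    """Integrate spot intensity per frame with local background subtraction.

    The per-frame value is the pixel sum inside a disk of the spot's window
    radius minus the annulus median background (per pixel) times the disk
    area. The annulus starts ``gap`` px outside the disk.
    """
    cy, cx = spot.center
    r_out = spot.window_radius + gap + annulus_width
    h, w = stack.shape
    iy, ix = int(round(cy)), int(round(cx))
    if not (r_out <= iy < h - r_out and r_out <= ix < w - r_out):
        raise ValueError(
            f"extraction window (r={r_out}) at ({cy:.1f}, {cx:.1f}) clipped by "
            f"frame bounds {h}x{w}"
        )

    win = stack.frames[:, iy - r_out : iy + r_out + 1, ix - r_out : ix + r_out + 1]
    dy, dx = np.mgrid[-r_out : r_out + 1, -r_out : r_out + 1]
    dist = np.hypot(dy + (iy - cy), dx + (ix - cx))
    disk = dist <= spot.window_radius
    annulus = (dist > spot.window_radius + gap) & (dist <= r_out)

    signal = win[:, disk].sum(axis=1)
    background = np.median(win[:, annulus], axis=1) * disk.sum()
    return Trajectory(
        signal - background,
        stack.frame_interval,
        molecule_id=molecule_id or f"spot@{cy:.1f},{cx:.1f}",
        source="movie",
    )


def _event_runs(above: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_len as (start, stop) pairs."""
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]
    return [(int(a), int(b)) for a, b in zip(starts, stops) if b - a >= min_len]


def qc_select(
    traj: Trajectory,
    pre_frames: int = 300,
    event_sigmas: float = 3.0,
    min_event_frames: int = 3,
    min_events: int = 2,
    drift_tolerance: float = 2.0,
) -> QcReport:
    """Apply the trajectory selection criteria.

    A trajectory passes iff

    1. no excursion above ``baseline + event_sigmas * sd`` lasting
       ``min_event_frames`` occurs before protein injection (frames
       ``[0, pre_frames)``, half-open);
    2. the post-injection baseline (median of sub-threshold frames) stays
       within ``drift_tolerance`` baseline SDs of the pre-injection
       baseline;
    3. at least ``min_events`` excursions persisting ``min_event_frames``
       above threshold exist after injection.

    The decision is invariant to adding a constant offset to the trace.
    Use :meth:`smg4.trajectory.Trajectory.trimmed` to obtain the analysis
    segment (pre-injection frames removed) for idealization.
    """
    x = traj.intensities
    if len(x) <= pre_frames + min_event_frames:
        raise ValueError(
            f"trajectory of {len(x)} frames too short for pre_frames={pre_frames}"
            f" + min_event_frames={min_event_frames}"
        )

    pre = x[:pre_frames]
    baseline_mean = float(np.median(pre))
    baseline_sd = float(pre.std())
    if baseline_sd == 0:
        baseline_sd = 1e-12  # flat synthetic baseline: any excursion is an event
    threshold = baseline_mean + event_sigmas * baseline_sd

    reasons = []

    pre_events = _event_runs(pre > threshold, min_event_frames)
    if pre_events:
        reasons.append("pre-injection event")

    post = x[pre_frames:]
    sub = post[post <= threshold]
    post_median = float(np.median(sub)) if sub.size else float("nan")
    if not sub.size or abs(post_median - baseline_mean) >= drift_tolerance * baseline_sd:
        reasons.append("baseline drift")

    post_events = _event_runs(post > threshold, min_event_frames)
    if len(post_events) < min_events:
        reasons.append(f"fewer than {min_events} events")

    return QcReport(
        passed=not reasons,
        reasons=reasons,
        n_events_detected=len(post_events),
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
        post_baseline_median=post_median,
        molecule_id=traj.molecule_id,
        thresholds={
            "pre_frames": pre_frames,
            "event_sigmas": event_sigmas,
            "min_event_frames": min_event_frames,
            "min_events": min_events,
            "drift_tolerance": drift_tolerance,
        },
    )


def select_trajectories(
    trajs: list[Trajectory], pre_frames: int = 300, **qc_kwargs
) -> tuple[list[Trajectory], list[QcReport]]:
    """QC every trajectory; return passing analysis segments and all reports."""
    selected, reports = [], []
    for traj in trajs:
        report = qc_select(traj, pre_frames=pre_frames, **qc_kwargs)
        reports.append(report)
        if report.passed:
            selected.append(traj.trimmed(pre_frames))
    return selected, reports
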