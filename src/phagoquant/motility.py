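"""3-D microglial-process length and motility from two-photon time-lapse stacks.

The measurement follows the intensity-profile centerline scheme used for
fine fluorescent processes: the process of interest is reoriented so its
long axis runs along y, and in every z-slice the intensity profile of
each horizontal (x) line crossing the process is examined.  Per line and
slice, the left and right borders (xL, xR) of the process are located
from the profile (background level, prominence over the flanks, and
optionally the inflexion points).  Per y-line the borders across slices
give a 3-D center point:

    zC = (zU + zB) / 2          (upper/bottom slice containing the process)
    xC = (xR + xL) / 2

where, if zC falls between slices ("virtual slice"), xR and xL are first
averaged over the two neighbouring slices.  The 3-D skeleton length of
the process in a frame is the summed Euclidean distance between center
points of consecutive lines (in um, honouring anisotropic voxels), and
motility is the absolute length change between consecutive frames divided
by the frame interval.  Protraction / retraction are the means over
frame pairs in which length increased / decreased.

Stacks are assumed registered (drift-corrected) upstream; this module
performs no registration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import GapError, UndefinedMetricError, ValidationError

__all__ = [
    "ZStackSeries",
    "BorderParams",
    "ProcessSelection",
    "ProcessSkeleton",
    "MotilityTrace",
    "reorient_process",
    "detect_borders",
    "center_point",
    "extract_skeleton",
    "skeleton_length",
    "motility_trace",
    "measure_process",
    "occupancy_fraction",
]

logger = logging.getLogger(__name__)

#: Two-photon acquisition geometry used throughout: 0.1 x 0.1 um pixels,
#: 1 um z-steps, one stack every 1.5 min.
DEFAULT_VOXEL_SIZE_UM = (0.1, 0.1, 1.0)
DEFAULT_FRAME_INTERVAL_MIN = 1.5


@dataclass(frozen=True)
class ZStackSeries:
    """4-D fluorescence time-lapse: axes (frame, z, y, x).

    ``voxel_size_um`` is (dx, dy, dz).
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValidationError(
                f"stack must be 4-D (t,z,y,x); got shape {self.data.shape}"
            )
        if any(v <= 0 for v in self.voxel_size_um) or self.frame_interval_min <= 0:
            raise ValidationError("voxel sizes and frame interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class BorderParams:
    """Knobs of the border-detection rule.

    prominence_fraction: level (as a fraction of peak height above
        background) to which intensity must fall to mark a border;
        0.5 is the full-width-at-half-maximum convention.
    use_inflexion: refine each border to the nearest inflexion point
        (discrete second-derivative sign change) of the profile.
    smooth_sigma: Gaussian smoothing (pixels) applied to each profile
        before detection; 0 disables.
    min_rel_height: a line/slice is considered to contain the process
        only if its peak exceeds background by this fraction of the
        process's global dynamic range (rejects noise-only lines).
    axial_smooth_sigma: Gaussian smoothing (lines) applied *along y* to
        the per-(z, y) peak-intensity map before deciding which slices
        contain the process; exploits the continuity of a process along
        its axis to keep the z extent stable under noise.  0 disables.
    center_smooth_window: moving-average window (lines) applied to the
        recovered xC centerline; 1 disables.
    z_smooth_window: moving-average window (lines) applied to the
        recovered zC centerline.  zC is quantized at half a z-step by the
        center rule (0.5 um at 1 um z-steps, against 0.1 um lines), so a
        window of ~2 um of lines converts the staircase into a sub-slice
        estimate instead of letting each 0.5 um jump inflate the summed
        length; 1 disables.
    min_lines: minimum number of center points for a frame to count.
    """

    prominence_fraction: float = 0.5
    use_inflexion: bool = True
    smooth_sigma: float = 1.5
    min_rel_height: float = 0.3
    axial_smooth_sigma: float = 2.0
    center_smooth_window: int = 7
    z_smooth_window: int = 21
    min_lines: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.prominence_fraction <= 1):
            raise ValidationError("prominence_fraction must be in (0, 1]")
        for name in ("center_smooth_window", "z_smooth_window"):
            w = getattr(self, name)
            if w < 1 or w % 2 == 0:
                raise ValidationError(f"{name} must be odd and >= 1")


@dataclass(frozen=True)
class ProcessSelection:
    """Manual selection of one process: ROI, rotation, background.

    ``roi`` is (y0, y1, x0, x1) in pixels (half-open), or None for the
    full field.  ``angle_deg`` is the in-plane rotation that makes the
    process vertical (aligned with y).  ``background`` is the intensity
    floor; if None it is estimated as the median of the ROI boundary
    pixels of each frame.
    """

    roi: tuple[int, int, int, int] | None = None
    angle_deg: float = 0.0
    background: float | None = None
    border: BorderParams = field(default_factory=BorderParams)


@dataclass(frozen=True)
class ProcessSkeleton:
    """Per-line center points of one frame, in pixel coordinates."""

    y: np.ndarray  # int lines, strictly increasing
    xc: np.ndarray  # sub-pixel columns
    zc: np.ndarray  # slices, possibly half-integer
    n_gap_lines: int = 0


@dataclass(frozen=True)
class MotilityTrace:
    """Lengths and motility of one process across the recording.

    ``motilities_um_min[i]`` covers the frame pair
    (``pair_frames[i]``, ``pair_frames[i] + 1``); pairs touching a frame
    in which the process could not be measured are dropped.
    Protraction / retraction are NaN when no frame pair increased /
    decreased in length.
    """

    frame_indices: tuple[int, ...]
    lengths_um: np.ndarray
    pair_frames: tuple[int, ...]
    motilities_um_min: np.ndarray
    mean_motility: float
    mean_protraction: float
    mean_retraction: float
    dropped_frames: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# geometry


def reorient_process(stack: ZStackSeries, selection: ProcessSelection) -> ZStackSeries:
    """Crop the ROI and rotate in-plane so the process axis runs along y.

    Rotation uses bilinear resampling per (frame, slice); z and t are
    untouched.  Requires square xy pixels (dx == dy) for the rotation to
    be metrically valid.
    """
    data = stack.data
    if selection.roi is not None:
        y0, y1, x0, x1 = selection.roi
        ny, nx = data.shape[2], data.shape[3]
        if not (0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
            raise ValidationError(f"ROI {selection.roi} outside image bounds")
        data = data[:, :, y0:y1, x0:x1]
    angle = float(selection.angle_deg)
    if not np.isfinite(angle):
        raise ValidationError("rotation angle must be finite")
    if angle % 360.0 != 0.0:
        dx, dy, _ = stack.voxel_size_um
        if not np.isclose(dx, dy):
            raise ValidationError("in-plane rotation requires dx == dy")
        data = ndimage.rotate(
            data.astype(float), angle, axes=(3, 2), order=1, reshape=True, cval=0.0
        )
    return replace(stack, data=np.ascontiguousarray(data))


def detect_borders(
    profile: np.ndarray,
    background: float,
    params: BorderParams | None = None,
    min_height: float = 0.0,
) -> tuple[float, float] | None:
    """Locate the left/right borders of a process on one intensity line.

    Returns sub-pixel ``(xL, xR)`` or None when the line does not contain
    the process (peak at or below ``background + min_height``).  Borders
    are where intensity first falls back to
    ``background + prominence_fraction * (peak - background)`` walking
    outward from the maximum, linearly interpolated between samples and,
    when ``use_inflexion`` is set, snapped to the nearest inflexion point
    of the profile within a few pixels.
    """
    params = params or BorderParams()
    prof = np.asarray(profile, dtype=float)
    if prof.ndim != 1 or prof.size < 3:
        raise ValidationError("profile must be 1-D with >= 3 samples")
    if not np.all(np.isfinite(prof)):
        raise ValidationError("profile contains non-finite intensities")
    if params.smooth_sigma > 0:
        prof = ndimage.gaussian_filter1d(prof, params.smooth_sigma, mode="nearest")
    m = int(np.argmax(prof))
    peak = prof[m]
    if peak <= background + max(min_height, 0.0) or peak <= background:
        return None
    if m == 0 or m == prof.size - 1:
        return None  # no flanking pixels: prominence criterion inapplicable
    level = background + params.prominence_fraction * (peak - background)
    xr = _walk_to_level(prof, m, level, direction=+1)
    xl = _walk_to_level(prof, m, level, direction=-1)
    if np.isnan(xr) or np.isnan(xl):
        return None  # profile never returns to the border level inside the ROI
    if params.use_inflexion:
        xr = _refine_inflexion(prof, xr, m, prof.size - 1)
        xl = _refine_inflexion(prof, xl, 0, m)
    if xl > xr:
        xl, xr = xr, xl
    return float(xl), float(xr)


def _walk_to_level(prof: np.ndarray, start: int, level: float, direction: int) -> float:
    """First sub-pixel position at `level`, walking outward from the peak.

    NaN when the profile never falls to the level before the array edge.
    """
    i = start
    last = prof.size - 1 if direction > 0 else 0
    while i != last:
        j = i + direction
        if prof[j] < level:
            # linear interpolation between samples i and j
            frac = (prof[i] - level) / (prof[i] - prof[j])
            return i + direction * frac
        i = j
    return float("nan")


def _refine_inflexion(
    prof: np.ndarray, x: float, lo: int, hi: int, window: int = 3
) -> float:
    """Snap a border to the nearest second-derivative sign change.

    Candidates are sub-pixel zero crossings of the discrete second
    difference within `window` pixels of the half-max crossing, limited
    to [lo, hi]; the crossing itself is kept when no candidate exists.
    """
    d2 = np.diff(prof, 2)  # d2[i] ~ f''(i + 1)
    idx = np.nonzero(d2[:-1] * d2[1:] < 0)[0]
    if idx.size == 0:
        return x
    # sub-pixel zero crossing between i+1 and i+2
    cand = idx + 1 + d2[idx] / (d2[idx] - d2[idx + 1])
    cand = cand[(cand >= lo) & (cand <= hi) & (np.abs(cand - x) <= window)]
    if cand.size == 0:
        return x
    return float(cand[np.argmin(np.abs(cand - x))])


def center_point(
    borders_by_z: Mapping[int, tuple[float, float]],
) -> tuple[float, float]:
    """Center (xC, zC) of a process at one y-line from per-slice borders.

    zC is the midpoint of the upper and bottom slices containing the
    process; when zC is a half-integer ("virtual slice") the borders of
    the two flanking slices are averaged before taking the x midpoint.
    """
    if not borders_by_z:
        raise ValidationError("no slice contains the process at this line")
    zs = sorted(borders_by_z)
    zb, zu = zs[0], zs[-1]
    zc = (zu + zb) / 2.0
    if zc == int(zc):
        z = int(zc)
        if z not in borders_by_z:
            raise GapError(f"process absent from central slice z={z}")
        xl, xr = borders_by_z[z]
    else:
        lo, hi = int(np.floor(zc)), int(np.ceil(zc))
        if lo not in borders_by_z or hi not in borders_by_z:
            raise GapError(
                f"virtual central slice z={zc} requires slices {lo} and {hi}"
            )
        xl = (borders_by_z[lo][0] + borders_by_z[hi][0]) / 2.0
        xr = (borders_by_z[lo][1] + borders_by_z[hi][1]) / 2.0
    return (xl + xr) / 2.0, zc


def extract_skeleton(
    volume: np.ndarray,
    background: float,
    params: BorderParams | None = None,
) -> ProcessSkeleton:
    """Per-line center points of a vertically aligned process in one stack.

    ``volume`` has axes (z, y, x).  Lines whose peak does not clear the
    noise rejection threshold are skipped; lines where the center-slice
    rule cannot be applied (gaps) are skipped and counted.
    """
    params = params or BorderParams()
    if volume.ndim != 3:
        raise ValidationError("volume must be 3-D (z, y, x)")
    vol = volume.astype(float)
    if params.smooth_sigma > 0:
        vol = ndimage.gaussian_filter1d(vol, params.smooth_sigma, axis=2, mode="nearest")
    vmax = float(vol.max(initial=background))
    min_height = params.min_rel_height * max(vmax - background, 0.0)
    # which (z, y) lines contain the process: peak height above threshold,
    # with the peak map smoothed along y so noise cannot flicker zU/zB
    line_peak = vol.max(axis=2)
    if params.axial_smooth_sigma > 0:
        line_peak = ndimage.gaussian_filter1d(
            line_peak, params.axial_smooth_sigma, axis=1, mode="nearest"
        )
    candidate = line_peak > background + min_height
    # a line belongs to the process only if its own (un-smoothed-in-y) peak
    # clears the bar too: stops the axially smoothed presence map from
    # spilling past the process ends onto noise-only lines
    line_keep = vol.max(axis=(0, 2)) > background + min_height
    line_params = replace(params, smooth_sigma=0.0)  # profiles already smoothed
    ys, xcs, zcs = [], [], []
    n_gaps = 0
    for y in range(volume.shape[1]):
        if not line_keep[y]:
            continue
        borders: dict[int, tuple[float, float]] = {}
        for z in np.nonzero(candidate[:, y])[0]:
            b = detect_borders(vol[z, y, :], background, line_params, 0.0)
            if b is not None:
                borders[int(z)] = b
        if not borders:
            continue
        try:
            xc, zc = center_point(borders)
        except GapError:
            n_gaps += 1
            continue
        ys.append(y)
        xcs.append(xc)
        zcs.append(zc)
    y_arr = np.asarray(ys, dtype=int)
    xc_arr = np.asarray(xcs, dtype=float)
    zc_arr = np.asarray(zcs, dtype=float)
    if y_arr.size:
        # keep the largest contiguous run of lines: isolated detections away
        # from the process body are noise
        runs = np.split(
            np.arange(y_arr.size), np.nonzero(np.diff(y_arr) > 1)[0] + 1
        )
        best = max(runs, key=len)
        y_arr, xc_arr, zc_arr = y_arr[best], xc_arr[best], zc_arr[best]
    if params.center_smooth_window > 1 and xc_arr.size >= params.center_smooth_window:
        xc_arr = _moving_average(xc_arr, params.center_smooth_window)
    if params.z_smooth_window > 1 and zc_arr.size >= params.z_smooth_window:
        zc_arr = _moving_average(zc_arr, params.z_smooth_window)
    return ProcessSkeleton(
        y=y_arr,
        xc=xc_arr,
        zc=zc_arr,
        n_gap_lines=n_gaps,
    )


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    padded = np.pad(x, half, mode="edge")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def skeleton_length(
    skeleton: ProcessSkeleton,
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM,
) -> float:
    """3-D length (um): summed distances between consecutive center points."""
    if skeleton.y.size < 2:
        raise UndefinedMetricError("skeleton_length", "fewer_than_two_center_points")
    dx, dy, dz = voxel_size_um
    dyu = np.diff(skeleton.y) * dy
    dxu = np.diff(skeleton.xc) * dx
    dzu = np.diff(skeleton.zc) * dz
    return float(np.sum(np.sqrt(dyu**2 + dxu**2 + dzu**2)))


def motility_trace(
    lengths_um: Sequence[float],
    frame_interval_min: float,
    frame_indices: Sequence[int] | None = None,
    dropped_frames: Sequence[int] = (),
) -> MotilityTrace:
    """Motility statistics from per-frame lengths.

    Motility per frame pair is |dL| / interval (um/min); pairs are only
    formed between consecutive frame indices (so dropped frames break the
    chain).  Mean protraction / retraction average the pairs where length
    increased / decreased; zero-change pairs count toward mean motility
    only.
    """
    lengths = np.asarray(lengths_um, dtype=float)
    if lengths.size < 2:
        raise UndefinedMetricError("motility_trace", "fewer_than_two_frames")
    if frame_interval_min <= 0:
        raise ValidationError("frame interval must be > 0")
    idx = (
        np.arange(lengths.size)
        if frame_indices is None
        else np.asarray(frame_indices, dtype=int)
    )
    if idx.size != lengths.size or np.any(np.diff(idx) < 1):
        raise ValidationError("frame_indices must be strictly increasing")
    consecutive = np.diff(idx) == 1
    if not np.any(consecutive):
        raise UndefinedMetricError("motility_trace", "no_consecutive_frame_pairs")
    deltas = np.diff(lengths)[consecutive]
    pair_frames = tuple(int(f) for f in idx[:-1][consecutive])
    motilities = np.abs(deltas) / frame_interval_min
    protr = motilities[deltas > 0]
    retr = motilities[deltas < 0]
    return MotilityTrace(
        frame_indices=tuple(int(f) for f in idx),
        lengths_um=lengths,
        pair_frames=pair_frames,
        motilities_um_min=motilities,
        mean_motility=float(motilities.mean()),
        mean_protraction=float(protr.mean()) if protr.size else float("nan"),
        mean_retraction=float(retr.mean()) if retr.size else float("nan"),
        dropped_frames=tuple(int(f) for f in dropped_frames),
    )


def measure_process(
    stack: ZStackSeries, selection: ProcessSelection | None = None
) -> MotilityTrace:
    """Full per-process pipeline: reorient, skeletonize each frame, trace.

    Frames in which the process cannot be measured (too few center points)
    are dropped, along with the frame pairs touching them; the trace
    records which.
    """
    selection = selection or ProcessSelection()
    sub = reorient_process(stack, selection)
    params = selection.border
    frames, lengths, dropped = [], [], []
    for f in range(sub.n_frames):
        volume = sub.data[f]
        background = (
            selection.background
            if selection.background is not None
            else _boundary_median(volume)
        )
        skel = extract_skeleton(volume, background, params)
        if skel.y.size < max(params.min_lines, 2):
            dropped.append(f)
            logger.warning("frame %d dropped: %d center points", f, skel.y.size)
            continue
        frames.append(f)
        lengths.append(skeleton_length(skel, sub.voxel_size_um))
    if len(frames) < 2:
        raise UndefinedMetricError(
            "measure_process", "process_detectable_in_fewer_than_two_frames"
        )
    return motility_trace(lengths, sub.frame_interval_min, frames, dropped)


def _boundary_median(volume: np.ndarray) -> float:
    """Background estimate: median of the xy-boundary pixels of a volume."""
    edges = np.concatenate(
        [
            volume[:, 0, :].ravel(),
            volume[:, -1, :].ravel(),
            volume[:, :, 0].ravel(),
            volume[:, :, -1].ravel(),
        ]
    )
    return float(np.median(edges))


# ---------------------------------------------------------------------------
# occupancy


def occupancy_fraction(
    volume: np.ndarray,
    threshold: float | None = None,
    min_slices: int = 1,
) -> float:
    """Percentage of pixels occupied by labeled microglia (area fraction).

    Per z-slice, the fraction of pixels strictly above ``threshold`` is
    computed and the fractions are averaged over slices; the result is a
    percentage.  ``threshold=None`` selects Otsu's threshold on the whole
    volume.  ``min_slices`` enforces a minimum number of slices to
    average over (set 10 to follow the ten-images-per-stack convention).
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim == 2:
        vol = vol[None]
    if vol.ndim != 3 or vol.size == 0:
        raise ValidationError("volume must be a non-empty 2-D or 3-D array")
    if vol.shape[0] < min_slices:
        raise ValidationError(
            f"{vol.shape[0]} slices < required minimum {min_slices}"
        )
    if threshold is None:
        if np.ptp(vol) == 0:
            raise ValidationError("cannot auto-threshold a constant image")
        threshold = float(threshold_otsu(vol))
    per_slice = (vol > threshold).mean(axis=(1, 2))
    return float(per_slice.mean() * 100.0)
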