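"""Wound-closure quantification, kymographs and track directedness.

A scratch wound in a phase-contrast image of a confluent monolayer appears as
a smooth, low-texture band between two textured cell sheets.  Segmentation
exploits this: a sliding-window standard deviation map separates cell-covered
(high-texture) from cell-free (low-texture) pixels via Otsu's threshold,
followed by morphological closing and selection of the connected component
that straddles the declared wound axis.  Because the statistic is local
contrast, the measured closure is invariant to global affine intensity
rescaling of the stack.

Closure is reported as area normalized to the first frame,
closure% = 100·(1 − A(t)/A(0)), and a closure rate in %/h from an ordinary
least-squares fit.  Kymographs average a small number of horizontal line
profiles (7 by default) through the wound ROI per frame and stack them in
time.  Track directedness is the cosine of each displacement step against
the field axis (+x): +1 rightward (cathodal), −1 leftward, 0 undirected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk


@dataclass(frozen=True)
class SegmentationParams:
    """Texture-based wound segmentation settings."""

    texture_window: int = 15  # sliding-std window, px (~1.5 cell diameters)
    closing_radius: int = 5  # px
    #: the std window smears cell texture into the wound, biasing its
    #: boundary inward; the selected component is dilated by this many px to
    #: compensate (None -> texture_window // 3)
    boundary_dilation: int | None = None
    #: Otsu interclass contrast below which the texture map is considered
    #: unimodal (no wound/background distinction), relative to its mean
    min_contrast: float = 0.25
    #: a unimodal frame whose mean texture is below this fraction of its mean
    #: intensity is "fully smooth" (degenerate whole-frame wound); above it,
    #: "fully textured" (no wound).  Assumes non-negative intensity data.
    smooth_fraction: float = 0.05


@dataclass
class WoundSegmentation:
    mask: np.ndarray
    area_px: float
    flag: str | None = None  # None | "empty" | "degenerate"


def _local_std(img: np.ndarray, window: int) -> np.ndarray:
    m = ndi.uniform_filter(img, size=window, mode="reflect")
    m2 = ndi.uniform_filter(img * img, size=window, mode="reflect")
    return np.sqrt(np.maximum(m2 - m * m, 0.0))


def segment_wound(
    frame: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    wound_axis_col: int | None = None,
) -> WoundSegmentation:
    """Segment the cell-free wound band of a single grayscale frame.

    ``wound_axis_col`` is the image column the wound is declared to straddle
    (defaults to the centre column); among low-texture components the largest
    one intersecting that column is returned.

    Degenerate frames are flagged: a fully textured frame (monolayer without
    a wound) yields an empty mask with flag ``"empty"``; a fully smooth frame
    yields the whole frame with flag ``"degenerate"``.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    h, w = img.shape
    axis = w // 2 if wound_axis_col is None else int(wound_axis_col)

    tex = _local_std(img, params.texture_window)
    level = float(np.abs(img).mean())

    def smooth() -> bool:
        return level <= 0 or float(tex.mean()) < params.smooth_fraction * level

    if float(tex.max()) <= 0:
        return WoundSegmentation(np.ones_like(img, bool), float(img.size), "degenerate")

    thr = threshold_otsu(tex)
    low = tex < thr
    hi_mean = float(tex[~low].mean()) if (~low).any() else 0.0
    lo_mean = float(tex[low].mean()) if low.any() else 0.0
    if hi_mean <= 0 or (hi_mean - lo_mean) < params.min_contrast * hi_mean:
        # unimodal texture: either a bare/smooth frame (whole-frame wound)
        # or a wound-free monolayer (no wound), told apart by texture level
        if smooth():
            return WoundSegmentation(
                np.ones_like(img, bool), float(img.size), "degenerate"
            )
        return WoundSegmentation(np.zeros_like(img, bool), 0.0, "empty")

    # pad by edge replication so the closing is free of border artefacts
    cr = params.closing_radius
    low = ndi.binary_closing(np.pad(low, cr, mode="edge"), structure=disk(cr))[
        cr:-cr, cr:-cr
    ]
    labels, n = ndi.label(low)
    if n == 0:
        return WoundSegmentation(np.zeros_like(img, bool), 0.0, "empty")
    on_axis = np.unique(labels[:, axis])
    on_axis = on_axis[on_axis > 0]
    if on_axis.size == 0:
        return WoundSegmentation(np.zeros_like(img, bool), 0.0, "empty")
    sizes = ndi.sum_labels(low, labels, on_axis)
    best = int(on_axis[np.argmax(sizes)])
    mask = labels == best
    dil = params.boundary_dilation
    if dil is None:
        dil = params.texture_window // 3
    if dil > 0:
        mask = ndi.binary_dilation(mask, structure=disk(dil))
    return WoundSegmentation(mask, float(mask.sum()), None)


@dataclass
class ClosureCurve:
    """Per-frame wound area normalized to the first frame."""

    time_h: np.ndarray
    area_px: np.ndarray
    normalized_area: np.ndarray  # A(t)/A(0)
    closure_percent: np.ndarray  # 100 (1 - A/A0)
    flags: list  # per-frame segmentation flags

    @property
    def expanded(self) -> np.ndarray:
        """Frames where the wound grew beyond its initial area."""
        return self.closure_percent < 0


def closure_curve(
    stack: np.ndarray,
    frame_interval_min: float,
    params: SegmentationParams = SegmentationParams(),
    wound_axis_col: int | None = None,
) -> ClosureCurve:
    """Closure curve of a grayscale time-lapse stack (T, H, W)."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a (T, H, W) grayscale stack")
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    segs = [segment_wound(f, params, wound_axis_col) for f in stack]
    areas = np.array([s.area_px for s in segs], dtype=float)
    if areas[0] <= 0:
        raise ZeroDivisionError("frame-0 wound area is zero; cannot normalize")
    norm = areas / areas[0]
    t = np.arange(stack.shape[0]) * frame_interval_min / 60.0
    return ClosureCurve(
        time_h=t,
        area_px=areas,
        normalized_area=norm,
        closure_percent=100.0 * (1.0 - norm),
        flags=[s.flag for s in segs],
    )


def closure_rate(
    curve: ClosureCurve, window: tuple[float, float] | None = None
) -> float:
    """Closure rate in %/h: OLS slope of closure% vs time.

    The default window runs from t=0 until the first frame at >= 95% closure
    (the slope would otherwise be diluted by the saturated plateau), or over
    all frames if the wound never closes that far.
    """
    t = curve.time_h
    y = curve.closure_percent
    if window is None:
        closed = np.nonzero(y >= 95.0)[0]
        end = closed[0] if closed.size else len(t) - 1
        sel = slice(0, max(int(end) + 1, 3))
    else:
        m = (t >= window[0]) & (t <= window[1])
        sel = np.nonzero(m)[0]
        if sel.size < 3:
            raise ValueError("need at least 3 points in the fit window")
    tt, yy = t[sel], y[sel]
    if len(tt) < 3 or np.ptp(tt) == 0:
        raise ValueError("degenerate fit window")
    slope, _ = np.polyfit(tt, yy, 1)
    return float(slope)


@dataclass
class Kymograph:
    """Time (rows) vs position across the wound (columns)."""

    data: np.ndarray  # (n_frames, roi_width)
    roi: tuple[int, int, int, int]  # row0, col0, row1, col1
    n_lines: int
    frame_interval_min: float


def kymograph(
    stack: np.ndarray,
    roi: tuple[int, int, int, int],
    n_lines: int = 7,
    frame_interval_min: float = 10.0,
) -> Kymograph:
    """Average ``n_lines`` evenly spaced horizontal lines in the ROI per frame.

    Line rows sit at the centres of ``n_lines`` equal vertical strips of the
    ROI (half-spacing margins at top and bottom).  A 12-h stack imaged every
    10 min yields 72 rows.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a (T, H, W) grayscale stack")
    r0, c0, r1, c1 = roi
    T, H, W = stack.shape
    if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
        raise ValueError("ROI outside frame bounds")
    height = r1 - r0
    if n_lines < 1 or n_lines > height:
        raise ValueError("n_lines must be between 1 and the ROI height")
    rows = r0 + np.floor((np.arange(n_lines) + 0.5) * height / n_lines).astype(int)
    data = stack[:, rows, c0:c1].mean(axis=1)
    return Kymograph(
        data=data, roi=roi, n_lines=n_lines, frame_interval_min=frame_interval_min
    )


@dataclass
class TrackStats:
    """Directedness and motility statistics for a cohort of tracks."""

    per_cell: pd.DataFrame  # cell_id, mean_step_cos, net_cos, path_len, speed
    cohort_mean: float  # mean of per-cell mean step cosines
    cohort_sd: float
    n_excluded: int  # cells with no nonzero displacement


class TrackSet:
    """Validated per-cell trajectories (frame, cell_id, x, y)."""

    REQUIRED = ("frame", "cell_id", "x", "y")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"track table missing column(s): {', '.join(missing)}")
        df = df[list(self.REQUIRED)].copy()
        df["frame"] = df["frame"].astype(int)
        df["cell_id"] = df["cell_id"].astype(int)
        df = df.sort_values(["cell_id", "frame"], kind="stable").reset_index(drop=True)
        for cid, sub in df.groupby("cell_id"):
            fr = sub["frame"].to_numpy()
            if np.any(np.diff(fr) <= 0):
                raise ValueError(f"non-monotone frames within track {cid}")
        self.df = df

    def __len__(self) -> int:
        return self.df["cell_id"].nunique()


def directedness(
    tracks: TrackSet | pd.DataFrame, frame_interval_min: float = 10.0
) -> TrackStats:
    """Per-cell and cohort directedness along the +x field axis.

    Per displacement step, cosθ = Δx/√(Δx²+Δy²); zero-length steps are
    skipped.  Reported per cell as the mean step cosine (headline statistic)
    and the net-displacement cosine; cells whose steps are all zero are
    excluded and counted.
    """
    if isinstance(tracks, pd.DataFrame):
        tracks = TrackSet(tracks)
    dt_h = frame_interval_min / 60.0

    recs = []
    n_excluded = 0
    for cid, sub in tracks.df.groupby("cell_id"):
        if len(sub) < 2:
            n_excluded += 1
            continue
        dx = np.diff(sub["x"].to_numpy())
        dy = np.diff(sub["y"].to_numpy())
        step = np.hypot(dx, dy)
        nz = step > 0
        if not nz.any():
            n_excluded += 1
            continue
        cosines = dx[nz] / step[nz]
        net = np.array([sub["x"].iloc[-1] - sub["x"].iloc[0],
                        sub["y"].iloc[-1] - sub["y"].iloc[0]])
        net_len = np.hypot(*net)
        dframes = np.diff(sub["frame"].to_numpy())
        recs.append(
            dict(
                cell_id=cid,
                mean_step_cos=float(cosines.mean()),
                net_cos=float(net[0] / net_len) if net_len > 0 else 0.0,
                path_length=float(step.sum()),
                mean_speed=float(step.sum() / (dframes.sum() * dt_h)),
            )
        )
    per_cell = pd.DataFrame(
        recs, columns=["cell_id", "mean_step_cos", "net_cos", "path_length", "mean_speed"]
    )
    vals = per_cell["mean_step_cos"].to_numpy()
    return TrackStats(
        per_cell=per_cell,
        cohort_mean=float(vals.mean()) if vals.size else float("nan"),
        cohort_sd=float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
        n_excluded=n_excluded,
    )
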