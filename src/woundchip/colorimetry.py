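"""Colorimetric pH sensing with a polyaniline (PANI) indicator layer.

PANI changes color with its protonation/oxidation state: yellow-green in
acid (emeraldine salt), green-blue-blue around neutral (emeraldine base),
and blue to dark purple in base (pernigraniline).  The hue of an RGB image
of the coated channel therefore encodes local pH.  Hue is computed from the
*mean* RGB color of the region of interest (not as a per-pixel average of
hues), then mapped through a bi-dose-response calibration curve

    hue(pH) = A1 + (A2 - A1) * [ p / (1 + 10^{h1 (logx01 - pH)})
                               + (1 - p) / (1 + 10^{h2 (logx02 - pH)}) ]

— a sum of two logistic transitions that captures the two color-change
regimes of PANI over a wide pH range.  pH estimation inverts the fitted
curve numerically on its (monotone) calibration domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit


class CalibrationFitError(RuntimeError):
    """Nonlinear calibration fit failed to converge."""


class HueWarning(UserWarning):
    pass


def rgb_to_hue(rgb: np.ndarray) -> float:
    """Hue in degrees [0, 360) of a single RGB color by the max/min rule.

    Achromatic colors (max == min) have undefined hue; 0° is returned by
    convention with a warning.
    """
    r, g, b = (float(v) for v in rgb)
    mx, mn = max(r, g, b), min(r, g, b)
    if mx == mn:
        warnings.warn("achromatic mean color: hue undefined, returning 0", HueWarning)
        return 0.0
    d = mx - mn
    if mx == r:
        h = ((g - b) / d) % 6.0
    elif mx == g:
        h = (b - r) / d + 2.0
    else:
        h = (r - g) / d + 4.0
    return 60.0 * h


def mean_hue(image: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Hue (degrees) of the mean RGB color over ``mask``.

    Averaging RGB first and converting once differs from averaging per-pixel
    hues (hue is a nonlinear, circular quantity); the mean-color convention
    is used throughout this package.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[-1] < 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if mask is None:
        mask = np.ones(img.shape[:2], dtype=bool)
    if not np.any(mask):
        raise ValueError("empty mask")
    mean_rgb = img[mask].reshape(-1, img.shape[-1])[:, :3].mean(axis=0)
    return rgb_to_hue(mean_rgb)


def bidose_response(
    pH: np.ndarray | float,
    A1: float,
    A2: float,
    logx01: float,
    logx02: float,
    h1: float,
    h2: float,
    p: float,
) -> np.ndarray | float:
    """Dual-logistic hue-vs-pH model; tends to A1 (A2) at low (high) pH."""
    x = np.asarray(pH, dtype=float)
    term1 = p / (1.0 + 10.0 ** (h1 * (logx01 - x)))
    term2 = (1.0 - p) / (1.0 + 10.0 ** (h2 * (logx02 - x)))
    out = A1 + (A2 - A1) * (term1 + term2)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted bi-dose-response hue-vs-pH relation and its valid domain."""

    A1: float
    A2: float
    logx01: float
    logx02: float
    h1: float
    h2: float
    p: float
    rmse: float = 0.0
    pH_min: float = 2.0
    pH_max: float = 12.0

    def __call__(self, pH):
        return bidose_response(
            pH, self.A1, self.A2, self.logx01, self.logx02, self.h1, self.h2, self.p
        )

    @property
    def params(self) -> tuple[float, ...]:
        return (self.A1, self.A2, self.logx01, self.logx02, self.h1, self.h2, self.p)

    def is_monotone(self, n: int = 512) -> bool:
        grid = np.linspace(self.pH_min, self.pH_max, n)
        d = np.diff(self(grid))
        return bool(np.all(d >= 0) or np.all(d <= 0))


#: curve used by the synthetic PANI renderer: green (~80°) in acid through
#: blue to purple (~280°) in base, transitions near pH 6 and 9.5
DEFAULT_PANI_CURVE = CalibrationCurve(
    A1=80.0, A2=280.0, logx01=6.0, logx02=9.5, h1=1.0, h2=1.0, p=0.5,
    pH_min=2.7, pH_max=11.3,
)


def fit_calibration(
    pH_values: np.ndarray,
    hue_values: np.ndarray,
    *,
    max_nfev: int = 20000,
) -> CalibrationCurve:
    """Least-squares bi-dose-response fit of hue vs pH.

    Requires at least 8 distinct pH points (a 15-buffer series spanning
    pH ≈ 2.7–11.3 is typical).  Initialization is heuristic: asymptotes from
    the extreme hues, transition centres from the 25%/75% response crossings,
    unit slopes, equal weights.  Deterministic for given data.
    """
    pH = np.asarray(pH_values, dtype=float)
    hue = np.asarray(hue_values, dtype=float)
    if pH.shape != hue.shape or pH.ndim != 1:
        raise ValueError("pH and hue must be 1-D arrays of equal length")
    if np.unique(pH).size < 8:
        raise CalibrationFitError("need >= 8 distinct pH points for a stable fit")

    order = np.argsort(pH)
    pH, hue = pH[order], hue[order]
    a1, a2 = float(hue[0]), float(hue[-1])
    span = a2 - a1 if a2 != a1 else 1.0
    resp = (hue - a1) / span

    def crossing(level: float) -> float:
        above = np.nonzero(resp >= level)[0]
        return float(pH[above[0]]) if above.size else float(np.median(pH))

    p0 = [a1, a2, crossing(0.25), crossing(0.75), 1.0, 1.0, 0.5]
    lo = [-360.0, -360.0, pH.min() - 2, pH.min() - 2, 0.01, 0.01, 0.0]
    hi = [720.0, 720.0, pH.max() + 2, pH.max() + 2, 10.0, 10.0, 1.0]
    try:
        popt, _ = curve_fit(
            bidose_response, pH, hue, p0=p0, bounds=(lo, hi), max_nfev=max_nfev
        )
    except RuntimeError as exc:
        raise CalibrationFitError(f"calibration fit did not converge: {exc}") from exc

    resid = hue - bidose_response(pH, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return CalibrationCurve(
        *(float(v) for v in popt),
        rmse=rmse,
        pH_min=float(pH.min()),
        pH_max=float(pH.max()),
    )


def hue_to_pH(
    hue: float, curve: CalibrationCurve, tol: float = 1e-4
) -> tuple[float, bool]:
    """Invert the calibration curve by bisection on its domain.

    Returns (pH, extrapolated).  Hues outside the curve's range over the
    calibration domain are clamped to the nearest domain edge and flagged.
    """
    if not curve.is_monotone():
        raise ValueError("calibration curve is not monotone on its domain")
    lo, hi = curve.pH_min, curve.pH_max
    f_lo, f_hi = float(curve(lo)), float(curve(hi))
    a, b = sorted((f_lo, f_hi))
    if hue <= a or hue >= b:
        edge = lo if abs(hue - f_lo) <= abs(hue - f_hi) else hi
        if hue < a - 1e-12 or hue > b + 1e-12:
            warnings.warn(
                f"hue {hue:.2f} outside calibration range [{a:.2f}, {b:.2f}]; "
                "clamped to domain edge",
                HueWarning,
            )
            return float(edge), True
        return float(edge), False
    root = brentq(lambda x: float(curve(x)) - hue, lo, hi, xtol=tol)
    return float(root), False


@dataclass
class PhTrace:
    """Time course of hue and estimated pH within one region of interest."""

    label: str
    time_h: np.ndarray
    hue_deg: np.ndarray
    pH: np.ndarray
    extrapolated: np.ndarray  # bool flags per frame


def roi_ph_traces(
    stack: np.ndarray,
    rois: dict[str, np.ndarray | tuple[int, int, int, int]],
    curve: CalibrationCurve,
    frame_interval_min: float,
) -> list[PhTrace]:
    """Per-frame mean hue → pH for each labelled ROI of an RGB time-lapse.

    ``rois`` maps label → boolean mask or (row0, col0, row1, col1) rectangle.
    """
    stack = np.asarray(stack)
    if stack.ndim != 4 or stack.shape[-1] < 3:
        raise ValueError("expected a (T, H, W, 3) RGB stack")
    n_t, H, W = stack.shape[:3]
    t = np.arange(n_t) * frame_interval_min / 60.0

    traces = []
    for label, roi in rois.items():
        if isinstance(roi, tuple):
            r0, c0, r1, c1 = roi
            if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
                raise ValueError(f"ROI {label!r} outside image bounds")
            mask = np.zeros((H, W), dtype=bool)
            mask[r0:r1, c0:c1] = True
        else:
            mask = np.asarray(roi, dtype=bool)
            if mask.shape != (H, W):
                raise ValueError(f"ROI {label!r} mask shape mismatch")
            if not mask.any():
                raise ValueError(f"ROI {label!r} is empty")
        hues = np.array([mean_hue(stack[k], mask) for k in range(n_t)])
        est = np.array([hue_to_pH(h, curve) for h in hues])
        traces.append(
            PhTrace(
                label=label,
                time_h=t,
                hue_deg=hues,
                pH=est[:, 0].astype(float),
                extrapolated=est[:, 1].astype(bool),
            )
        )
    return traces


def wound_zone_trace(traces: list[PhTrace], labels: tuple[str, ...]) -> PhTrace:
    """Average of several in-channel traces (e.g. before/centre/after wound)."""
    sel = [tr for tr in traces if tr.label in labels]
    if not sel:
        raise ValueError("no traces match the requested labels")
    return PhTrace(
        label="wound_zone_mean",
        time_h=sel[0].time_h.copy(),
        hue_deg=np.mean([tr.hue_deg for tr in sel], axis=0),
        pH=np.mean([tr.pH for tr in sel], axis=0),
        extrapolated=np.any([tr.extrapolated for tr in sel], axis=0),
    )
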