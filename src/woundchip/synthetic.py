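"""Ground-truthed synthetic data for the wound-closure analysis pipeline.

No microscope data ships with this package; instead a seeded generator
produces (a) collective-migration tracks of two cell sheets closing a
scratch gap under an optional electric-field bias, (b) phase-contrast-like
rendered image stacks of those sheets, and (c) RGB stacks of a PANI-coated
channel whose hue follows a known hue-vs-pH calibration curve.  Every
generated object carries its ground truth (tracks, per-frame wound masks,
closure rate, cohort directedness), so the analysis operators can be tested
end to end with known answers.

The migration model is a persistent random walk with drift: each cell's new
heading blends its previous heading, a random turn, a field-bias term along
±x, and — for cells at a free edge — a gap-ward protrusion term standing in
for the edge-driven motility that closes unstimulated wounds.  Pairwise
exclusion keeps cells from overlapping.  The model makes no mechanistic
claim about electrotaxis; it is the simplest generator exhibiting the
observables the analysis measures (closure, directedness, relay reversal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import cKDTree

from .colorimetry import CalibrationCurve, DEFAULT_PANI_CURVE


class PackingError(ValueError):
    """Requested cell count does not fit in the sheet at the exclusion radius."""


@dataclass(frozen=True)
class SimulationParams:
    """Conditions of one synthetic scratch-closure run.

    The defaults describe the canonical stimulation protocol: a 12-h
    time-lapse imaged every 10 min (72 frames), a 512-px field of view with a
    160-px scratch gap, and sheets of 100 cells each.  ``bias`` weights a
    drift toward +x (the cathode side); ``bias_schedule`` optionally gives a
    signed bias per frame for relay scenarios.  ``motility_factor`` scales
    the step length to emulate motility-inhibited (diabetic-like) cells.
    """

    n_cells_per_sheet: int = 320
    domain_px: tuple[int, int] = (512, 512)  # (width, height)
    gap_px: float = 160.0
    persistence: float = 0.6
    speed_px_per_h: float = 12.0
    bias: float = 0.0
    bias_schedule: tuple[float, ...] | None = None  # signed bias per frame
    motility_factor: float = 1.0
    #: kenotactic march of the free edge into the gap, px/h (scaled by
    #: motility_factor); this is what closes unstimulated wounds
    edge_speed_px_per_h: float = 1.8
    #: field modulation of the edge march: the edge advancing with the field
    #: is boosted by (1 + bias_gain*bias), the opposing edge is attenuated
    #: but keeps at least bias_floor of its kenotactic speed
    bias_gain: float = 6.0
    bias_floor: float = 0.6
    edge_band_px: float = 22.0
    exclusion_radius_px: float = 16.0
    #: cell-cell adhesion: pairs separated beyond rest_factor*exclusion_radius
    #: are pulled back with this per-iteration strength (elastic monolayer)
    adhesion_strength: float = 0.2
    adhesion_rest_factor: float = 1.05
    adhesion_cutoff_factor: float = 1.35
    #: density-regulated division keeps the spreading monolayer confluent:
    #: cells with at most `division_max_neighbors` neighbours within
    #: 1.55*exclusion_radius divide with per-frame probability
    #: division_rate * motility_factor (motility inhibition also slows
    #: proliferation), but never within two edge bands of the front
    division_rate: float = 0.15
    division_max_neighbors: int = 4
    #: cells this close to their sheet's outer wall are frozen, representing
    #: the monolayer continuing beyond the field of view
    anchor_band_px: float = 12.0
    cell_radius_px: float = 9.0
    frame_interval_min: float = 10.0
    duration_h: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.persistence < 1.0):
            raise ValueError("persistence must be in [0, 1)")
        if self.bias < 0:
            raise ValueError("bias must be >= 0 (its sign comes from the schedule)")
        if not (0.0 < self.motility_factor <= 1.0):
            raise ValueError("motility factor must be in (0, 1]")
        if self.speed_px_per_h < 0 or self.exclusion_radius_px <= 0:
            raise ValueError("invalid kinematic parameters")

    @property
    def n_frames(self) -> int:
        # half-open convention: 12 h at 10 min -> 72 frames at t = 0..710 min
        return int(round(self.duration_h * 60.0 / self.frame_interval_min))

    def signed_bias(self, frame: int) -> float:
        if self.bias_schedule is not None:
            return self.bias_schedule[frame]
        return self.bias


def relay_bias_schedule(
    params: SimulationParams, bias: float, relay_period_min: float = 30.0
) -> tuple[float, ...]:
    """Signed per-frame bias alternating every relay period (+x first)."""
    out = []
    for k in range(params.n_frames):
        t_min = k * params.frame_interval_min
        phase = int(t_min // relay_period_min)
        out.append(bias if phase % 2 == 0 else -bias)
    return tuple(out)


@dataclass
class GroundTruth:
    """Everything the generator knows about a synthetic run."""

    params: SimulationParams
    tracks: pd.DataFrame  # frame, cell_id, x, y
    positions: list  # per frame: (n_k, 2) array (population grows by division)
    wound_masks: np.ndarray  # (n_frames, H, W) bool
    wound_area_px: np.ndarray
    true_closure_percent: np.ndarray
    true_closure_rate: float  # %/h, OLS over all frames
    true_directedness: float  # cohort mean step cosine

    @property
    def n_frames(self) -> int:
        return len(self.positions)


def _initial_positions(params: SimulationParams, rng: np.random.Generator):
    """Jittered rectangular grids of exactly n cells per sheet.

    Rows run flush to the top/bottom borders so the sheets span the full
    image height and the scratch band is the only cell-free region between
    them.  The grid pitch follows from the requested cell count; a pitch
    tighter than the exclusion radius cannot relax and raises PackingError.
    """
    W, H = params.domain_px
    n = params.n_cells_per_sheet
    sheet_w = (W - params.gap_px) / 2.0
    nx = max(1, int(round(np.sqrt(n * sheet_w / H))))
    nyr = int(np.ceil(n / nx))
    pitch_x = sheet_w / nx
    pitch_y = H / nyr
    if min(pitch_x, pitch_y) < 0.8 * params.exclusion_radius_px:
        raise PackingError(
            f"{n} cells per sheet do not fit a {sheet_w:.0f}x{H} px sheet at "
            f"exclusion radius {params.exclusion_radius_px} px"
        )
    xs = (np.arange(nx) + 0.5) * pitch_x
    ys = np.linspace(0.0, float(H - 1), nyr)
    gx, gy = np.meshgrid(xs, ys)
    lattice = np.column_stack([gx.ravel(), gy.ravel()])[:n]

    def jittered():
        jit = rng.uniform(-0.2, 0.2, size=(n, 2)) * [pitch_x, pitch_y]
        return lattice + jit

    left = jittered()
    right = jittered()
    right[:, 0] = W - right[:, 0]
    pos = np.vstack([left, right])
    pos[:, 1] = np.clip(pos[:, 1], 0, H - 1)
    sheet = np.repeat([0, 1], n)
    return pos, sheet


def _edge_cells(pos, sheet, params, band: float | None = None) -> np.ndarray:
    """Cells within ``band`` of their sheet's gap-facing front (per y-bin)."""
    if band is None:
        band = params.edge_band_px
    H = params.domain_px[1]
    n_bins = max(1, int(H // 32))
    bins = np.clip((pos[:, 1] / H * n_bins).astype(int), 0, n_bins - 1)
    edge = np.zeros(len(pos), dtype=bool)
    for s, extreme in ((0, np.max), (1, np.min)):
        sel = sheet == s
        for b in range(n_bins):
            m = sel & (bins == b)
            if not m.any():
                continue
            front = extreme(pos[m, 0])
            if s == 0:
                edge[m & (pos[:, 0] > front - band)] = True
            else:
                edge[m & (pos[:, 0] < front + band)] = True
    return edge


def _relax(pos, params: SimulationParams, n_iter=4):
    """Pairwise exclusion + short-range adhesion, with wall clipping.

    Overlapping pairs (d < exclusion radius) are pushed apart; separated
    neighbour pairs (rest < d < cutoff) are pulled back toward the rest
    length, which keeps the monolayer cohesive and transmits edge protrusion
    into the bulk as tension.  Pairs in the dead zone feel nothing.
    """
    W, H = params.domain_px
    r_ex = params.exclusion_radius_px
    r_rest = params.adhesion_rest_factor * r_ex
    r_cut = params.adhesion_cutoff_factor * r_ex
    k = params.adhesion_strength
    for _ in range(n_iter):
        pos[:, 0] = np.clip(pos[:, 0], 0, W - 1)
        pos[:, 1] = np.clip(pos[:, 1], 0, H - 1)
        tree = cKDTree(pos)
        pairs = tree.query_pairs(r_cut, output_type="ndarray")
        if len(pairs) == 0:
            break
        d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
        dist = np.linalg.norm(d, axis=1)
        dist = np.where(dist < 1e-9, 1e-9, dist)
        corr = np.where(
            dist < r_ex,
            (r_ex - dist) / 2.0,  # push apart
            np.where(dist > r_rest, -k * (dist - r_rest) / 2.0, 0.0),  # pull back
        )
        vec = d / dist[:, None] * corr[:, None]
        np.add.at(pos, pairs[:, 0], vec)
        np.add.at(pos, pairs[:, 1], -vec)
    pos[:, 0] = np.clip(pos[:, 0], 0, W - 1)
    pos[:, 1] = np.clip(pos[:, 1], 0, H - 1)
    return pos


def wound_mask_from_positions(
    pos: np.ndarray, params: SimulationParams
) -> np.ndarray:
    """True cell-free wound band implied by a set of cell positions.

    Cells are stamped as discs, the occupancy is morphologically closed to
    bridge intercellular gaps, and the wound is the connected cell-free
    component that straddles the image centre column.
    """
    W, H = params.domain_px
    occ = np.zeros((H, W), dtype=bool)
    r = int(round(params.cell_radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    stamp = xx * xx + yy * yy <= r * r
    for x, y in pos:
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(cx - r, 0), min(cx + r + 1, W)
        y0, y1 = max(cy - r, 0), min(cy + r + 1, H)
        if x0 >= x1 or y0 >= y1:
            continue
        occ[y0:y1, x0:x1] |= stamp[
            y0 - (cy - r) : y1 - (cy - r), x0 - (cx - r) : x1 - (cx - r)
        ]
    # bridge intercellular gaps; pad by edge replication so the closing has
    # no border artefacts (outside the view the monolayer continues)
    close_r = int(round(params.exclusion_radius_px / 2))
    if close_r > 0:
        padded = np.pad(occ, close_r, mode="edge")
        occ = ndi.binary_closing(padded, structure=_disk(close_r))[
            close_r:-close_r, close_r:-close_r
        ]
    free = ~occ
    labels, n = ndi.label(free)
    col = W // 2
    ids = np.unique(labels[:, col])
    ids = ids[ids > 0]
    if ids.size == 0:
        return np.zeros((H, W), dtype=bool)
    sizes = ndi.sum_labels(free, labels, ids)
    return labels == int(ids[np.argmax(sizes)])


def _disk(r: int) -> np.ndarray:
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return xx * xx + yy * yy <= r * r


def simulate_collective(params: SimulationParams) -> GroundTruth:
    """Simulate two cell sheets closing a central scratch gap.

    Cells perform a persistent random walk with field bias and gap-ward edge
    protrusion; exclusion/adhesion keeps the monolayer cohesive, and
    density-regulated division backfills the space freed as the fronts
    advance, so the sheets stay confluent while spreading.  Returns a
    GroundTruth with tracks, per-frame true wound masks and areas, the true
    closure rate (%/h, least squares over all frames) and the true cohort
    directedness.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(params.seed)
    W, H = params.domain_px
    pos, sheet = _initial_positions(params, rng)
    n = len(pos)
    dt_h = params.frame_interval_min / 60.0
    step_len = params.speed_px_per_h * params.motility_factor * dt_h

    theta = rng.uniform(0, 2 * np.pi, n)
    heading = np.column_stack([np.cos(theta), np.sin(theta)])
    cell_ids = np.arange(n)
    next_id = n
    r_div = 1.55 * params.exclusion_radius_px

    n_frames = params.n_frames
    positions = [pos.copy()]
    frame_rows = [
        pd.DataFrame(dict(frame=0, cell_id=cell_ids, x=pos[:, 0], y=pos[:, 1]))
    ]
    for k in range(1, n_frames):
        beta = params.signed_bias(k - 1)
        phi = rng.uniform(0, 2 * np.pi, len(pos))
        turn = np.column_stack([np.cos(phi), np.sin(phi)])
        edge = _edge_cells(pos, sheet, params)
        gapward = np.where(sheet == 0, 1.0, -1.0)
        drive = params.persistence * heading + (1.0 - params.persistence) * turn
        drive[:, 0] += beta
        norm = np.linalg.norm(drive, axis=1, keepdims=True)
        norm[norm < 1e-12] = 1.0
        heading = drive / norm
        new_pos = pos + heading * step_len
        # deterministic gap-ward march of the free edge, modulated by the
        # field: the edge moving with the field is boosted, the opposing
        # edge attenuated (floored), emulating leader-cell electrotaxis
        boost = np.clip(1.0 + params.bias_gain * beta * gapward, params.bias_floor, None)
        v_edge = params.edge_speed_px_per_h * params.motility_factor * boost * dt_h
        new_pos[:, 0] += np.where(edge, gapward * v_edge, 0.0)
        # cells at the outer walls stay put: the monolayer continues beyond
        # the field of view
        anchored = np.where(
            sheet == 0,
            pos[:, 0] < params.anchor_band_px,
            pos[:, 0] > W - 1 - params.anchor_band_px,
        )
        new_pos[anchored] = pos[anchored]
        pos = _relax(new_pos, params)
        pos[anchored] = new_pos[anchored]

        # density-regulated division backfills the bulk as the front advances
        if params.division_rate > 0:
            tree = cKDTree(pos)
            counts = np.array([len(c) - 1 for c in tree.query_ball_point(pos, r_div)])
            sparse = counts <= params.division_max_neighbors
            # backfill only behind the front band so division pressure does
            # not itself push the edge forward
            near_front = _edge_cells(pos, sheet, params, band=2.0 * params.edge_band_px)
            divide = sparse & ~near_front & (
                rng.random(len(pos))
                < params.division_rate * np.sqrt(params.motility_factor)
            )
            if divide.any():
                mothers = np.nonzero(divide)[0]
                ang = rng.uniform(0, 2 * np.pi, len(mothers))
                offset = 0.55 * params.exclusion_radius_px
                daughters = pos[mothers] + offset * np.column_stack(
                    [np.cos(ang), np.sin(ang)]
                )
                d_theta = rng.uniform(0, 2 * np.pi, len(mothers))
                pos = np.vstack([pos, daughters])
                heading = np.vstack(
                    [heading, np.column_stack([np.cos(d_theta), np.sin(d_theta)])]
                )
                sheet = np.concatenate([sheet, sheet[mothers]])
                new_ids = np.arange(next_id, next_id + len(mothers))
                next_id += len(mothers)
                cell_ids = np.concatenate([cell_ids, new_ids])
                pos = _relax(pos, params, n_iter=2)

        positions.append(pos.copy())
        frame_rows.append(
            pd.DataFrame(dict(frame=k, cell_id=cell_ids, x=pos[:, 0], y=pos[:, 1]))
        )

    tracks = pd.concat(frame_rows, ignore_index=True)

    masks = np.stack(
        [wound_mask_from_positions(positions[k], params) for k in range(n_frames)]
    )
    areas = masks.sum(axis=(1, 2)).astype(float)
    a0 = areas[0] if areas[0] > 0 else 1.0
    closure = 100.0 * (1.0 - areas / a0)
    t = np.arange(n_frames) * dt_h
    # same fit-window convention as the closure-rate estimator: from t=0
    # until the wound is essentially closed, else all frames
    closed = np.nonzero(closure >= 95.0)[0]
    end = int(closed[0]) if closed.size else n_frames - 1
    sel = slice(0, max(end + 1, 3))
    rate = float(np.polyfit(t[sel], closure[sel], 1)[0])

    per_cell = []
    for _, sub in tracks.groupby("cell_id"):
        dx = np.diff(sub["x"].to_numpy())
        dy = np.diff(sub["y"].to_numpy())
        step = np.hypot(dx, dy)
        nz = step > 0
        if nz.any():
            per_cell.append(float((dx[nz] / step[nz]).mean()))
    true_dir = float(np.mean(per_cell)) if per_cell else float("nan")

    return GroundTruth(
        params=params,
        tracks=tracks,
        positions=positions,
        wound_masks=masks,
        wound_area_px=areas,
        true_closure_percent=closure,
        true_closure_rate=rate,
        true_directedness=true_dir,
    )


@dataclass(frozen=True)
class RenderParams:
    """Phase-contrast-like rendering settings (16-bit grayscale)."""

    background_level: float = 22000.0
    background_gradient: float = 1500.0  # linear shading across the frame
    background_noise: float = 250.0
    cell_interior_level: float = 20000.0
    cell_interior_noise: float = 5200.0  # texture the segmenter keys on
    rim_level: float = 42000.0
    rim_width_px: float = 2.5
    global_noise: float = 300.0


def render_stack(
    truth: GroundTruth, render: RenderParams = RenderParams()
) -> np.ndarray:
    """Render a GroundTruth as a (T, H, W) uint16 phase-contrast-like stack.

    Cells are textured discs (bright rim, noisy interior) on a smooth shaded
    background, plus white noise.  The cell-free gap is low-texture by
    construction, which is the contrast the wound segmenter exploits.
    Deterministic given the simulation seed.
    """
    params = truth.params
    W, H = params.domain_px
    n_frames = truth.n_frames
    if n_frames < 2:
        raise ValueError("need at least 2 frames to render a stack")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xC311]))

    r = params.cell_radius_px
    ri = int(np.ceil(r))
    yy, xx = np.mgrid[-ri : ri + 1, -ri : ri + 1]
    dist = np.hypot(xx, yy)
    inside = dist <= r
    rim = inside & (dist >= r - render.rim_width_px)

    gx = np.linspace(-0.5, 0.5, W)[None, :]
    gy = np.linspace(-0.5, 0.5, H)[:, None]
    background = render.background_level + render.background_gradient * (gx + gy)

    out = np.empty((n_frames, H, W), dtype=np.uint16)
    for k in range(n_frames):
        frame = background + rng.normal(0, render.background_noise, (H, W))
        for (x, y) in truth.positions[k]:
            cx, cy = int(round(x)), int(round(y))
            x0, x1 = max(cx - ri, 0), min(cx + ri + 1, W)
            y0, y1 = max(cy - ri, 0), min(cy + ri + 1, H)
            if x0 >= x1 or y0 >= y1:
                continue
            sy = slice(y0 - (cy - ri), y1 - (cy - ri))
            sx = slice(x0 - (cx - ri), x1 - (cx - ri))
            ins = inside[sy, sx]
            rm = rim[sy, sx]
            patch = frame[y0:y1, x0:x1]
            tex = render.cell_interior_level + rng.normal(
                0, render.cell_interior_noise, patch.shape
            )
            patch[ins] = tex[ins]
            patch[rm] = render.rim_level
        frame += rng.normal(0, render.global_noise, (H, W))
        out[k] = np.clip(frame, 0, 65535).astype(np.uint16)
    return out


# ---------------------------------------------------------------------------
# scenario presets emulating the study conditions: a healthy unstimulated
# control closing at ~3.5 %/h, uni-directional and relayed (pseudo-converging)
# stimulation accelerating closure, and motility-inhibited (diabetic-like)
# cells at ~1.0 %/h recovering to ~2.8 %/h under uni-directional stimulation
# ---------------------------------------------------------------------------

SCENARIOS: dict[str, dict] = {
    "control": dict(bias=0.0, motility_factor=1.0),
    "uni": dict(bias=0.55, motility_factor=1.0),
    "converging": dict(bias=0.8, motility_factor=1.0, relay=True),
    "inhibited": dict(bias=0.0, motility_factor=0.28),
    # stimulation also restores proliferative backfill (division_rate), not
    # just edge motility, so inhibited cultures recover most of their rate
    "inhibited+uni": dict(
        bias=0.55, motility_factor=0.28, bias_gain=10.5, division_rate=0.3
    ),
}


def scenario_params(name: str, seed: int = 0, **overrides) -> SimulationParams:
    """SimulationParams preset for a named study scenario."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; options: {sorted(SCENARIOS)}")
    spec = dict(SCENARIOS[name])
    relay = spec.pop("relay", False)
    params = SimulationParams(seed=seed, **spec, **overrides)
    if relay:
        params = replace(
            params, bias_schedule=relay_bias_schedule(params, params.bias), bias=0.0
        )
    return params


def synthetic_ph_stack(
    ph_schedule,
    curve: CalibrationCurve = DEFAULT_PANI_CURVE,
    hue_noise_deg: float = 2.0,
    shape: tuple[int, int] = (64, 96),
    n_frames: int | None = None,
    seed: int = 0,
    saturation: float = 0.8,
    value: float = 0.85,
) -> np.ndarray:
    """Render an RGB stack whose hue encodes a pH field through ``curve``.

    ``ph_schedule`` is either an array (T, H, W) of per-pixel pH, an array
    (T,) of spatially uniform pH per frame, or a callable t_index -> (H, W)
    array.  Hue noise (degrees, per pixel) is added before HSV→RGB
    conversion; saturation and value are fixed, so recovered hue is invariant
    to the overall brightness.  Returns a (T, H, W, 3) uint8 stack.
    """
    from matplotlib.colors import hsv_to_rgb

    H, W = shape
    if callable(ph_schedule):
        if n_frames is None:
            raise ValueError("n_frames required with a callable schedule")
        fields = np.stack([np.broadcast_to(ph_schedule(k), (H, W)) for k in range(n_frames)])
    else:
        arr = np.asarray(ph_schedule, dtype=float)
        if arr.ndim == 1:
            fields = np.broadcast_to(arr[:, None, None], (arr.shape[0], H, W))
        elif arr.ndim == 3:
            fields = arr
            H, W = arr.shape[1:]
        else:
            raise ValueError("ph_schedule must be (T,), (T, H, W) or callable")

    if np.any(fields < curve.pH_min - 1e-9) or np.any(fields > curve.pH_max + 1e-9):
        raise ValueError("pH schedule leaves the calibration domain")

    rng = np.random.default_rng(seed)
    hue = np.asarray(curve(fields), dtype=float)
    hue = hue + rng.normal(0, hue_noise_deg, hue.shape)
    hsv = np.stack(
        [
            (hue % 360.0) / 360.0,
            np.full_like(hue, saturation),
            np.full_like(hue, value),
        ],
        axis=-1,
    )
    rgb = hsv_to_rgb(hsv)
    return (rgb * 255.0).round().astype(np.uint8)
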