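"""Quasi-static electric-field solver for microchannel networks.

Steady current conservation ∇·(σh ∇V) = 0 is solved on the rasterized
sheet-conductance grid with a 5-point finite-difference stencil.  Walls are
zero-flux; the injected current I is sourced uniformly over the active anode
footprint and sunk over the cathode footprint; the gauge is fixed by pinning
one cathode cell to 0 V.  Face conductances between neighbouring cells are
harmonic means, which handles conductivity jumps (channel edges) correctly.

Because the channel height is much smaller than any lateral dimension the
thin-sheet (2.5-D) model is an accurate stand-in for the full 3-D problem in
the channel interior; absolute network resistances additionally depend on the
reservoir and electrode geometry and are validated here only against closed
forms for uniform conductors.

Sign conventions: the field E = -∇V points from anode to cathode, so with the
canonical anode-left / cathode-right placement the field (and cathodal
migration) is +x.  Units on output: V in mV, E in mV/mm, J in A/m²,
currents in µA, resistances in kΩ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import (
    ChannelNetwork,
    ConductivityMap,
    ElectrodeConfig,
    ElectrodeRole,
    GeometryError,
    Scheme,
    WoundZone,
)


class ConnectivityError(RuntimeError):
    """Anode and cathode footprints are not joined by a conducting path."""


class CalibrationError(RuntimeError):
    """No input current can reach the target field at the wound centre."""


@dataclass
class FieldSolution:
    """Potential / field / current-density maps for one electrode state."""

    map: ConductivityMap
    potential_mV: np.ndarray  # (ny, nx), NaN outside conducting region
    Ex: np.ndarray  # mV/mm
    Ey: np.ndarray  # mV/mm
    E_mag: np.ndarray  # mV/mm
    Jx: np.ndarray  # A/m^2
    Jy: np.ndarray  # A/m^2
    injected_current_uA: float
    resistance_kohm: float
    state: str = "uni"
    anode_reservoir_index: int = 0
    cathode_reservoir_index: int = 0

    @property
    def J_mag(self) -> np.ndarray:
        return np.hypot(self.Jx, self.Jy)

    def power_density(self) -> np.ndarray:
        """Dissipated areal power density |J|^2 h / sigma = sigma h |E|^2, W/m^2.

        Computed from the sheet conductance and the field so it is defined on
        every conducting cell; zero elsewhere.
        """
        e_si = np.nan_to_num(self.E_mag)  # mV/mm == V/m
        return self.map.sheet_conductance * e_si**2


@dataclass
class WoundProfiles:
    """|E| line profiles through the wound-zone centroid."""

    along_position_mm: np.ndarray  # y positions
    along_E: np.ndarray  # |E| on the vertical line through the centre
    across_position_mm: np.ndarray  # x positions
    across_E: np.ndarray  # |E| on the horizontal line
    center_E: float  # mV/mm at the intersection


def _electrode_component(cond: np.ndarray, masks: list[np.ndarray]) -> np.ndarray:
    """Connected conducting component containing every mask, else raise."""
    labels, _ = ndi.label(cond)
    sets = []
    for m in masks:
        s = set(np.unique(labels[m & cond])) - {0}
        if not s:
            raise ConnectivityError("electrode footprint has no conducting cells")
        sets.append(s)
    common = set.intersection(*sets)
    if not common:
        raise ConnectivityError("anode and cathode are not connected")
    return labels == common.pop()


def _assemble(g: np.ndarray, spacing_mm: float):
    """Sparse weighted graph Laplacian over conducting cells.

    Face conductance between two neighbouring cells of sheet conductance g1,
    g2 is the harmonic mean (cell size cancels for a square grid).
    Returns (L, index map) where index maps (i, j) -> unknown number.
    """
    ny, nx = g.shape
    cond = g > 0
    idx = -np.ones((ny, nx), dtype=np.int64)
    idx[cond] = np.arange(int(cond.sum()))
    n = int(cond.sum())

    rows, cols, vals = [], [], []

    def add_edges(ga, gb, ia, ib):
        both = (ga > 0) & (gb > 0)
        w = np.zeros_like(ga)
        w[both] = 2.0 * ga[both] * gb[both] / (ga[both] + gb[both])
        a = ia[both]
        b = ib[both]
        wv = w[both]
        rows.extend([a, b, a, b])
        cols.extend([b, a, a, b])
        vals.extend([-wv, -wv, wv, wv])

    add_edges(g[:, :-1], g[:, 1:], idx[:, :-1], idx[:, 1:])
    add_edges(g[:-1, :], g[1:, :], idx[:-1, :], idx[1:, :])

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    L = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return L, idx


def solve_field(
    cmap: ConductivityMap,
    config: ElectrodeConfig,
    state: str | int = "uni",
    current_uA: float | None = None,
) -> FieldSolution:
    """Solve the steady potential for one electrode state.

    Parameters
    ----------
    state
        ``"uni"`` for the uni-directional scheme; for pseudo-converging pass
        the index (0 or 1) of the active anode, or ``"anode0"``/``"anode1"``.
    current_uA
        Override the configured injected current (used by calibration).

    Returns
    -------
    FieldSolution
    """
    anodes = config.anodes
    if config.scheme is Scheme.UNI_DIRECTIONAL:
        active_anode = anodes[0]
        label = "uni"
    else:
        if isinstance(state, str):
            if state == "uni":
                state = 0
            else:
                state = int(state.removeprefix("anode"))
        active_anode = anodes[int(state)]
        label = f"anode{int(state)}"

    I_uA = active_anode.current_uA if current_uA is None else float(current_uA)
    I_A = I_uA * 1e-6

    anode_mask = cmap.electrode_masks[active_anode.reservoir_index] & cmap.conducting
    cathode_mask = (
        cmap.electrode_masks[config.cathode.reservoir_index] & cmap.conducting
    )
    component = _electrode_component(cmap.conducting, [anode_mask, cathode_mask])
    g = np.where(component, cmap.sheet_conductance, 0.0)
    anode_mask &= component
    cathode_mask &= component

    L, idx = _assemble(g, cmap.grid_spacing)
    n = L.shape[0]
    b = np.zeros(n)
    b[idx[anode_mask]] = I_A / anode_mask.sum()
    b[idx[cathode_mask]] -= I_A / cathode_mask.sum()

    # gauge: pin one cathode cell to 0 V
    pin = int(idx[cathode_mask].ravel()[0])
    L = L.tolil()
    L.rows[pin] = [pin]
    L.data[pin] = [1.0]
    L = L.tocsr()
    b[pin] = 0.0

    V = spla.spsolve(L, b)
    res = np.linalg.norm(L @ V - b)
    scale = max(np.linalg.norm(b), 1e-30)
    if not np.all(np.isfinite(V)) or res / scale > 1e-8:
        raise RuntimeError(f"field solve did not reach tolerance (rel res {res/scale:.2e})")

    ny, nx = g.shape
    Vgrid = np.full((ny, nx), np.nan)
    Vgrid[component] = V
    # conducting islands without any source stay at the gauge potential
    Vgrid[cmap.conducting & ~component] = 0.0

    R_ohm = (
        float(np.nanmean(Vgrid[anode_mask]) - np.nanmean(Vgrid[cathode_mask])) / I_A
        if I_A != 0
        else 0.0
    )

    Ex, Ey = _gradient_field(Vgrid, cmap.grid_spacing)  # V/m == mV/mm
    h_m = cmap.network.channel_height * 1e-3 if cmap.network is not None else None
    sigma = np.zeros_like(g)
    if h_m:
        sigma[cmap.conducting] = g[cmap.conducting] / h_m
    Jx = sigma * np.nan_to_num(Ex)
    Jy = sigma * np.nan_to_num(Ey)

    return FieldSolution(
        map=cmap,
        potential_mV=Vgrid * 1e3,
        Ex=Ex,
        Ey=Ey,
        E_mag=np.hypot(Ex, Ey),
        Jx=Jx,
        Jy=Jy,
        injected_current_uA=I_uA,
        resistance_kohm=R_ohm / 1e3,
        state=label,
        anode_reservoir_index=active_anode.reservoir_index,
        cathode_reservoir_index=config.cathode.reservoir_index,
    )


def _gradient_field(V: np.ndarray, spacing_mm: float):
    """E = -∇V by central differences, one-sided at channel edges (V in volts,
    spacing in mm, so the result is V/m = mV/mm)."""
    h = spacing_mm * 1e-3
    ny, nx = V.shape
    Ex = np.full_like(V, np.nan)
    Ey = np.full_like(V, np.nan)
    ok = np.isfinite(V)

    def d1(a, okm, axis):
        out = np.full_like(a, np.nan)
        fwd = np.roll(a, -1, axis)
        bwd = np.roll(a, 1, axis)
        okf = np.roll(okm, -1, axis)
        okb = np.roll(okm, 1, axis)
        # mask wrap-around
        if axis == 1:
            okf[:, -1] = False
            okb[:, 0] = False
        else:
            okf[-1, :] = False
            okb[0, :] = False
        central = okm & okf & okb
        out[central] = (fwd[central] - bwd[central]) / (2 * h)
        fonly = okm & okf & ~okb
        out[fonly] = (fwd[fonly] - a[fonly]) / h
        bonly = okm & ~okf & okb
        out[bonly] = (a[bonly] - bwd[bonly]) / h
        iso = okm & ~okf & ~okb
        out[iso] = 0.0
        return out

    Ex = -d1(V, ok, axis=1)
    Ey = -d1(V, ok, axis=0)
    return Ex, Ey


def cut_current_uA(sol: FieldSolution, x_cut_mm: float) -> float:
    """Net current (µA) crossing the vertical line x = x_cut, +x positive.

    Computed from face conductances times potential differences across the
    cut, i.e. exactly the discrete flux the solver conserves.
    """
    cmap = sol.map
    j = int(np.searchsorted(cmap.x, x_cut_mm))
    if j <= 0 or j >= len(cmap.x):
        raise GeometryError("cut outside grid")
    g = cmap.sheet_conductance
    V = sol.potential_mV * 1e-3
    ga, gb = g[:, j - 1], g[:, j]
    both = (ga > 0) & (gb > 0)
    w = np.zeros_like(ga)
    w[both] = 2 * ga[both] * gb[both] / (ga[both] + gb[both])
    dv = np.where(both, V[:, j - 1] - V[:, j], 0.0)
    return float(np.nansum(w * dv)) * 1e6


def wound_profiles(sol: FieldSolution, wound_zone: WoundZone | None = None) -> WoundProfiles:
    """|E| profiles along (y) and across (x) the wound through its centroid."""
    cmap = sol.map
    if wound_zone is None:
        if cmap.network is None:
            raise GeometryError("no wound zone available")
        wound_zone = cmap.network.wound_zone
    if not cmap.wound_mask.any():
        raise GeometryError("wound zone outside conducting region")
    cx, cy = wound_zone.center
    jc = int(np.argmin(np.abs(cmap.x - cx)))
    ic = int(np.argmin(np.abs(cmap.y - cy)))
    if not cmap.conducting[ic, jc]:
        raise GeometryError("wound centre is not a conducting cell")
    E = sol.E_mag
    return WoundProfiles(
        along_position_mm=cmap.y.copy(),
        along_E=E[:, jc].copy(),
        across_position_mm=cmap.x.copy(),
        across_E=E[ic, :].copy(),
        center_E=float(E[ic, jc]),
    )


def field_at_wound_center(sol: FieldSolution) -> float:
    return wound_profiles(sol).center_E


def calibrate_current(
    cmap: ConductivityMap,
    config: ElectrodeConfig,
    target_E_center: float,
    state: str | int = "uni",
    *,
    verify: bool = True,
) -> float:
    """Input current (µA) that yields ``target_E_center`` (mV/mm) at the wound
    centre.

    The problem is linear in I, so one unit solve plus scaling suffices; a
    confirming solve checks the result to 0.5%.
    """
    if not (target_E_center > 0):
        raise CalibrationError("target field must be > 0")
    probe = solve_field(cmap, config, state, current_uA=1.0)
    e1 = field_at_wound_center(probe)
    if not np.isfinite(e1) or e1 <= 0:
        raise CalibrationError("zero field at wound centre for any current (dead zone)")
    I = target_E_center / e1
    if verify:
        check = field_at_wound_center(solve_field(cmap, config, state, current_uA=I))
        if abs(check - target_E_center) > 5e-3 * target_E_center:
            raise CalibrationError(
                f"calibration verification failed: {check} vs {target_E_center}"
            )
    return float(I)


def branch_mask(cmap: ConductivityMap, segment, t0: float = 1 / 3, t1: float = 2 / 3) -> np.ndarray:
    """Conducting cells inside the [t0, t1] parametric span of a segment."""
    import shapely
    from shapely.geometry import LineString

    p0 = np.asarray(segment.start)
    p1 = np.asarray(segment.end)
    sub = LineString([p0 + t0 * (p1 - p0), p0 + t1 * (p1 - p0)]).buffer(
        segment.width / 2.0, cap_style="flat"
    )
    XX, YY = np.meshgrid(cmap.x, cmap.y)
    inside = shapely.contains_xy(sub, XX.ravel(), YY.ravel()).reshape(cmap.shape)
    return inside & cmap.conducting


def cathode_branch_mask(sol: FieldSolution) -> np.ndarray:
    """Middle third of the channel branch that feeds the cathode reservoir."""
    cmap = sol.map
    if cmap.network is None:
        raise GeometryError("no network metadata on the conductivity map")
    cathode = cmap.network.reservoirs[sol.cathode_reservoir_index]
    c = np.asarray(cathode.center)
    seg = min(
        cmap.network.segments,
        key=lambda s: min(
            np.linalg.norm(c - np.asarray(s.start)),
            np.linalg.norm(c - np.asarray(s.end)),
        ),
    )
    return branch_mask(cmap, seg)


def dead_zone_metric(
    sol: FieldSolution, reference_mask: np.ndarray | None = None
) -> float:
    """|E| at the wound centre over mean |E| in a reference branch region.

    1 for a uniform straight channel; < 1 when current short-cuts around the
    junction and starves the wound region (dead zone).  ``reference_mask``
    defaults to the middle third of the cathode-containing branch — the branch
    that carries the full injected current in every electrode state.
    """
    center = field_at_wound_center(sol)
    if reference_mask is None:
        reference_mask = cathode_branch_mask(sol)
    vals = sol.E_mag[reference_mask & np.isfinite(sol.E_mag)]
    ref = float(np.mean(vals)) if vals.size else 0.0
    if ref <= 0:
        raise ZeroDivisionError("zero reference field: dead-zone ratio undefined")
    return center / ref


def relay_sequence(
    cmap: ConductivityMap,
    config: ElectrodeConfig,
    duration_h: float,
    relay_period_min: float | None = None,
) -> list[tuple[tuple[float, float], FieldSolution]]:
    """Alternating anode solutions for the pseudo-converging relay scheme.

    Returns [((t_start_h, t_end_h), FieldSolution), ...] with the active anode
    switching each period (anode 0 first).  Both distinct solutions are solved
    once and reused across intervals.
    """
    if config.scheme is not Scheme.PSEUDO_CONVERGING:
        raise GeometryError("relay sequence requires the pseudo_converging scheme")
    period_min = config.relay_period_min if relay_period_min is None else relay_period_min
    if period_min <= 0:
        raise GeometryError("relay period must be > 0")
    if duration_h < 0:
        raise GeometryError("duration must be >= 0")
    period_h = period_min / 60.0
    n = int(round(duration_h / period_h))
    sols = [solve_field(cmap, config, state=k) for k in range(2)]
    out = []
    for k in range(n):
        t0, t1 = k * period_h, min((k + 1) * period_h, duration_h)
        out.append(((t0, t1), sols[k % 2]))
    return out
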