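"""Joule-energy analytics, transient heat solve, and electrode charge budget.

The thermal model bounds the temperature rise in the wound zone during a DC
stimulation protocol.  The chip is treated as a stack of thin layers over the
2-D plan view: the electrolyte-filled channel (where present), a plastic
substrate below and a plastic lid above.  Per grid cell the layers contribute
a lumped areal heat capacity (J m⁻² K⁻¹) and an in-plane sheet thermal
conductance (W K⁻¹ per square); heat leaves through the top and bottom faces
by convection to the surroundings.  The volumetric Joule source |J|²/σ of the
field solution becomes an areal source σh|E|² on conducting cells.

Because losses are linear, the temperature rise grows monotonically to a
steady state; the reported maximum is therefore conservative with respect to
protocol length.  The steady state is independent of the heat capacities,
which only set how fast it is approached.

Note on material data: thermal conductivity of the PBS electrolyte defaults
to 2 W m⁻¹ K⁻¹ and the water-like heat capacity to 4184 J kg⁻¹ K⁻¹; both are
configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fields import FieldSolution
from .geometry import ConductivityMap


class DomainError(ValueError):
    """Physically invalid input (negative current, zero diameter, ...)."""


@dataclass(frozen=True)
class Material:
    """Bulk material properties."""

    k: float  # thermal conductivity, W/m/K
    rho: float  # density, kg/m^3
    cp: float  # heat capacity, J/kg/K
    sigma: float = 0.0  # electrical conductivity, S/m

    def __post_init__(self) -> None:
        if self.k <= 0 or self.rho <= 0 or self.cp <= 0:
            raise DomainError("material properties must be > 0")


@dataclass(frozen=True)
class MaterialProps:
    """Per-material property table for the chip stack."""

    electrolyte: Material = Material(k=2.0, rho=1000.0, cp=4184.0, sigma=1.54)
    acrylic: Material = Material(k=0.19, rho=1190.0, cp=1420.0, sigma=1e-14)
    electrode_polymer: Material = Material(k=0.348, rho=1060.0, cp=1415.0, sigma=2000.0)


@dataclass(frozen=True)
class ThermalBC:
    """Boundary conditions for the heat solve.

    Convective exchange with the incubator environment at ``T_ext`` through
    ``n_convective_faces`` horizontal faces (top and bottom by default).  An
    optional linearized radiative term adds 4·ε·σ_SB·T³ to the loss
    coefficient; it is negligible at the sub-kelvin rises seen here and off
    by default.
    """

    T_ext: float = 310.15  # K
    h_conv: float = 5.0  # W/m^2/K
    emissivity: float = 0.95
    include_radiation: bool = False
    T_init: float = 310.15  # K
    n_convective_faces: int = 2

    def __post_init__(self) -> None:
        if self.h_conv < 0:
            raise DomainError("convective coefficient must be >= 0")
        if not (0.0 <= self.emissivity <= 1.0):
            raise DomainError("emissivity must be in [0, 1]")

    def loss_coefficient(self) -> float:
        """Effective areal loss coefficient, W/m^2/K."""
        h = self.h_conv * self.n_convective_faces
        if self.include_radiation:
            h += 4.0 * self.emissivity * 5.670374419e-8 * self.T_ext**3
        return h


@dataclass(frozen=True)
class ElectrodeSpec:
    """Disc electrode with a finite capacitive charge store."""

    diameter_mm: float = 12.0
    csc_mC_per_cm2: float = 40.0  # charge storage capacity

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.csc_mC_per_cm2 < 0:
            raise DomainError("electrode spec values must be positive")

    @property
    def area_cm2(self) -> float:
        return math.pi * (self.diameter_mm / 20.0) ** 2

    @property
    def stored_charge_mC(self) -> float:
        return self.csc_mC_per_cm2 * self.area_cm2


def joule_energy(current_uA: float, resistance_kohm: float, duration_h: float) -> float:
    """Dissipated energy I²Rt in joules for a galvanostatic protocol.

    25 µA across 101.6 kΩ for 12 h gives 2.74 J; 20 µA across 108.3 kΩ for
    12 h gives 1.87 J.
    """
    if current_uA < 0 or resistance_kohm < 0 or duration_h < 0:
        raise DomainError("inputs must be >= 0")
    I = current_uA * 1e-6
    R = resistance_kohm * 1e3
    t = duration_h * 3600.0
    return I * I * R * t


def disc_current_density(current_mA: float, diameter_mm: float) -> float:
    """Current density over a disc electrode, mA/cm²."""
    if diameter_mm <= 0:
        raise DomainError("diameter must be > 0")
    if current_mA < 0:
        raise DomainError("current must be >= 0")
    return current_mA / (math.pi * (diameter_mm / 20.0) ** 2)


def capacitive_duration(spec: ElectrodeSpec, current_uA: float) -> float:
    """How long the electrode can source current capacitively: t = q/i, s."""
    if current_uA <= 0:
        raise DomainError("current must be > 0")
    return spec.stored_charge_mC * 1e-3 / (current_uA * 1e-6)


@dataclass
class ChargeBudget:
    """State-of-charge traces for relay-switched anodes."""

    time_h: np.ndarray  # phase boundary times
    soc_mC: np.ndarray  # (n_anodes, n_times) remaining charge
    faradaic_onset: bool
    onset_time_h: float | None  # first time an anode's net discharge exceeds q
    onset_phase: int | None  # 1-based index of the offending active phase


def relay_charge_budget(
    spec: ElectrodeSpec,
    current_uA: float,
    relay_period_min: float,
    duration_h: float,
    recharge_fraction: float = 0.9,
    n_anodes: int = 2,
) -> ChargeBudget:
    """Charge accounting for alternating anodes under a relay scheme.

    Each anode delivers I·τ of charge during its active phase and passively
    recovers ``recharge_fraction`` of that just-delivered charge from solution
    while idle.  Faradaic onset is flagged when an anode's cumulative net
    discharge exceeds its stored charge q = CSC·area, i.e. when delivery can
    no longer be purely capacitive.
    """
    if not (0.0 <= recharge_fraction <= 1.0):
        raise DomainError("recharge fraction must be in [0, 1]")
    if current_uA < 0 or relay_period_min <= 0 or duration_h < 0:
        raise DomainError("invalid protocol values")

    q = spec.stored_charge_mC
    tau_s = relay_period_min * 60.0
    phase_charge = current_uA * 1e-6 * tau_s * 1e3  # mC per full active phase
    n_phases = int(math.ceil(duration_h * 3600.0 / tau_s)) if duration_h > 0 else 0

    soc = np.full(n_anodes, q)
    times = [0.0]
    socs = [soc.copy()]
    onset_time = None
    onset_phase = None
    for ph in range(n_phases):
        t0 = ph * tau_s
        t1 = min((ph + 1) * tau_s, duration_h * 3600.0)
        frac = (t1 - t0) / tau_s
        active = ph % n_anodes
        delivered = phase_charge * frac
        new_soc = soc[active] - delivered
        if onset_time is None and new_soc < 0.0:
            # onset when the cumulative net discharge crosses q mid-phase
            t_cross = t0 + soc[active] / (current_uA * 1e-6 * 1e3) if current_uA > 0 else t1
            onset_time = t_cross / 3600.0
            onset_phase = ph + 1
        soc[active] = new_soc
        # idle anodes recover up to recharge_fraction of one phase's delivery
        for a in range(n_anodes):
            if a != active:
                deficit = q - soc[a]
                if deficit > 0:
                    soc[a] += min(deficit, recharge_fraction * phase_charge)
        times.append(t1 / 3600.0)
        socs.append(soc.copy())

    return ChargeBudget(
        time_h=np.asarray(times),
        soc_mC=np.asarray(socs).T,
        faradaic_onset=onset_time is not None,
        onset_time_h=onset_time,
        onset_phase=onset_phase,
    )


@dataclass
class ThermalResult:
    """Outcome of a transient heat solve."""

    time_h: np.ndarray
    wound_max_dT: np.ndarray  # max ΔT over the wound mask at each time, °C
    global_max_dT: np.ndarray
    max_wound_dT: float  # max over time within the wound zone, °C
    final_dT_map: np.ndarray

    @property
    def steady(self) -> bool:
        if len(self.wound_max_dT) < 2:
            return False
        a, b = self.wound_max_dT[-2:]
        return abs(b - a) <= 1e-6 * max(abs(b), 1e-12)


@dataclass(frozen=True)
class LayerStack:
    """Out-of-plane layer thicknesses, mm."""

    substrate_mm: float = 1.0
    lid_mm: float = 8.5


def transient_heat(
    cmap: ConductivityMap,
    sol: FieldSolution | None,
    props: MaterialProps = MaterialProps(),
    bc: ThermalBC = ThermalBC(),
    duration_h: float = 12.0,
    dt_s: float = 60.0,
    layers: LayerStack = LayerStack(),
    source_W_m2: np.ndarray | None = None,
) -> ThermalResult:
    """Implicit transient heat solve of the layered chip plan view.

    Parameters
    ----------
    cmap
        Conductivity map defining the grid and the channel footprint.  Use a
        generous rasterization margin (several mm) so lateral spreading into
        the surrounding plastic is captured; heat spreads over a length
        sqrt(k_sheet/h_loss) ≈ 10–20 mm here.
    sol
        Field solution providing the Joule source (σh|E|², W/m²).  Pass
        ``None`` together with ``source_W_m2`` for a prescribed source.
    duration_h, dt_s
        Protocol length and backward-Euler step.

    Returns
    -------
    ThermalResult with the maximum wound-zone temperature rise in °C.
    """
    if duration_h <= 0:
        raise DomainError("duration must be > 0")
    if dt_s <= 0:
        raise DomainError("time step must be > 0")
    if sol is not None and sol.map.shape != cmap.shape:
        raise ValueError(
            "field solution was computed on a different grid than the "
            "conductivity map; solve the field on the thermal grid"
        )

    ny, nx = cmap.shape
    a_cell = (cmap.grid_spacing * 1e-3) ** 2  # m^2
    chan = cmap.conducting
    h_ch = cmap.network.channel_height * 1e-3 if cmap.network is not None else 0.08e-3
    t_sub = layers.substrate_mm * 1e-3
    t_lid = layers.lid_mm * 1e-3

    el, ac = props.electrolyte, props.acrylic
    # areal heat capacity: plastic everywhere, electrolyte only in channels
    # (outside the channel the adhesive layer is modelled as plastic too)
    cap = np.full((ny, nx), ac.rho * ac.cp * (t_sub + t_lid + h_ch))
    cap[chan] = ac.rho * ac.cp * (t_sub + t_lid) + el.rho * el.cp * h_ch
    # in-plane sheet thermal conductance
    ksheet = np.full((ny, nx), ac.k * (t_sub + t_lid + h_ch))
    ksheet[chan] = ac.k * (t_sub + t_lid) + el.k * h_ch

    if source_W_m2 is None:
        if sol is None:
            source_W_m2 = np.zeros((ny, nx))
        else:
            source_W_m2 = sol.power_density()
    src = np.asarray(source_W_m2, dtype=float)

    h_loss = bc.loss_coefficient()

    # assemble conduction Laplacian over all cells (harmonic-mean faces)
    idx = np.arange(ny * nx).reshape(ny, nx)
    rows, cols, vals = [], [], []

    def add(ka, kb, ia, ib):
        w = 2.0 * ka * kb / (ka + kb)  # W/K per square; square grid: per face
        a, b, wv = ia.ravel(), ib.ravel(), w.ravel()
        rows.extend([a, b, a, b])
        cols.extend([b, a, a, b])
        vals.extend([-wv, -wv, wv, wv])

    add(ksheet[:, :-1], ksheet[:, 1:], idx[:, :-1], idx[:, 1:])
    add(ksheet[:-1, :], ksheet[1:, :], idx[:-1, :], idx[1:, :])
    K = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ny * nx, ny * nx),
    )

    C = sp.diags((cap * a_cell).ravel())  # J/K per cell
    H = sp.diags(np.full(ny * nx, h_loss * a_cell))  # W/K per cell
    S = (src * a_cell).ravel()  # W per cell

    A = (C / dt_s + K + H).tocsc()
    lu = spla.splu(A)

    n_steps = int(math.ceil(duration_h * 3600.0 / dt_s))
    dT = np.zeros(ny * nx)
    wound = cmap.wound_mask.ravel()
    if not wound.any():
        wound = chan.ravel()
    t_hist = [0.0]
    w_hist = [0.0]
    g_hist = [0.0]
    crhs = C / dt_s
    for k in range(n_steps):
        dT = lu.solve(crhs @ dT + S)
        t_hist.append(min((k + 1) * dt_s, duration_h * 3600.0) / 3600.0)
        w_hist.append(float(dT[wound].max()) if wound.any() else 0.0)
        g_hist.append(float(dT.max()))

    return ThermalResult(
        time_h=np.asarray(t_hist),
        wound_max_dT=np.asarray(w_hist),
        global_max_dT=np.asarray(g_hist),
        max_wound_dT=float(np.max(w_hist)),
        final_dT_map=dT.reshape(ny, nx),
    )


def steady_uniform_dT(source_W_m2: float, bc: ThermalBC) -> float:
    """Closed-form steady rise for a spatially uniform source: q'' / h_loss."""
    h = bc.loss_coefficient()
    if h <= 0:
        raise DomainError("steady state undefined without convective loss")
    return source_W_m2 / h
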