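"""Parametric microchannel-network layouts and their rasterization.

A chip is a planar network of straight microchannel segments that meet at a
central junction, terminated by circular open reservoirs that hold the
electrodes.  Three canonical layouts are supported:

``straight``
    one channel, two reservoirs; supports only a uni-directional field.
``t_junction``
    three branches at right angles; a converging configuration short-cuts
    current through the bend and leaves a field dead zone at the junction.
``peace_sign``
    two anode branches angled toward the junction, one cathode branch, and a
    fourth "scratch runway" branch (0.9 mm wide so a p10 pipette tip fits)
    used to create the wound; the angling mitigates the dead zone.

Coordinates are millimetres, origin at the network junction, x to the right
and y up.  The wound zone is an axis-aligned rectangle centred on the
junction.  Rasterization produces a cell-centred grid of sheet conductance
(electrolyte conductivity times channel height, in siemens) used by the
field and thermal solvers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
import shapely

from shapely.geometry import LineString, Point, box
from shapely.ops import unary_union

#: conductivity of 1x (10 mM) phosphate-buffered saline, S/m
PBS_CONDUCTIVITY = 1.54

#: default channel width, mm (scratch runway; adopted for all branches)
DEFAULT_WIDTH_MM = 0.9
#: default channel height (out-of-plane), mm
DEFAULT_HEIGHT_MM = 0.08
#: default branch length junction->reservoir, mm
DEFAULT_BRANCH_MM = 5.0
#: default reservoir radius, mm
DEFAULT_RESERVOIR_MM = 2.0
#: default wound-zone extent along the channel axis, mm (pipette-tip scale)
DEFAULT_WOUND_SPAN_MM = 0.7


class LayoutKind(str, Enum):
    STRAIGHT = "straight"
    T_JUNCTION = "t_junction"
    PEACE_SIGN = "peace_sign"


class ElectrodeRole(str, Enum):
    ANODE = "anode"
    CATHODE = "cathode"


class Scheme(str, Enum):
    UNI_DIRECTIONAL = "uni_directional"
    PSEUDO_CONVERGING = "pseudo_converging"


class GeometryError(ValueError):
    """Invalid chip geometry (non-positive dimension, empty region, ...)."""


class ResolutionError(ValueError):
    """Grid spacing too coarse to resolve the narrowest channel."""


@dataclass(frozen=True)
class Segment:
    """A straight channel segment of constant width (mm)."""

    start: tuple[float, float]
    end: tuple[float, float]
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise GeometryError(f"segment width must be > 0, got {self.width}")
        if math.dist(self.start, self.end) == 0:
            raise GeometryError("zero-length segment")

    @property
    def length(self) -> float:
        return math.dist(self.start, self.end)

    def polygon(self):
        return LineString([self.start, self.end]).buffer(
            self.width / 2.0, cap_style="flat"
        )


@dataclass(frozen=True)
class Reservoir:
    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GeometryError(f"reservoir radius must be > 0, got {self.radius}")

    def polygon(self):
        return Point(self.center).buffer(self.radius, quad_segs=64)


@dataclass(frozen=True)
class WoundZone:
    """Axis-aligned rectangle (mm): (xmin, ymin, xmax, ymax)."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if self.xmax <= self.xmin or self.ymax <= self.ymin:
            raise GeometryError("degenerate wound zone")

    @property
    def center(self) -> tuple[float, float]:
        return ((self.xmin + self.xmax) / 2.0, (self.ymin + self.ymax) / 2.0)

    def polygon(self):
        return box(self.xmin, self.ymin, self.xmax, self.ymax)


@dataclass(frozen=True)
class ChannelNetwork:
    """A planar microchannel network with reservoirs and a wound zone."""

    layout_kind: LayoutKind
    segments: tuple[Segment, ...]
    reservoirs: tuple[Reservoir, ...]
    wound_zone: WoundZone
    scratch_runway_width: float = DEFAULT_WIDTH_MM
    channel_height: float = DEFAULT_HEIGHT_MM

    def __post_init__(self) -> None:
        if self.channel_height <= 0:
            raise GeometryError("channel height must be > 0")
        if self.scratch_runway_width <= 0:
            raise GeometryError("runway width must be > 0")
        if self.segments and not any(
            s.polygon().intersects(self.wound_zone.polygon()) for s in self.segments
        ):
            raise GeometryError("wound zone does not intersect any channel segment")

    @property
    def min_width(self) -> float:
        if not self.segments:
            return math.inf
        return min(s.width for s in self.segments)

    def conducting_polygon(self):
        parts = [s.polygon() for s in self.segments]
        parts += [r.polygon() for r in self.reservoirs]
        if not parts:
            return shapely.geometry.Polygon()
        return unary_union(parts)

    def geometry_hash(self) -> str:
        import hashlib

        desc = repr(
            (
                self.layout_kind.value,
                self.segments,
                self.reservoirs,
                self.wound_zone,
                self.scratch_runway_width,
                self.channel_height,
            )
        )
        return hashlib.sha256(desc.encode()).hexdigest()


@dataclass(frozen=True)
class Electrode:
    reservoir_index: int
    role: ElectrodeRole
    current_uA: float  # magnitude of injected current when active


@dataclass(frozen=True)
class ElectrodeConfig:
    """Electrode placement and stimulation scheme.

    In ``uni_directional`` mode the single anode sources ``current_uA`` and the
    cathode sinks it.  In ``pseudo_converging`` mode two anodes flank the
    cathode and a relay activates exactly one anode at a time, switching every
    ``relay_period_min`` minutes.
    """

    electrodes: tuple[Electrode, ...]
    scheme: Scheme
    relay_period_min: float = 30.0

    def __post_init__(self) -> None:
        anodes = [e for e in self.electrodes if e.role is ElectrodeRole.ANODE]
        cathodes = [e for e in self.electrodes if e.role is ElectrodeRole.CATHODE]
        if self.scheme is Scheme.UNI_DIRECTIONAL:
            if len(anodes) != 1 or len(cathodes) != 1:
                raise GeometryError("uni_directional needs 1 anode + 1 cathode")
        else:
            if len(anodes) != 2 or len(cathodes) != 1:
                raise GeometryError("pseudo_converging needs 2 anodes + 1 cathode")
            if self.relay_period_min <= 0:
                raise GeometryError("relay period must be > 0")

    @property
    def anodes(self) -> list[Electrode]:
        return [e for e in self.electrodes if e.role is ElectrodeRole.ANODE]

    @property
    def cathode(self) -> Electrode:
        return next(e for e in self.electrodes if e.role is ElectrodeRole.CATHODE)


@dataclass
class ConductivityMap:
    """Cell-centred raster of sheet conductance over a rectangular domain.

    ``sheet_conductance[i, j]`` is sigma*h (S) of the cell centred at
    ``(x[j], y[i])``; zero outside the channels and reservoirs.  Row index i
    increases with y.
    """

    grid_spacing: float  # mm
    x: np.ndarray  # cell-centre x coordinates, mm, shape (nx,)
    y: np.ndarray  # cell-centre y coordinates, mm, shape (ny,)
    sheet_conductance: np.ndarray  # S, shape (ny, nx)
    electrode_masks: list[np.ndarray]  # one bool mask per reservoir
    wound_mask: np.ndarray  # bool
    network: ChannelNetwork = field(repr=False, default=None)

    @property
    def conducting(self) -> np.ndarray:
        return self.sheet_conductance > 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.sheet_conductance.shape

    def conducting_area_mm2(self) -> float:
        return float(self.conducting.sum()) * self.grid_spacing**2


def _positive(name: str, value: float) -> float:
    if not (value > 0):
        raise GeometryError(f"{name} must be > 0, got {value}")
    return float(value)


def build_layout(
    layout_kind: LayoutKind | str,
    *,
    branch_length: float = DEFAULT_BRANCH_MM,
    width: float = DEFAULT_WIDTH_MM,
    runway_width: float = DEFAULT_WIDTH_MM,
    channel_height: float = DEFAULT_HEIGHT_MM,
    reservoir_radius: float = DEFAULT_RESERVOIR_MM,
    anode_angle_deg: float = 45.0,
    wound_span: float = DEFAULT_WOUND_SPAN_MM,
) -> ChannelNetwork:
    """Build one of the canonical chip layouts.

    Parameters
    ----------
    layout_kind
        ``straight``, ``t_junction`` or ``peace_sign``.
    branch_length
        Junction-to-reservoir length of each branch, mm.
    width, runway_width
        Channel widths, mm.  The runway (peace sign only) defaults to 0.9 mm.
    anode_angle_deg
        Angle of the peace-sign anode branches above/below the -x axis.
    wound_span
        Extent of the wound zone along x, mm.

    Returns
    -------
    ChannelNetwork
    """
    kind = LayoutKind(layout_kind)
    L = _positive("branch_length", branch_length)
    w = _positive("width", width)
    rw = _positive("runway_width", runway_width)
    _positive("channel_height", channel_height)
    rr = _positive("reservoir_radius", reservoir_radius)
    ws = _positive("wound_span", wound_span)

    def endpoint(angle_deg: float) -> tuple[float, float]:
        a = math.radians(angle_deg)
        return (L * math.cos(a), L * math.sin(a))

    def reservoir_at(angle_deg: float) -> Reservoir:
        a = math.radians(angle_deg)
        c = ((L + rr) * math.cos(a), (L + rr) * math.sin(a))
        return Reservoir(c, rr)

    wound = WoundZone(-ws / 2.0, -w / 2.0, ws / 2.0, w / 2.0)

    if kind is LayoutKind.STRAIGHT:
        segments = (Segment((-L, 0.0), (L, 0.0), w),)
        reservoirs = (reservoir_at(180.0), reservoir_at(0.0))
    elif kind is LayoutKind.T_JUNCTION:
        # two collinear arms (anode left, cathode right) plus a perpendicular
        # branch below the junction that hosts the second anode
        segments = (
            Segment((-L, 0.0), (0.0, 0.0), w),
            Segment((0.0, 0.0), (L, 0.0), w),
            Segment((0.0, 0.0), (0.0, -L), w),
        )
        reservoirs = (reservoir_at(180.0), reservoir_at(0.0), reservoir_at(270.0))
    else:
        # peace sign: central (cathode) branch up, two anode branches angled
        # anode_angle_deg below the horizontal so their current crosses the
        # junction before bending toward the cathode, runway straight down
        left = 180.0 + anode_angle_deg
        right = -anode_angle_deg
        segments = (
            Segment((0.0, 0.0), endpoint(left), w),  # left anode branch
            Segment((0.0, 0.0), endpoint(right), w),  # right anode branch
            Segment((0.0, 0.0), (0.0, L), w),  # central cathode branch
            Segment((0.0, 0.0), (0.0, -L), rw),  # scratch runway
        )
        reservoirs = (
            reservoir_at(left),
            reservoir_at(right),
            reservoir_at(90.0),
            reservoir_at(270.0),
        )

    return ChannelNetwork(
        layout_kind=kind,
        segments=segments,
        reservoirs=reservoirs,
        wound_zone=wound,
        scratch_runway_width=rw,
        channel_height=channel_height,
    )


def default_electrodes(
    network: ChannelNetwork,
    scheme: Scheme | str,
    current_uA: float = 25.0,
    relay_period_min: float = 30.0,
) -> ElectrodeConfig:
    """Canonical electrode placement for a layout.

    Uni-directional: anode in the leftmost reservoir, cathode in the rightmost
    one, so the field crosses the wound in +x (cathodal migration is +x).
    Pseudo-converging: anodes in the leftmost and rightmost reservoirs (they
    flank the wound) and the cathode in the topmost remaining reservoir (the
    central cathode branch), so the relay alternately pushes the wound edges
    inward from each side.
    """
    scheme = Scheme(scheme)
    xs = [r.center[0] for r in network.reservoirs]
    left_idx = int(np.argmin(xs))
    right_idx = int(np.argmax(xs))
    if scheme is Scheme.UNI_DIRECTIONAL:
        anode_idx = [left_idx]
        cathode_idx = right_idx
    else:
        if len(network.reservoirs) < 3:
            raise GeometryError("pseudo_converging needs at least 3 reservoirs")
        anode_idx = [left_idx, right_idx]
        rest = [i for i in range(len(network.reservoirs)) if i not in anode_idx]
        ys = [network.reservoirs[i].center[1] for i in rest]
        cathode_idx = rest[int(np.argmax(ys))]
    electrodes = [
        Electrode(i, ElectrodeRole.ANODE, current_uA) for i in anode_idx
    ] + [Electrode(cathode_idx, ElectrodeRole.CATHODE, current_uA)]
    return ElectrodeConfig(tuple(electrodes), scheme, relay_period_min)


def layout_to_config(network: ChannelNetwork, **build_params) -> dict:
    """Config mapping (units in key names) for a canonical layout."""
    cfg = {
        "layout": {
            "kind": network.layout_kind.value,
            "runway_width_mm": network.scratch_runway_width,
            "channel_height_mm": network.channel_height,
        }
    }
    cfg["layout"].update(build_params)
    return cfg


def layout_from_config(cfg: dict) -> ChannelNetwork:
    """Build a canonical layout from a config mapping (see layout_to_config)."""
    section = cfg.get("layout", cfg)
    kind = section["kind"]
    keymap = {
        "branch_length_mm": "branch_length",
        "width_mm": "width",
        "runway_width_mm": "runway_width",
        "channel_height_mm": "channel_height",
        "reservoir_radius_mm": "reservoir_radius",
        "anode_angle_deg": "anode_angle_deg",
        "wound_span_mm": "wound_span",
    }
    kwargs = {
        keymap[k]: float(v) for k, v in section.items() if k in keymap
    }
    return build_layout(kind, **kwargs)


def rasterize(
    network: ChannelNetwork,
    grid_spacing: float,
    sigma: float = PBS_CONDUCTIVITY,
    *,
    margin: float = 1.0,
    electrode_footprint_fraction: float = 0.6,
) -> ConductivityMap:
    """Rasterize a network to a sheet-conductance grid.

    Cells whose centres fall inside a channel segment or reservoir get sheet
    conductance sigma * channel_height (with lengths converted to metres);
    all other cells are non-conducting.  Electrode footprints are discs of
    ``electrode_footprint_fraction`` times the reservoir radius, centred on
    each reservoir, representing the submerged electrode tip.

    Parameters
    ----------
    grid_spacing : mm; must be <= min(channel width)/6.
    sigma : electrolyte conductivity, S/m.
    margin : mm of non-conducting border kept around the network (enlarge for
        thermal solves so lateral heat spreading is captured).
    """
    if grid_spacing <= 0:
        raise ResolutionError("grid spacing must be > 0")
    if sigma < 0:
        raise GeometryError("conductivity must be >= 0")
    if network.segments and grid_spacing > network.min_width / 6.0 + 1e-12:
        raise ResolutionError(
            f"grid spacing {grid_spacing} mm too coarse for channel width "
            f"{network.min_width} mm (need <= width/6)"
        )

    poly = network.conducting_polygon()
    if poly.is_empty:
        xmin, ymin, xmax, ymax = -1.0, -1.0, 1.0, 1.0
    else:
        xmin, ymin, xmax, ymax = poly.bounds
    xmin -= margin
    ymin -= margin
    xmax += margin
    ymax += margin

    nx = max(2, int(math.ceil((xmax - xmin) / grid_spacing)))
    ny = max(2, int(math.ceil((ymax - ymin) / grid_spacing)))
    x = xmin + (np.arange(nx) + 0.5) * grid_spacing
    y = ymin + (np.arange(ny) + 0.5) * grid_spacing
    XX, YY = np.meshgrid(x, y)

    if poly.is_empty:
        inside = np.zeros((ny, nx), dtype=bool)
    else:
        inside = shapely.contains_xy(poly, XX.ravel(), YY.ravel()).reshape(ny, nx)

    sheet = np.where(inside, sigma * network.channel_height * 1e-3, 0.0)

    electrode_masks = []
    for r in network.reservoirs:
        rad = electrode_footprint_fraction * r.radius
        mask = (XX - r.center[0]) ** 2 + (YY - r.center[1]) ** 2 <= rad**2
        electrode_masks.append(mask & inside)

    wz = network.wound_zone
    wound_mask = (
        (XX >= wz.xmin) & (XX <= wz.xmax) & (YY >= wz.ymin) & (YY <= wz.ymax) & inside
    )

    return ConductivityMap(
        grid_spacing=grid_spacing,
        x=x,
        y=y,
        sheet_conductance=sheet,
        electrode_masks=electrode_masks,
        wound_mask=wound_mask,
        network=network,
    )
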