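"""Arterial-network data model: vessel segments, Windkessel outlets, templates.

The celiac/hepatic circulation is represented as a directed graph of rigid
cylindrical segments. Each segment carries a Hagen-Poiseuille resistance
computed from its radius and length; a stenotic sub-length is modelled as a
series resistance with the effective radius ``r * sqrt(1 - area_reduction)``.
Boundary conditions are a single fixed-pressure inlet (the aorta) and
two-parameter Windkessel outlets, of which only the peripheral resistance is
active under steady flow.

Units at every public interface: mm for geometry, mmHg for pressure,
ml/min for flow, hence mmHg*min/ml for resistance and Pa*s for viscosity.
Conversions from the SI Poiseuille formula are centralised in
:data:`SI_RESISTANCE_TO_CLINICAL`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import networkx as nx

__all__ = [
    "Variant",
    "VesselSegment",
    "WindkesselOutlet",
    "InletBC",
    "ArterialNetwork",
    "poiseuille_resistance",
    "segment_resistance",
    "build_template",
    "validate_network",
    "DEFAULT_VISCOSITY_PA_S",
    "DEFAULT_INLET_PRESSURE_MMHG",
]

#: Default dynamic viscosity of whole blood, Pa*s. Not patient-specific here:
#: outlet calibration absorbs the scale, so only flow ratios are sensitive.
DEFAULT_VISCOSITY_PA_S = 0.0035

#: Aortic inlet pressure, mmHg (fixed; flow distribution is invariant to a
#: proportional rescaling once outlets are calibrated).
DEFAULT_INLET_PRESSURE_MMHG = 100.0

MMHG_PER_PA = 1.0 / 133.322
ML_PER_M3 = 1.0e6
MIN_PER_S = 1.0 / 60.0

#: Multiply a resistance in Pa*s/m^3 by this to get mmHg*min/ml.
SI_RESISTANCE_TO_CLINICAL = MMHG_PER_PA * MIN_PER_S / ML_PER_M3


class Variant(str, enum.Enum):
    """Hepatic arterial anatomy variants covered by the templates."""

    MICHELS_I = "MICHELS_I"
    MICHELS_VIII_REPLACED_RHA = "MICHELS_VIII_REPLACED_RHA"
    CELIAC_STENOSIS = "CELIAC_STENOSIS"


def poiseuille_resistance(radius: float, length: float, viscosity: float) -> float:
    """Hagen-Poiseuille resistance of a straight cylindrical vessel.

    R = 8 * mu * L / (pi * r^4), evaluated in SI and converted to the
    clinical unit mmHg*min/ml.

    Parameters
    ----------
    radius, length : float
        Lumen radius and vessel length, mm.
    viscosity : float
        Dynamic viscosity, Pa*s.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if length <= 0:
        raise ValueError(f"length must be > 0, got {length}")
    if viscosity <= 0:
        raise ValueError(f"viscosity must be > 0, got {viscosity}")
    r_m = radius * 1e-3
    l_m = length * 1e-3
    r_si = 8.0 * viscosity * l_m / (math.pi * r_m**4)
    return r_si * SI_RESISTANCE_TO_CLINICAL


@dataclass(frozen=True)
class VesselSegment:
    """One rigid vessel segment, oriented proximal -> distal.

    ``area_reduction`` is the luminal cross-section loss of a stenosis
    occupying ``stenosis_length`` mm of the segment (0 = healthy).
    """

    id: str
    name: str
    proximal_node: str
    distal_node: str
    radius: float  # mm
    length: float  # mm
    area_reduction: float = 0.0
    stenosis_length: float = 0.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0 (segment {self.id})")
        if self.length <= 0:
            raise ValueError(f"length must be > 0 (segment {self.id})")
        if self.proximal_node == self.distal_node:
            raise ValueError(f"proximal_node == distal_node (segment {self.id})")
        if not 0.0 <= self.area_reduction < 1.0:
            raise ValueError(f"area_reduction must be in [0, 1) (segment {self.id})")
        if self.stenosis_length < 0 or self.stenosis_length > self.length:
            raise ValueError(
                f"stenosis_length must be in [0, length] (segment {self.id})"
            )


def segment_resistance(segment: VesselSegment, viscosity: float) -> float:
    """Resistance of a segment, mmHg*min/ml, including any stenotic sub-length.

    Healthy and stenotic portions are in series; the stenotic portion uses
    the effective radius r*sqrt(1 - area_reduction) (Poiseuille in the
    narrowed lumen, no jet/recovery losses -- a reduced-order choice).
    """
    if segment.area_reduction == 0.0 or segment.stenosis_length == 0.0:
        return poiseuille_resistance(segment.radius, segment.length, viscosity)
    r_eff = segment.radius * math.sqrt(1.0 - segment.area_reduction)
    healthy_len = segment.length - segment.stenosis_length
    res = poiseuille_resistance(r_eff, segment.stenosis_length, viscosity)
    if healthy_len > 0:
        res += poiseuille_resistance(segment.radius, healthy_len, viscosity)
    return res


@dataclass(frozen=True)
class WindkesselOutlet:
    """Two-parameter Windkessel outlet: peripheral resistance + compliance.

    Under steady flow only ``resistance`` acts; ``compliance`` is kept for
    the pulsatile waveform demonstrator.
    """

    node: str
    resistance: float  # mmHg*min/ml
    compliance: float = 0.01  # ml/mmHg
    reference_pressure: float = 0.0  # mmHg (distal drainage pressure)

    def __post_init__(self):
        if self.resistance <= 0:
            raise ValueError(f"resistance must be > 0 (outlet {self.node})")
        if self.compliance < 0:
            raise ValueError(f"compliance must be >= 0 (outlet {self.node})")


@dataclass(frozen=True)
class InletBC:
    """Fixed-pressure inlet (aortic) boundary condition."""

    node: str
    pressure: float = DEFAULT_INLET_PRESSURE_MMHG  # mmHg

    def __post_init__(self):
        if self.pressure <= 0:
            raise ValueError(f"pressure must be > 0 (inlet {self.node})")


@dataclass(frozen=True)
class ArterialNetwork:
    """A patient's arterial network: segments + one inlet + Windkessel outlets."""

    segments: tuple[VesselSegment, ...]
    inlet: InletBC
    outlets: tuple[WindkesselOutlet, ...]
    variant: Variant = Variant.MICHELS_I
    viscosity: float = DEFAULT_VISCOSITY_PA_S  # Pa*s
    clamped_segments: frozenset[str] = field(default_factory=frozenset)

    # -- lookups ---------------------------------------------------------
    def segment(self, segment_id: str) -> VesselSegment:
        for s in self.segments:
            if s.id == segment_id:
                return s
        raise KeyError(f"unknown segment id {segment_id!r}")

    def outlet_at(self, node: str) -> WindkesselOutlet | None:
        for o in self.outlets:
            if o.node == node:
                return o
        return None

    @property
    def nodes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.segments:
            seen.setdefault(s.proximal_node)
            seen.setdefault(s.distal_node)
        return tuple(seen)

    # -- functional updates ---------------------------------------------
    def with_outlet_resistance(self, node: str, resistance: float) -> "ArterialNetwork":
        if self.outlet_at(node) is None:
            raise KeyError(f"no outlet at node {node!r}")
        outlets = tuple(
            replace(o, resistance=resistance) if o.node == node else o
            for o in self.outlets
        )
        return replace(self, outlets=outlets)

    def with_segment(self, segment: VesselSegment) -> "ArterialNetwork":
        segments = tuple(segment if s.id == segment.id else s for s in self.segments)
        return replace(self, segments=segments)


# ---------------------------------------------------------------------------
# Anatomy templates
# ---------------------------------------------------------------------------

# Default geometry (radius mm, length mm) per segment. Invented but
# physiological: large conduit arteries 1.5-4 mm radius, 20-60 mm long; the
# pancreaticoduodenal arcade is collapsed to one narrow equivalent segment.
# Calibration of outlet resistances absorbs geometric error.
_TEMPLATE_SEGMENTS = (
    # (id, name, proximal, distal, radius_mm, length_mm)
    ("CT", "celiac trunk", "AO", "CEL", 3.2, 25.0),
    ("SA", "splenic artery", "CEL", "SPL", 2.6, 50.0),
    ("CHA", "common hepatic artery", "CEL", "HEP", 2.2, 35.0),
    ("PHA", "proper hepatic artery", "HEP", "LIV", 2.0, 30.0),
    ("GDA", "gastroduodenal artery", "HEP", "PDA", 1.7, 30.0),
    ("ARCADE", "pancreaticoduodenal arcade", "PDA", "SMAJ", 1.0, 60.0),
    ("SMA", "superior mesenteric artery", "AO", "SMAJ", 3.0, 40.0),
)

_RHA_SEGMENT = ("RHA", "replaced right hepatic artery", "SMAJ", "RHL", 1.8, 40.0)

# Default outlet resistances, mmHg*min/ml: chosen so the uncalibrated
# template yields flows of the right order (PHA ~270, GDA ~40, splenic ~300,
# SMA ~500 ml/min at 100 mmHg).
DEFAULT_OUTLET_RESISTANCES: dict[str, float] = {
    "SPL": 0.33,
    "LIV": 0.37,
    "PDA": 2.45,
    "SMAJ": 0.20,
    "RHL": 1.50,
}

#: Default severity of the celiac-trunk stenosis template (fraction of
#: cross-sectional area lost, over the full trunk length).
DEFAULT_STENOSIS_AREA_REDUCTION = 0.85


def build_template(
    variant: Variant | str,
    geometry_overrides: dict[str, dict[str, float]] | None = None,
    *,
    inlet_pressure: float = DEFAULT_INLET_PRESSURE_MMHG,
    viscosity: float = DEFAULT_VISCOSITY_PA_S,
    outlet_resistances: dict[str, float] | None = None,
    area_reduction: float | None = None,
) -> ArterialNetwork:
    """Build a template network for a named anatomical variant.

    MICHELS_I: aorta -> celiac trunk -> {splenic, common hepatic}; the common
    hepatic bifurcates into the proper hepatic (liver outlet) and the
    gastroduodenal, which joins the SMA territory through a single equivalent
    pancreaticoduodenal-arcade segment. MICHELS_VIII adds a replaced right
    hepatic artery off the SMA junction. CELIAC_STENOSIS is MICHELS_I with an
    area reduction over the full celiac trunk (default 0.85).

    ``geometry_overrides`` maps segment id -> field overrides
    (radius/length/area_reduction/stenosis_length); ``outlet_resistances``
    maps outlet node -> resistance.
    """
    variant = Variant(variant)
    seg_rows = list(_TEMPLATE_SEGMENTS)
    if variant is Variant.MICHELS_VIII_REPLACED_RHA:
        seg_rows.append(_RHA_SEGMENT)

    overrides = dict(geometry_overrides or {})
    unknown = set(overrides) - {row[0] for row in seg_rows}
    if unknown:
        raise KeyError(f"geometry_overrides for absent segments: {sorted(unknown)}")

    segments = []
    for sid, name, prox, dist, radius, length in seg_rows:
        kw: dict[str, float] = {"radius": radius, "length": length}
        kw.update(overrides.get(sid, {}))
        segments.append(
            VesselSegment(id=sid, name=name, proximal_node=prox, distal_node=dist, **kw)
        )
    network = ArterialNetwork(
        segments=tuple(segments),
        inlet=InletBC(node="AO", pressure=inlet_pressure),
        outlets=tuple(
            WindkesselOutlet(node=node, resistance=res)
            for node, res in DEFAULT_OUTLET_RESISTANCES.items()
            if node in {s.distal_node for s in segments}
            | {s.proximal_node for s in segments}
        ),
        variant=variant,
        viscosity=viscosity,
    )
    if outlet_resistances:
        for node, res in outlet_resistances.items():
            network = network.with_outlet_resistance(node, res)

    if variant is Variant.CELIAC_STENOSIS:
        sev = DEFAULT_STENOSIS_AREA_REDUCTION if area_reduction is None else area_reduction
        ct = network.segment("CT")
        if "area_reduction" not in overrides.get("CT", {}):
            network = network.with_segment(
                replace(ct, area_reduction=sev, stenosis_length=ct.length)
            )
    elif area_reduction is not None:
        raise ValueError("area_reduction only applies to the CELIAC_STENOSIS variant")
    return network


def validate_network(network: ArterialNetwork) -> list[str]:
    """Structural diagnostics for a network; empty list = all invariants hold.

    Checks: unique segment ids, known outlet/clamp references, at most one
    outlet per node, inlet not also an outlet, inlet attached, connectivity,
    and that every leaf node is either the inlet or carries exactly one
    outlet. Returns named violations instead of raising.
    """
    diags: list[str] = []
    seen_ids: set[str] = set()
    for s in network.segments:
        if s.id in seen_ids:
            diags.append(f"duplicate_segment_id:{s.id}")
        seen_ids.add(s.id)

    nodes = set(network.nodes)
    outlet_nodes: list[str] = [o.node for o in network.outlets]
    for node in outlet_nodes:
        if node not in nodes:
            diags.append(f"unknown_outlet_node:{node}")
        if outlet_nodes.count(node) > 1 and f"multiple_outlets:{node}" not in diags:
            diags.append(f"multiple_outlets:{node}")
    if network.inlet.node not in nodes:
        diags.append(f"inlet_detached:{network.inlet.node}")
    if network.inlet.node in outlet_nodes:
        diags.append(f"inlet_is_outlet:{network.inlet.node}")
    for sid in sorted(network.clamped_segments):
        if sid not in seen_ids:
            diags.append(f"unknown_clamped_segment:{sid}")

    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((s.proximal_node, s.distal_node) for s in network.segments)
    if nodes and not nx.is_connected(g):
        comp = min(nx.connected_components(g), key=lambda c: sorted(c)[0])
        diags.append(f"disconnected:{sorted(comp)[0]}")

    outlet_set = set(outlet_nodes)
    for node in sorted(nodes):
        if g.degree(node) == 1 and node != network.inlet.node and node not in outlet_set:
            diags.append(f"dangling_leaf:{node}")
    return diags
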