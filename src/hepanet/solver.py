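"""Steady-state flow solver and the pulsatile Windkessel demonstrator.

The steady problem is nodal analysis on a resistive network: unknown nodal
pressures satisfy Kirchhoff conservation at every node except the
fixed-pressure inlet, with each Windkessel outlet contributing a conductance
to its reference (venous) pressure. Clamped segments are removed from the
system exactly — no large-resistance approximation — so clamped flows are
bit-exact zeros. The linear system is solved by a dense direct method
(networks here have ~10 nodes).

Sign convention: a segment's flow is positive in its declared
proximal -> distal orientation; the gastroduodenal artery is oriented
bifurcation -> arcade, so collateral perfusion of the liver (stenosis or
common-hepatic clamping) appears as a negative GDA flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import networkx as nx

from .errors import NetworkValidationError, NoOpenPathError
from .network import (
    ArterialNetwork,
    WindkesselOutlet,
    segment_resistance,
    validate_network,
)

__all__ = ["FlowSolution", "solve_steady", "clamp", "windkessel_waveform"]

BASELINE = "baseline"
CLAMP_GDA = "clamp_GDA"
CLAMP_CHA = "clamp_CHA"
SCENARIOS = (BASELINE, CLAMP_GDA, CLAMP_CHA)


@dataclass(frozen=True)
class FlowSolution:
    """Signed segment flows (ml/min) and nodal pressures (mmHg) for one scenario."""

    segment_flows: dict[str, float]
    node_pressures: dict[str, float]
    outlet_flows: dict[str, float]
    scenario: str
    residual: float  # max absolute nodal imbalance, ml/min

    def flow(self, segment_id: str) -> float:
        try:
            return self.segment_flows[segment_id]
        except KeyError:
            raise KeyError(f"no segment {segment_id!r} in solution") from None

    @property
    def inlet_flow(self) -> float:
        return sum(self.outlet_flows.values())


def clamp(network: ArterialNetwork, segment_id: str) -> ArterialNetwork:
    """Return a copy of the network with ``segment_id`` clamped (zero flow).

    Idempotent; raises KeyError for unknown segments.
    """
    network.segment(segment_id)  # existence check
    return replace(
        network, clamped_segments=frozenset(network.clamped_segments | {segment_id})
    )


def solve_steady(network: ArterialNetwork, scenario: str = BASELINE) -> FlowSolution:
    """Solve steady flows/pressures under the fixed inlet and resistive outlets.

    Conservation holds at every interior node; each open segment obeys
    dP = Q * R_segment and each outlet Q = (P_node - P_ref) / R_outlet.
    Compliance is inactive at steady state. Deterministic: identical input
    gives bit-identical output.

    Raises :class:`NoOpenPathError` if clamping leaves no open route from
    the inlet to any outlet, and :class:`NetworkValidationError` for
    structurally invalid networks.
    """
    diags = validate_network(network)
    if diags:
        raise NetworkValidationError(diags)

    inlet = network.inlet
    nodes = sorted(set(network.nodes) | {inlet.node})
    open_segments = [s for s in network.segments if s.id not in network.clamped_segments]

    # Reachability on the open graph: the inlet must still feed some outlet.
    g_open = nx.Graph()
    g_open.add_nodes_from(nodes)
    g_open.add_edges_from((s.proximal_node, s.distal_node) for s in open_segments)
    reachable = nx.node_connected_component(g_open, inlet.node)
    outlet_nodes = {o.node for o in network.outlets}
    if not (reachable & outlet_nodes):
        raise NoOpenPathError("every route from the inlet is clamped")

    unknowns = [n for n in nodes if n != inlet.node]
    index = {n: i for i, n in enumerate(unknowns)}
    n_unk = len(unknowns)
    a = np.zeros((n_unk, n_unk))
    b = np.zeros(n_unk)

    conductance: dict[str, float] = {
        s.id: 1.0 / segment_resistance(s, network.viscosity) for s in open_segments
    }
    for s in open_segments:
        g = conductance[s.id]
        for node, other in ((s.proximal_node, s.distal_node),
                            (s.distal_node, s.proximal_node)):
            if node == inlet.node:
                continue
            i = index[node]
            a[i, i] += g
            if other == inlet.node:
                b[i] += g * inlet.pressure
            else:
                a[i, index[other]] -= g

    for o in network.outlets:
        i = index[o.node]
        g = 1.0 / o.resistance
        a[i, i] += g
        b[i] += g * o.reference_pressure

    # Components cut off from the inlet with no outlet have indeterminate
    # pressure (all their flows are zero); pin them to 0 mmHg.
    for comp in nx.connected_components(g_open):
        if inlet.node in comp or comp & outlet_nodes:
            continue
        for node in comp:
            i = index[node]
            a[i, :] = 0.0
            a[i, i] = 1.0
            b[i] = 0.0

    try:
        p = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NoOpenPathError(str(exc)) from exc

    pressures = {inlet.node: float(inlet.pressure)}
    pressures.update({n: float(p[index[n]]) for n in unknowns})

    flows: dict[str, float] = {}
    for s in network.segments:
        if s.id in network.clamped_segments:
            flows[s.id] = 0.0
        else:
            flows[s.id] = (
                (pressures[s.proximal_node] - pressures[s.distal_node])
                * conductance[s.id]
            )
    outlet_flows = {
        o.node: (pressures[o.node] - o.reference_pressure) / o.resistance
        for o in network.outlets
    }

    # Nodal imbalance check (inlet excluded: it is the source).
    residual = 0.0
    for node in unknowns:
        net_in = 0.0
        for s in network.segments:
            if s.distal_node == node:
                net_in += flows[s.id]
            elif s.proximal_node == node:
                net_in -= flows[s.id]
        net_in -= outlet_flows.get(node, 0.0)
        residual = max(residual, abs(net_in))

    return FlowSolution(
        segment_flows=flows,
        node_pressures=pressures,
        outlet_flows=outlet_flows,
        scenario=scenario,
        residual=residual,
    )


def windkessel_waveform(
    outlet: WindkesselOutlet,
    amplitude: float,
    period: float,
    n_cycles: int = 10,
    *,
    systole_fraction: float = 1.0 / 3.0,
    dt: float = 1e-3,
    initial_pressure: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic pressure response of one Windkessel outlet to half-sine pulses.

    The inflow is a pulse train: Q(t) = amplitude * sin(pi t / T_sys) during
    systole (T_sys = systole_fraction * period) and 0 in diastole. The ODE
    C dP/dt = Q(t) - (P - P_ref)/R is integrated exactly on each piecewise
    interval; with C = 0 it degenerates to P = P_ref + Q(t) R.

    Parameters are in clinical units (ml/min, mmHg*min/ml, ml/mmHg) with
    ``period`` and ``dt`` in seconds. Returns (t_seconds, pressure_mmHg)
    sampled on the dt grid over ``n_cycles`` cycles. A periodic steady state
    is reached once n_cycles spans a few time constants R*C.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    if not 0 < systole_fraction < 1:
        raise ValueError("systole_fraction must be in (0, 1)")

    r = outlet.resistance
    p_ref = outlet.reference_pressure
    t_sys = systole_fraction * period
    omega = math.pi / t_sys
    t = np.arange(0.0, n_cycles * period + dt / 2, dt)
    phase = np.mod(t, period)
    q = np.where(phase < t_sys, amplitude * np.sin(omega * phase), 0.0)

    if outlet.compliance == 0.0:
        return t, p_ref + q * r

    tau = r * outlet.compliance * 60.0  # mmHg*min/ml * ml/mmHg -> minutes -> s
    k = amplitude * r / (1.0 + (omega * tau) ** 2)
    p0 = p_ref if initial_pressure is None else initial_pressure

    pressures = np.empty_like(t)
    p_start = p0  # pressure at the start of the current cycle
    for i, (ti, ph) in enumerate(zip(t, phase)):
        # evolve analytically from the start of this cycle
        if ph < t_sys or math.isclose(ph, 0.0):
            part = k * (math.sin(omega * ph) - omega * tau * math.cos(omega * ph))
            pressures[i] = (
                p_ref + part + (p_start - p_ref + k * omega * tau) * math.exp(-ph / tau)
            )
        else:
            p_end_sys = (
                p_ref
                + k * (math.sin(math.pi) - omega * tau * math.cos(math.pi))
                + (p_start - p_ref + k * omega * tau) * math.exp(-t_sys / tau)
            )
            pressures[i] = p_ref + (p_end_sys - p_ref) * math.exp(-(ph - t_sys) / tau)
        if i + 1 < len(t) and np.mod(t[i + 1], period) < ph:
            # crossing into the next cycle: evolve p_start to the cycle end
            p_end_sys = (
                p_ref
                + k * omega * tau
                + (p_start - p_ref + k * omega * tau) * math.exp(-t_sys / tau)
            )
            p_start = p_ref + (p_end_sys - p_ref) * math.exp(-(period - t_sys) / tau)
    return t, pressures
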