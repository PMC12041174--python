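"""Independent oracles used by the solver tests.

The series-parallel reduction below solves tree-shaped resistive networks by
textbook equivalent-resistance collapse and back-substitution. It shares no
code with the nodal solver it checks (only the resistance formula, which has
its own hand-computed test).
"""

from collections import defaultdict

import numpy as np

import hepanet as hp
from hepanet.network import segment_resistance


def series_parallel_solve(network):
    """Flows/pressures of a tree network by series-parallel reduction.

    Assumes: tree topology rooted at the inlet, all outlet reference
    pressures equal (used as the ground), no clamps.
    """
    ref = network.outlets[0].reference_pressure
    assert all(o.reference_pressure == ref for o in network.outlets)
    children = defaultdict(list)
    for s in network.segments:
        children[s.proximal_node].append(s)
    res = {s.id: segment_resistance(s, network.viscosity) for s in network.segments}

    def equivalent(node):
        conductances = []
        outlet = network.outlet_at(node)
        if outlet is not None:
            conductances.append(1.0 / outlet.resistance)
        for seg in children[node]:
            conductances.append(1.0 / (res[seg.id] + equivalent(seg.distal_node)))
        return 1.0 / sum(conductances)

    pressures = {network.inlet.node: network.inlet.pressure}
    flows = {}

    def descend(node):
        for seg in children[node]:
            q = (pressures[node] - ref) / (res[seg.id] + equivalent(seg.distal_node))
            flows[seg.id] = q
            pressures[seg.distal_node] = pressures[node] - q * res[seg.id]
            descend(seg.distal_node)

    descend(network.inlet.node)
    return flows, pressures


def random_tree_network(rng: np.random.Generator, max_segments: int = 8):
    """A random tree-shaped ArterialNetwork rooted at a 100 mmHg inlet."""
    n_seg = int(rng.integers(1, max_segments + 1))
    segments = []
    nodes = ["N0"]
    for i in range(n_seg):
        parent = nodes[int(rng.integers(0, len(nodes)))]
        child = f"N{i + 1}"
        nodes.append(child)
        segments.append(
            hp.VesselSegment(
                id=f"S{i}", name=f"seg{i}", proximal_node=parent, distal_node=child,
                radius=float(rng.uniform(1.0, 3.0)),
                length=float(rng.uniform(10.0, 60.0)),
            )
        )
    has_child = {s.proximal_node for s in segments}
    outlets = []
    for node in nodes:
        if node == "N0":
            continue
        is_leaf = node not in has_child
        if is_leaf or rng.uniform() < 0.3:
            outlets.append(
                hp.WindkesselOutlet(node=node, resistance=float(rng.uniform(0.1, 3.0)))
            )
    return hp.ArterialNetwork(
        segments=tuple(segments),
        inlet=hp.InletBC(node="N0", pressure=100.0),
        outlets=tuple(outlets),
    )
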