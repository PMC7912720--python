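"""Labelling of the vertebrobasilar Y from an unlabelled polyline set.

The three main arteries are recognised purely geometrically, mirroring how
centerline tools label the posterior circulation from the vertebrobasilar
confluence: after pruning spurious short branches, the network must contain
exactly one degree-3 junction; the branch whose free endpoint reaches
highest (+Z, superior) is the basilar artery, and of the two remaining
branches the one whose free endpoint lies further toward +X (patient left)
is the left vertebral artery.  Labels are invariant to the input ordering
of the polylines and to the direction each polyline is traversed.
"""

from __future__ import annotations

import numpy as np

from .centerline import Centerline, VesselNetwork

_NODE_TOL = 1e-6


class TopologyError(ValueError):
    """Network does not reduce to a single three-branch junction."""


class TieError(ValueError):
    """Left/right assignment is ambiguous (equal X within tolerance)."""


def _node_key(point: np.ndarray, nodes: list) -> int:
    for i, q in enumerate(nodes):
        if np.linalg.norm(point - q) <= _NODE_TOL:
            return i
    nodes.append(np.asarray(point, dtype=float))
    return len(nodes) - 1


def identify_branches(polylines, min_branch_length: float = 3.0) -> VesselNetwork:
    """Label left VA / right VA / BA in a raw polyline set.

    Parameters
    ----------
    polylines : iterable of Centerline
        Unordered, arbitrarily oriented branches.  Branches shorter than
        ``min_branch_length`` (mm) whose removal does not disconnect the
        main Y are treated as reconstruction spurs and pruned.
    """
    branches = list(polylines)
    if not branches:
        raise TopologyError("empty polyline set")

    # Prune short spurs: anything under the length threshold that has at
    # least one endpoint not shared with a surviving branch.  Iterate until
    # stable so chains of spurs collapse.
    while True:
        nodes: list = []
        ends = [( _node_key(b.points[0], nodes), _node_key(b.points[-1], nodes)) for b in branches]
        degree = np.zeros(len(nodes), dtype=int)
        for i0, i1 in ends:
            degree[i0] += 1
            degree[i1] += 1
        removable = [
            k
            for k, b in enumerate(branches)
            if b.length < min_branch_length and (degree[ends[k][0]] == 1 or degree[ends[k][1]] == 1)
        ]
        if not removable or len(branches) <= 3:
            break
        branches = [b for k, b in enumerate(branches) if k not in set(removable)]

    junctions = np.flatnonzero(degree == 3)
    if len(junctions) != 1:
        raise TopologyError(
            f"expected exactly one three-branch junction after pruning, found {len(junctions)}"
        )
    if len(branches) != 3:
        raise TopologyError(f"expected 3 branches at the junction, found {len(branches)}")
    jnode = junctions[0]
    confluence = nodes[jnode]

    oriented = []  # centerlines re-oriented to END at the confluence
    free_pts = []
    for b, (i0, i1) in zip(branches, ends):
        if i1 == jnode:
            oriented.append(b)
            free_pts.append(b.points[0])
        elif i0 == jnode:
            oriented.append(b.reversed())
            free_pts.append(b.points[-1])
        else:
            raise TopologyError("branch not attached to the junction")

    z = np.array([p[2] for p in free_pts])
    ba_idx = int(np.argmax(z))
    rest = [k for k in range(3) if k != ba_idx]
    x = np.array([free_pts[k][0] for k in rest])
    if abs(x[0] - x[1]) <= _NODE_TOL:
        raise TieError("left/right vertebral arteries have equal X within tolerance")
    left_idx = rest[int(np.argmax(x))]
    right_idx = rest[0] if left_idx == rest[1] else rest[1]

    ba = oriented[ba_idx].reversed()  # BA runs from confluence to tip
    return VesselNetwork(
        left_va=oriented[left_idx],
        right_va=oriented[right_idx],
        ba=ba,
        confluence=confluence,
        basilar_tip=ba.points[-1],
    )
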