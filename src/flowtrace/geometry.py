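"""Vessel centerline geometry: segmentation, skeleton graph, marker paths.

Vessels are segmented on the t-MIP (or supplied as a mask), reduced to a
one-voxel-wide skeleton by 3-D morphological thinning, and turned into a
graph whose nodes are skeleton voxels and whose edges connect 26-adjacent
voxels with their Euclidean length in mm (anisotropic spacing).  A
marker set (proximal, thrombus, one or more distal markers) is snapped
onto the skeleton and minimum-cost paths are traced through the t-MIP
intensities: bright voxels are cheap, so paths stay inside vessels.
Where several distal paths share a prefix beyond the thrombus, the shared
part is the mother segment and the diverging parts are daughter segments.
"""
from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import List, Optional

import networkx as nx
import numpy as np
from skimage import measure, morphology

from .preprocess import Volume3D

COST_EPS_HU = 1.0  # guard keeping edge costs strictly positive


@dataclass
class VesselMask:
    """Binary vessel segmentation on the same grid as its source volume."""

    data: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)


@dataclass
class SkeletonGraph:
    """Voxel graph of the vessel centerlines.

    Nodes are skeleton voxel index triples; edges carry ``length_mm``.
    Degree 1 nodes are endpoints, degree 2 corridor voxels, degree >= 3
    branch nodes.
    """

    graph: nx.Graph
    spacing: tuple
    shape: tuple

    def endpoints(self):
        return [n for n, d in self.graph.degree if d == 1]

    def branch_nodes(self):
        return [n for n, d in self.graph.degree if d >= 3]


@dataclass
class MarkerSet:
    """Reference markers in voxel indices: proximal, thrombus, distal list."""

    proximal: tuple
    thrombus: tuple
    distal: list

    def __post_init__(self):
        self.proximal = tuple(int(v) for v in self.proximal)
        self.thrombus = tuple(int(v) for v in self.thrombus)
        self.distal = [tuple(int(v) for v in d) for d in self.distal]
        if not self.distal:
            raise ValueError("at least one distal marker is required")


@dataclass
class CenterlinePath:
    """Ordered centerline path from the proximal marker to a distal marker.

    ``labels`` partition the path into proximal / thrombus / distal legs;
    ``segment_ids`` subdivide the distal leg into mother and daughterN at
    the branch node where sibling paths diverge.
    """

    path_id: str
    voxels: list
    arclength_mm: np.ndarray
    labels: list
    segment_ids: list
    total_cost: Optional[float] = None
    breakpoints: list = field(default_factory=list)

    def __post_init__(self):
        n = len(self.voxels)
        if not (len(self.arclength_mm) == len(self.labels)
                == len(self.segment_ids) == n):
            raise ValueError("inconsistent path field lengths")
        if n > 1 and np.any(np.diff(self.arclength_mm) <= 0):
            raise ValueError("arc-length must be strictly increasing")

    def __len__(self):
        return len(self.voxels)


# ---------------------------------------------------------------------------
# segmentation

def segment_vessels(tmip: Volume3D, method: str = "threshold",
                    threshold_hu: float = None, percentile: float = None,
                    min_component_voxels: int = 27,
                    supplied_mask: VesselMask = None) -> VesselMask:
    """Binary vessel mask from the t-MIP.

    method="threshold": voxels at or above an absolute HU cutoff (or a
    percentile of the t-MIP) are kept and connected components smaller
    than ``min_component_voxels`` are removed.  method="supplied" passes
    a user mask through after a grid-compatibility check — the intended
    route when a dedicated segmentation tool produced the mask.
    """
    if method == "supplied":
        if supplied_mask is None:
            raise ValueError("method='supplied' requires supplied_mask")
        if supplied_mask.data.shape != tmip.data.shape:
            raise ValueError("supplied mask grid does not match the t-MIP")
        return supplied_mask
    if method != "threshold":
        raise ValueError(f"unknown segmentation method {method!r}")
    if threshold_hu is None:
        if percentile is None:
            raise ValueError("threshold method needs threshold_hu or percentile")
        threshold_hu = float(np.percentile(tmip.data, percentile))
    raw = tmip.data >= threshold_hu
    if min_component_voxels > 1 and raw.any():
        labels = measure.label(raw, connectivity=3)
        counts = np.bincount(labels.ravel())
        keep = counts >= min_component_voxels
        keep[0] = False
        raw = keep[labels]
    if not raw.any():
        raise ValueError(
            f"empty vessel mask: no component survives threshold "
            f"{threshold_hu} HU / size floor {min_component_voxels}")
    return VesselMask(raw, tmip.spacing, tmip.origin)


def restrict_to_roi(mask: VesselMask, roi: np.ndarray) -> VesselMask:
    """Voxelwise AND of the vessel mask with a region-of-interest mask."""
    roi = np.asarray(roi).astype(bool)
    if roi.shape != mask.data.shape:
        raise ValueError("ROI grid does not match the mask")
    out = mask.data & roi
    if not out.any():
        warnings.warn("ROI removed every vessel voxel")
    return VesselMask(out, mask.spacing, mask.origin)


# ---------------------------------------------------------------------------
# skeletonization

_NEIGHBORS26 = [off for off in product((-1, 0, 1), repeat=3) if any(off)]


def skeletonize(mask: VesselMask, prune_mm: float = 3.0) -> SkeletonGraph:
    """One-voxel-wide centerline skeleton as a 26-connected voxel graph.

    Morphological thinning preserves the topology of the mask, so the
    skeleton has the same number of connected components.  Spurs — side
    branches shorter than ``prune_mm`` hanging off a branch node with a
    free endpoint — are thinning artifacts and are removed before the
    graph is returned.
    """
    if not mask.data.any():
        raise ValueError("cannot skeletonize an empty mask")
    skel = morphology.skeletonize(mask.data)
    g = nx.Graph()
    nodes = [tuple(int(v) for v in c) for c in np.argwhere(skel)]
    g.add_nodes_from(nodes)
    nodeset = set(nodes)
    sp = np.asarray(mask.spacing)
    for n in nodes:
        for off in _NEIGHBORS26:
            m = (n[0] + off[0], n[1] + off[1], n[2] + off[2])
            if m > n and m in nodeset:
                g.add_edge(n, m, length_mm=float(np.linalg.norm(off * sp)))
    _prune_spurs(g, prune_mm)
    return SkeletonGraph(g, mask.spacing, mask.data.shape)


def _prune_spurs(g: nx.Graph, prune_mm: float, max_rounds: int = 10):
    for _ in range(max_rounds):
        removed = False
        for ep in sorted(n for n, d in g.degree if d == 1):
            if ep not in g:
                continue
            chain = [ep]
            length = 0.0
            cur, prev = ep, None
            while g.degree(cur) <= 2:
                nxt = [n for n in g.neighbors(cur) if n != prev]
                if not nxt:
                    break
                length += g.edges[cur, nxt[0]]["length_mm"]
                prev, cur = cur, nxt[0]
                if g.degree(cur) >= 3:
                    break
                chain.append(cur)
            # prune only spurs that terminate at a branch node
            if g.degree(cur) >= 3 and length < prune_mm:
                g.remove_nodes_from(chain)
                removed = True
        if not removed:
            break


# ---------------------------------------------------------------------------
# minimum-cost paths

def _edge_costs(tmip: Volume3D, skel: SkeletonGraph):
    g = skel.graph
    imax = max(tmip.data[n] for n in g.nodes)
    costs = {}
    for u, v, data in g.edges(data=True):
        mean_i = 0.5 * (tmip.data[u] + tmip.data[v])
        costs[(u, v)] = data["length_mm"] * (imax - mean_i + COST_EPS_HU)
    return costs


def _dijkstra(adj, src, dst):
    """Deterministic Dijkstra: equal-cost ties resolved toward the
    lexicographically smallest predecessor node."""
    dist = {src: 0.0}
    pred = {}
    heap = [(0.0, src)]
    done = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        if u == dst:
            break
        for v, w in adj.get(u, ()):
            nd = d + w
            old = dist.get(v)
            if old is None or nd < old - 1e-12:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
            elif abs(nd - old) <= 1e-12 and u < pred.get(v, u):
                pred[v] = u
    if dst not in dist:
        raise ValueError(f"no path between {src} and {dst}: "
                         "markers lie in disconnected skeleton components")
    path = [dst]
    while path[-1] != src:
        path.append(pred[path[-1]])
    return path[::-1], dist[dst]


def _adjacency(skel: SkeletonGraph, costs):
    adj = {}
    for (u, v), w in costs.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    for lst in adj.values():
        lst.sort()
    return adj


def _arclength(voxels, spacing):
    sp = np.asarray(spacing)
    steps = [0.0]
    for a, b in zip(voxels[:-1], voxels[1:]):
        steps.append(np.linalg.norm((np.subtract(b, a)) * sp))
    return np.cumsum(steps)


def min_cost_path(tmip: Volume3D, skel: SkeletonGraph, src, dst,
                  snap_radius_vox: float = 3.0) -> CenterlinePath:
    """Minimum-cost centerline path between two voxels.

    Edge cost is ``length_mm * (I_max - mean(I_u, I_v) + eps)`` with
    intensities from the t-MIP and I_max its maximum over the skeleton,
    so bright (vessel-core) routes are cheap and the eps = 1 HU guard
    keeps every cost positive.  Among equal-cost routes the one with the
    lexicographically smallest predecessor chain is returned.
    """
    src = snap_to_skeleton(skel, src, snap_radius_vox, "src")
    dst = snap_to_skeleton(skel, dst, snap_radius_vox, "dst")
    costs = _edge_costs(tmip, skel)
    adj = _adjacency(skel, costs)
    voxels, total = _dijkstra(adj, src, dst)
    arc = _arclength(voxels, skel.spacing)
    n = len(voxels)
    return CenterlinePath("path", voxels, arc, ["path"] * n, ["path"] * n,
                          total_cost=total)


def snap_to_skeleton(skel: SkeletonGraph, voxel, snap_radius_vox: float,
                     name: str):
    """Nearest skeleton node within the snap radius (mm metric).

    The radius is ``snap_radius_vox`` times the largest voxel spacing;
    ties are broken by the lowest lexicographic node index.
    """
    voxel = tuple(int(v) for v in voxel)
    if voxel in skel.graph:
        return voxel
    sp = np.asarray(skel.spacing)
    radius_mm = snap_radius_vox * max(skel.spacing)
    best = None
    for n in skel.graph.nodes:
        d = float(np.linalg.norm((np.subtract(n, voxel)) * sp))
        if d <= radius_mm:
            cand = (d, n)
            if best is None or cand < best:
                best = cand
    if best is None:
        raise ValueError(
            f"marker {name!r} at voxel {voxel} has no skeleton node within "
            f"{radius_mm:.1f} mm")
    return best[1]


def assemble_paths(tmip: Volume3D, skel: SkeletonGraph, markers: MarkerSet,
                   snap_radius_vox: float = 3.0) -> List[CenterlinePath]:
    """One labelled centerline path per distal marker.

    Each path runs proximal → thrombus → distal.  Voxels strictly before
    the thrombus marker are labelled 'proximal', the thrombus marker
    voxel 'thrombus', and everything beyond it 'distal'.  The distal
    portions of all paths are compared: their maximal common prefix is
    the mother segment and the diverging remainders become daughter1,
    daughter2, ... with the divergence (branch) node recorded as a
    breakpoint.  A single distal path keeps the whole distal leg as the
    mother segment.
    """
    prox = snap_to_skeleton(skel, markers.proximal, snap_radius_vox, "proximal")
    thromb = snap_to_skeleton(skel, markers.thrombus, snap_radius_vox, "thrombus")
    distals = [snap_to_skeleton(skel, d, snap_radius_vox, f"distal[{i}]")
               for i, d in enumerate(markers.distal)]
    costs = _edge_costs(tmip, skel)
    adj = _adjacency(skel, costs)
    leg_a, cost_a = _dijkstra(adj, prox, thromb)
    distal_seqs = []
    totals = []
    for i, d in enumerate(distals):
        if d in leg_a[:-1]:
            raise ValueError(
                f"distal marker {i} lies on the proximal leg (proximal of "
                "the thrombus marker); markers must be ordered "
                "proximal -> thrombus -> distal")
        leg_b, cost_b = _dijkstra(adj, thromb, d)
        distal_seqs.append(leg_b[1:])
        totals.append(cost_a + cost_b)
    # maximal distal prefix common to all paths = mother segment
    if len(distal_seqs) > 1:
        k = 0
        min_len = min(len(s) for s in distal_seqs)
        while k < min_len and all(s[k] == distal_seqs[0][k]
                                  for s in distal_seqs[1:]):
            k += 1
    else:
        k = len(distal_seqs[0]) if distal_seqs else 0
    paths = []
    for i, seq in enumerate(distal_seqs):
        voxels = leg_a + seq
        labels = (["proximal"] * (len(leg_a) - 1) + ["thrombus"]
                  + ["distal"] * len(seq))
        seg_ids = list(labels[:len(leg_a)])
        breakpoints = []
        for j, _ in enumerate(seq):
            if j < k or len(distal_seqs) == 1:
                seg_ids.append("mother")
            else:
                seg_ids.append(f"daughter{i + 1}")
        if len(distal_seqs) > 1 and k > 0 and k < len(seq):
            breakpoints.append((len(leg_a) + k - 1, seq[k - 1]))
        arc = _arclength(voxels, skel.spacing)
        paths.append(CenterlinePath(f"path{i + 1}", voxels, arc, labels,
                                    seg_ids, total_cost=totals[i],
                                    breakpoints=breakpoints))
    return paths
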