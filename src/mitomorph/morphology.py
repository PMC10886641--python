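"""Skeleton-graph morphometry of a binarized mitochondrial mask.

From a foreground mask the module derives, per cell:

1. connected components with areas and fitted-ellipse aspect ratios
   (``label_components``), and the **mitochondrial footprint** — the
   summed area of all components in µm²;
2. a one-pixel-wide topological skeleton (``skeletonize_mask``) and its
   graph decomposition (``analyze_skeleton``): junction pixels are
   skeleton pixels with more than two 8-connected skeleton neighbors
   (adjacent junction pixels merge into one junction node), endpoints
   have exactly one neighbor, and branches are maximal paths between
   nodes with geometric length 1 per orthogonal and √2 per diagonal
   step;
3. the two-class filter (``classify_objects``): a component is a
   mitochondrial **network** iff it has more than one branch and at
   least one junction, an **individual** mitochondrion iff it has
   exactly one branch and no junction; closed rings ("donuts") match
   neither rule and are tallied as unclassified with a reason code;
4. the per-cell morphometric summary (``cell_morphometrics``) with
   median-based aggregation: footprint, median network branch length,
   individual:network count ratio, median individual length, mean
   junctions per network (connectivity) and median individual aspect
   ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import convolve
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import skeletonize as sk_skeletonize
from sklearn.base import BaseEstimator

from .images import BinaryMask

SQRT2 = math.sqrt(2.0)

# deterministic neighbor order: orthogonal steps before diagonal ones
_NEIGHBOR_OFFSETS = [
    (-1, 0), (0, -1), (0, 1), (1, 0),
    (-1, -1), (-1, 1), (1, -1), (1, 1),
]


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------

@dataclass
class ComponentSet:
    """8-connected component labeling with per-component geometry."""

    labels: np.ndarray  # 0 = background
    props: pd.DataFrame  # component_id, area_px, area_um2, axes, aspect_ratio
    pixels_per_micron: float

    @property
    def n_components(self) -> int:
        return len(self.props)


def label_components(mask: BinaryMask) -> ComponentSet:
    """8-connected labeling with areas (px and µm²) and ellipse axes.

    The aspect ratio is major/minor of the ellipse with the same second
    moments as the component; a one-pixel (or perfectly isotropic)
    component gets aspect ratio 1, and a zero-width line maps to inf.
    """
    labels = sk_label(mask.pixels, connectivity=2)
    ppm = mask.pixels_per_micron
    rows = []
    for rp in regionprops(labels):
        major = float(rp.axis_major_length)
        minor = float(rp.axis_minor_length)
        if major == 0.0:
            aspect = 1.0
        elif minor == 0.0:
            aspect = float("inf")
        else:
            aspect = major / minor
        rows.append(
            {
                "component_id": int(rp.label),
                "area_px": int(rp.area),
                "area_um2": float(rp.area) / ppm**2,
                "ellipse_major_px": major,
                "ellipse_minor_px": minor,
                "aspect_ratio": aspect,
            }
        )
    props = pd.DataFrame(
        rows,
        columns=[
            "component_id", "area_px", "area_um2",
            "ellipse_major_px", "ellipse_minor_px", "aspect_ratio",
        ],
    )
    return ComponentSet(labels=labels, props=props, pixels_per_micron=ppm)


def mitochondrial_footprint(components: ComponentSet) -> float:
    """Total mitochondrial area in µm² (sum over all components)."""
    if components.n_components == 0:
        return 0.0
    return float(components.props["area_um2"].sum())


# ---------------------------------------------------------------------------
# skeleton
# ---------------------------------------------------------------------------

def _extend_tips(skel: np.ndarray, mask: np.ndarray, max_iter: int = 24) -> np.ndarray:
    """Regrow branch tips eroded by thinning.

    Zhang thinning retracts open branch ends by roughly the tube radius.
    The medial ridge of a tube (where the distance transform is locally
    maximal) ends exactly at the centerline end, so tips are extended
    step by step along their local direction while the distance
    transform does not drop — this stops at the cap, where the distance
    to the boundary starts falling.  Extensions never touch other
    skeleton pixels, so the topology is unchanged.
    """
    from scipy.ndimage import distance_transform_edt

    dt = distance_transform_edt(mask)
    S = skel.copy()
    h, w = S.shape

    def neighbors8(r, c):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    yield rr, cc

    nbr = convolve(S.astype(np.uint8), np.ones((3, 3), np.uint8),
                   mode="constant") - S.astype(np.uint8)
    tips = np.argwhere(S & (nbr == 1))
    for tip in tips:
        r, c = int(tip[0]), int(tip[1])
        prev = [(rr, cc) for rr, cc in neighbors8(r, c) if S[rr, cc]]
        if not prev:
            continue
        pr, pc = prev[0]
        # reference = interior ridge dt near the tip (walk a few pixels
        # back, in case thinning already reached the descending cap):
        # the centerline end sits one unit below the ridge, anything
        # past the cap is lower still
        ref = dt[r, c]
        br, bc, bprev = pr, pc, (r, c)
        for _ in range(3):
            ref = max(ref, dt[br, bc])
            back = [(rr, cc) for rr, cc in neighbors8(br, bc)
                    if S[rr, cc] and (rr, cc) != bprev]
            if len(back) != 1:
                break
            bprev, (br, bc) = (br, bc), back[0]
        for _ in range(max_iter):
            dr, dc = r - pr, c - pc
            best, best_dt = None, -1.0
            for ddr in (-1, 0, 1):
                for ddc in (-1, 0, 1):
                    if ddr * dr + ddc * dc <= 0:
                        continue
                    cr, cc_ = r + ddr, c + ddc
                    if not (0 <= cr < h and 0 <= cc_ < w):
                        continue
                    if not mask[cr, cc_] or S[cr, cc_]:
                        continue
                    # must touch the skeleton only at the current tip
                    touch = sum(S[rr, cc] for rr, cc in neighbors8(cr, cc_))
                    if touch != 1:
                        continue
                    if dt[cr, cc_] >= ref - 1.0 and dt[cr, cc_] > best_dt:
                        best, best_dt = (cr, cc_), dt[cr, cc_]
            if best is None:
                break
            S[best] = True
            pr, pc, (r, c) = r, c, best
    return S


def skeletonize_mask(mask: BinaryMask, extend_tips: bool = True) -> BinaryMask:
    """One-pixel-wide 8-connected topological skeleton (Zhang thinning).

    ``extend_tips`` regrows the branch ends that thinning erodes (about
    one tube radius per open end) along the distance-transform ridge of
    the mask; it adds pixels only inside the mask and never changes the
    component or branch topology.
    """
    S = sk_skeletonize(mask.pixels)
    if extend_tips:
        S = _extend_tips(S, mask.pixels)
    return BinaryMask(S, pixels_per_micron=mask.pixels_per_micron)


@dataclass
class SkeletonNode:
    node_id: int
    kind: str  # "junction" | "endpoint" | "isolated"
    pixels: list[tuple[int, int]]


@dataclass
class SkeletonBranch:
    branch_id: int
    node_ids: tuple[int | None, int | None]
    path: list[tuple[int, int]]
    length_px: float
    length_um: float
    closed: bool = False


@dataclass
class ComponentGraph:
    """Skeleton graph of one connected component."""

    component_id: int
    nodes: list[SkeletonNode]
    branches: list[SkeletonBranch]
    degenerate: bool = False  # single isolated skeleton pixel

    @property
    def branch_count(self) -> int:
        return len(self.branches)

    @property
    def junction_count(self) -> int:
        return sum(1 for n in self.nodes if n.kind == "junction")

    @property
    def endpoint_count(self) -> int:
        return sum(1 for n in self.nodes if n.kind == "endpoint")

    @property
    def branch_lengths_um(self) -> list[float]:
        return [b.length_um for b in self.branches]


@dataclass
class SkeletonGraph:
    """Per-component skeleton graphs of one cell image."""

    components: dict[int, ComponentGraph]
    pixels_per_micron: float

    def __iter__(self):
        return iter(self.components.values())


def _step_len(a: tuple[int, int], b: tuple[int, int]) -> float:
    return SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0


def _path_len(path: list[tuple[int, int]]) -> float:
    if len(path) == 1:
        return 1.0  # isolated-pixel convention: one pixel-equivalent
    return sum(_step_len(path[i], path[i + 1]) for i in range(len(path) - 1))


def analyze_skeleton(
    skel: BinaryMask, components: ComponentSet | None = None
) -> SkeletonGraph:
    """Decompose a 1-px skeleton into junction/endpoint nodes and branches.

    When ``components`` (labeling of the pre-skeleton mask) is given,
    component ids follow that labeling, so graphs can be joined with
    component areas downstream; otherwise the skeleton is labeled on its
    own.  Raises on non-skeleton input (any solid 2×2 foreground block).
    """
    S = skel.pixels
    ppm = skel.pixels_per_micron
    if (S[:-1, :-1] & S[:-1, 1:] & S[1:, :-1] & S[1:, 1:]).any():
        # 2x2 blocks are legitimate only at stable skeleton crossings
        # (all four pixels are junction pixels and thinning cannot reduce
        # them); a solid region that re-thinning would shrink is not a
        # skeleton
        if not np.array_equal(sk_skeletonize(S), S):
            raise ValueError(
                "input is not a 1-px skeleton (contains a reducible solid "
                "2x2 foreground block)"
            )

    if components is not None:
        labels = components.labels
        if ((S > 0) & (labels == 0)).any():
            raise ValueError("skeleton has pixels outside the labeled mask")
    else:
        labels = sk_label(S, connectivity=2)

    nbr_count = convolve(S.astype(np.uint8), np.ones((3, 3), np.uint8),
                         mode="constant") - S.astype(np.uint8)
    junction_mask = S & (nbr_count > 2)
    cluster_labels = sk_label(junction_mask, connectivity=2)

    coords = list(map(tuple, np.argwhere(S)))
    coord_set = set(coords)

    def neighbors(p: tuple[int, int]) -> list[tuple[int, int]]:
        out = []
        for dr, dc in _NEIGHBOR_OFFSETS:
            q = (p[0] + dr, p[1] + dc)
            if q in coord_set:
                out.append(q)
        return out

    # node bookkeeping: junction clusters share a node id, endpoints and
    # isolated pixels get their own
    node_of: dict[tuple[int, int], int] = {}
    nodes: dict[int, SkeletonNode] = {}
    next_node = 0
    cluster_to_node: dict[int, int] = {}
    for p in coords:
        cl = cluster_labels[p]
        if cl > 0:
            if cl not in cluster_to_node:
                cluster_to_node[cl] = next_node
                nodes[next_node] = SkeletonNode(next_node, "junction", [])
                next_node += 1
            nid = cluster_to_node[cl]
            nodes[nid].pixels.append(p)
            node_of[p] = nid
        elif nbr_count[p] == 1:
            nodes[next_node] = SkeletonNode(next_node, "endpoint", [p])
            node_of[p] = next_node
            next_node += 1
        elif nbr_count[p] == 0:
            nodes[next_node] = SkeletonNode(next_node, "isolated", [p])
            node_of[p] = next_node
            next_node += 1

    # during tracing, branch length is the plain step-metric path length;
    # junction-point corrections are applied afterwards (see below)
    def branch_length(path: list[tuple[int, int]]) -> float:
        return _path_len(path)

    used: set[tuple[int, int]] = set()
    branches: list[SkeletonBranch] = []
    seen_pairs: set[frozenset] = set()

    def trace(anchor: tuple[int, int], first: tuple[int, int]) -> None:
        start_node = node_of[anchor]
        path = [anchor, first]
        used.add(first)
        prev, cur = anchor, first
        while True:
            nbrs = [q for q in neighbors(cur) if q != prev]
            terms = []
            for q in nbrs:
                if q in node_of:
                    # skip re-touching the start junction cluster right away
                    if node_of[q] == start_node and len(path) < 4:
                        continue
                    terms.append(q)
            if terms:
                path.append(terms[0])
                end_node = node_of[terms[0]]
                break
            slabs = [q for q in nbrs if q not in node_of and q not in used]
            if not slabs:
                end_node = None  # dead end inside a slab run (rare)
                break
            nxt = slabs[0]
            used.add(nxt)
            path.append(nxt)
            prev, cur = cur, nxt
        L = branch_length(path)
        branches.append(
            SkeletonBranch(
                branch_id=len(branches),
                node_ids=(start_node, end_node),
                path=path,
                length_px=L,
                length_um=L / ppm,
            )
        )

    # branches leaving nodes through slab pixels, and direct node-node edges
    for p in sorted(node_of):
        nid = node_of[p]
        if nodes[nid].kind == "isolated":
            branches.append(
                SkeletonBranch(
                    branch_id=len(branches),
                    node_ids=(nid, nid),
                    path=[p],
                    length_px=1.0,
                    length_um=1.0 / ppm,
                )
            )
            continue
        for q in neighbors(p):
            if q in node_of:
                if node_of[q] != nid:
                    pair = frozenset((p, q))
                    if pair not in seen_pairs:
                        seen_pairs.add(pair)
                        path = [p, q]
                        L = branch_length(path)
                        branches.append(
                            SkeletonBranch(
                                branch_id=len(branches),
                                node_ids=(nid, node_of[q]),
                                path=path,
                                length_px=L,
                                length_um=L / ppm,
                            )
                        )
            elif q not in used:
                trace(p, q)

    # pure cycles: slab pixels never reached from any node
    for p in sorted(coord_set):
        if p in node_of or p in used:
            continue
        path = [p]
        used.add(p)
        prev, cur = None, p
        cap = len(coords) + 2
        while cap > 0:
            cap -= 1
            nbrs = [q for q in neighbors(cur) if q != prev]
            if p in nbrs and len(path) > 2:
                path.append(p)  # close the ring
                break
            nxt = [q for q in nbrs if q not in used]
            if not nxt:
                break
            used.add(nxt[0])
            path.append(nxt[0])
            prev, cur = cur, nxt[0]
        branches.append(
            SkeletonBranch(
                branch_id=len(branches),
                node_ids=(None, None),
                path=path,
                length_px=_path_len(path),
                length_um=_path_len(path) / ppm,
                closed=path[0] == path[-1] and len(path) > 2,
            )
        )

    # Branches conceptually meet at the junction *point*, while traced
    # paths stop at the edge of the merged junction-pixel cluster (which
    # thinning can also displace along an arm).  The junction point is
    # localized as the least-squares intersection of the arm centerlines
    # (a line fitted to the first path pixels of every attached branch),
    # and each attached branch gains the anchor-to-junction distance.
    for nid, node in nodes.items():
        if node.kind != "junction":
            continue
        centroid = np.mean(node.pixels, axis=0)
        ends = []  # (branch, end index 0/-1, anchor pixel)
        for br in branches:
            for end, end_nid in ((0, br.node_ids[0]), (-1, br.node_ids[1])):
                if end_nid == nid:
                    ends.append((br, end))
        A = np.zeros((2, 2))
        rhs = np.zeros(2)
        n_lines = 0
        for br, end in ends:
            pts = br.path[:6] if end == 0 else br.path[-6:][::-1]
            P = np.asarray(pts, dtype=float)
            if len(P) < 3:
                continue
            mean = P.mean(axis=0)
            _, _, vt = np.linalg.svd(P - mean, full_matrices=False)
            v = vt[0]
            proj = np.eye(2) - np.outer(v, v)
            A += proj
            rhs += proj @ mean
            n_lines += 1
        point = centroid
        if n_lines >= 2 and abs(np.linalg.det(A)) > 1e-6:
            cand = np.linalg.solve(A, rhs)
            # keep the refinement local: far solutions mean near-parallel
            # arms, where the intersection is ill-conditioned
            if np.hypot(*(cand - centroid)) <= 3.0:
                point = cand
        for br, end in ends:
            anchor = np.asarray(br.path[end], dtype=float)
            extra = min(float(np.hypot(*(point - anchor))), 3.5)
            br.length_px += extra
            br.length_um = br.length_px / ppm

    # group nodes/branches by component
    graphs: dict[int, ComponentGraph] = {}

    def graph_for(cid: int) -> ComponentGraph:
        if cid not in graphs:
            graphs[cid] = ComponentGraph(component_id=cid, nodes=[], branches=[])
        return graphs[cid]

    for nid, node in nodes.items():
        cid = int(labels[node.pixels[0]])
        graph_for(cid).nodes.append(node)
    for br in branches:
        cid = int(labels[br.path[0]])
        graph_for(cid).branches.append(br)
    for g in graphs.values():
        g.degenerate = (
            len(g.branches) == 1
            and len(g.branches[0].path) == 1
        )
    return SkeletonGraph(components=graphs, pixels_per_micron=ppm)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class MitoObject:
    """One connected component with its class under the two-class filter."""

    component_id: int
    mito_class: str  # "network" | "individual" | "unclassified"
    branch_count: int
    junction_count: int
    endpoint_count: int
    branch_lengths_um: list[float]
    area_um2: float
    aspect_ratio: float
    reason: str | None = None  # set for unclassified objects
    degenerate: bool = False


def classify_objects(
    graphs: SkeletonGraph, components: ComponentSet
) -> list[MitoObject]:
    """Apply the network/individual filter to every component.

    network    iff branch_count > 1 and junction_count >= 1
    individual iff branch_count == 1 and junction_count == 0 and the
               single branch is open (a closed ring has no endpoints and
               is tallied as unclassified with reason "loop")
    """
    by_id = {int(r.component_id): r for r in components.props.itertuples()}
    graph_ids = set(graphs.components)
    comp_ids = set(by_id)
    if graph_ids - comp_ids:
        raise ValueError(
            f"skeleton components {sorted(graph_ids - comp_ids)} missing "
            "from the component set"
        )
    if comp_ids - graph_ids:
        raise ValueError(
            f"components {sorted(comp_ids - graph_ids)} have no skeleton graph"
        )
    objects = []
    for cid in sorted(graph_ids):
        g = graphs.components[cid]
        row = by_id[cid]
        b, j, e = g.branch_count, g.junction_count, g.endpoint_count
        reason = None
        if b > 1 and j >= 1:
            cls = "network"
        elif b == 1 and j == 0 and e > 0:
            cls = "individual"
        elif b == 1 and j == 0 and g.degenerate:
            cls = "individual"  # isolated skeleton pixel: a "drop"
        else:
            cls = "unclassified"
            if e == 0 and j == 0:
                reason = "loop"
            else:
                reason = f"unmatched topology (branches={b}, junctions={j}, endpoints={e})"
        objects.append(
            MitoObject(
                component_id=cid,
                mito_class=cls,
                branch_count=b,
                junction_count=j,
                endpoint_count=e,
                branch_lengths_um=g.branch_lengths_um,
                area_um2=float(row.area_um2),
                aspect_ratio=float(row.aspect_ratio),
                reason=reason,
                degenerate=g.degenerate,
            )
        )
    return objects


# ---------------------------------------------------------------------------
# per-cell aggregation
# ---------------------------------------------------------------------------

@dataclass
class CellMorphometrics:
    """The per-cell morphometric parameter set (medians per cell).

    Missing values (NaN) appear whenever the relevant object set is
    empty — e.g. the individual:network ratio is undefined in a cell
    without networks; they are never silently reported as zero.
    """

    cell_id: str
    footprint_um2: float
    median_network_branch_len_um: float
    individual_to_network_ratio: float
    median_individual_len_um: float
    mean_junctions_per_network: float
    median_individual_aspect_ratio: float
    n_networks: int
    n_individuals: int
    n_unclassified: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def cell_morphometrics(
    objects: list[MitoObject], footprint_um2: float, cell_id: str = "cell"
) -> CellMorphometrics:
    """Aggregate classified objects into the per-cell parameter set."""
    networks = [o for o in objects if o.mito_class == "network"]
    individuals = [o for o in objects if o.mito_class == "individual"]
    n_unclassified = sum(1 for o in objects if o.mito_class == "unclassified")
    nan = float("nan")

    net_branch_lengths = [l for o in networks for l in o.branch_lengths_um]
    ind_lengths = [o.branch_lengths_um[0] for o in individuals]
    ind_aspects = [o.aspect_ratio for o in individuals if np.isfinite(o.aspect_ratio)]

    return CellMorphometrics(
        cell_id=cell_id,
        footprint_um2=float(footprint_um2),
        median_network_branch_len_um=(
            float(np.median(net_branch_lengths)) if net_branch_lengths else nan
        ),
        individual_to_network_ratio=(
            len(individuals) / len(networks) if networks else nan
        ),
        median_individual_len_um=(
            float(np.median(ind_lengths)) if ind_lengths else nan
        ),
        mean_junctions_per_network=(
            sum(o.junction_count for o in networks) / len(networks)
            if networks
            else nan
        ),
        median_individual_aspect_ratio=(
            float(np.median(ind_aspects)) if ind_aspects else nan
        ),
        n_networks=len(networks),
        n_individuals=len(individuals),
        n_unclassified=n_unclassified,
    )


def objects_frame(objects: list[MitoObject], cell_id: str = "cell") -> pd.DataFrame:
    """Per-object audit table (one row per component)."""
    return pd.DataFrame(
        [
            {
                "cell_id": cell_id,
                "component_id": o.component_id,
                "mito_class": o.mito_class,
                "reason": o.reason,
                "n_branches": o.branch_count,
                "n_junctions": o.junction_count,
                "n_endpoints": o.endpoint_count,
                "total_branch_len_um": float(np.sum(o.branch_lengths_um)),
                "area_um2": o.area_um2,
                "aspect_ratio": o.aspect_ratio,
                "degenerate": o.degenerate,
            }
            for o in objects
        ]
    )


@dataclass
class MorphologyResult:
    """Everything derived from one mask: components, graph, objects, summary."""

    components: ComponentSet
    skeleton: BinaryMask
    graph: SkeletonGraph
    objects: list[MitoObject]
    morphometrics: CellMorphometrics


class MitoNetworkAnalyzer(BaseEstimator):
    """Mask-to-morphometrics analyzer (components → skeleton → filter).

    A scikit-learn-style estimator over binary masks: ``transform``
    maps a list of :class:`BinaryMask` to a per-cell DataFrame, and
    ``analyze`` exposes all intermediates for a single mask.
    """

    def __init__(self, min_area_px: int = 1):
        self.min_area_px = min_area_px

    def fit(self, X=None, y=None):
        return self

    def analyze(self, mask: BinaryMask, cell_id: str = "cell") -> MorphologyResult:
        components = label_components(mask)
        if self.min_area_px > 1 and components.n_components:
            keep = components.props["area_px"] >= self.min_area_px
            drop_ids = set(components.props.loc[~keep, "component_id"])
            if drop_ids:
                pruned = np.isin(components.labels, list(drop_ids))
                cleaned = BinaryMask(
                    mask.pixels & ~pruned, pixels_per_micron=mask.pixels_per_micron
                )
                components = label_components(cleaned)
                mask = cleaned
        skeleton = skeletonize_mask(mask)
        graph = analyze_skeleton(skeleton, components)
        objects = classify_objects(graph, components)
        footprint = mitochondrial_footprint(components)
        morpho = cell_morphometrics(objects, footprint, cell_id=cell_id)
        return MorphologyResult(components, skeleton, graph, objects, morpho)

    def transform(self, X: list[BinaryMask], cell_ids: list[str] | None = None) -> pd.DataFrame:
        ids = cell_ids or [f"cell_{i:03d}" for i in range(len(X))]
        rows = [self.analyze(m, cid).morphometrics.as_dict() for m, cid in zip(X, ids)]
        return pd.DataFrame(rows)
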