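"""Synthetic single-cell scenes and kinetic traces with exact ground truth.

The generator emulates the two kinds of raw data the analysis pipeline
consumes:

* **Micrographs** containing a mix of branched tubular mitochondrial
  networks and short individual mitochondria (rods and spherical
  "drops"), optionally with closed "donut" loops.  Networks are grown as
  self-avoiding lattice walks with per-step branching, so the exact
  centerline, branch lengths, junction and endpoint counts of every
  object are known before rasterization.  Centerlines are dilated to a
  tube radius, blurred with an isotropic Gaussian PSF and corrupted with
  a Poisson + Gaussian camera noise model.
* **Fluorescence traces** with a linear drift (ROS probes) or a
  plateau-then-drop shape (TMRM with FCCP addition).

Every output is a deterministic function of the spec (including its
seed), which makes the generator usable as a ground-truth oracle in
recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import circle_perimeter, line as draw_line
from skimage.morphology import dilation, disk

from .images import BinaryMask, Micrograph, DEFAULT_PIXELS_PER_MICRON
from .kinetics import FluorescenceTrace

SQRT2 = math.sqrt(2.0)

# 8-connected compass directions, indexed clockwise.
_DIRS = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
)
_STEP_LEN = np.array([1.0, SQRT2, 1.0, SQRT2, 1.0, SQRT2, 1.0, SQRT2])


class SceneCrowdingError(RuntimeError):
    """Raised when objects cannot be placed without overlap."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic micrograph.

    Lengths are in µm unless the name says px.  ``branching_prob`` is the
    per-growth-step probability that a growing network branch spawns a
    side branch.  The noise model is Poisson shot noise (``poisson_scale``
    photons per intensity unit; 0 disables it) followed by additive
    Gaussian read noise of ``gaussian_sd``.
    """

    image_size: tuple[int, int] = (512, 512)
    pixels_per_micron: float = DEFAULT_PIXELS_PER_MICRON
    n_networks: int = 2
    n_individuals: int = 6
    n_spheres: int = 0
    branch_length_range: tuple[float, float] = (1.0, 3.0)
    branching_prob: float = 0.03
    tube_radius: int = 2
    psf_sigma: float = 1.0
    background_level: float = 100.0
    foreground_level: float = 400.0
    brightness_jitter: float = 0.0
    poisson_scale: float = 1.0
    gaussian_sd: float = 10.0
    include_loops: bool = False
    n_loops: int = 1
    network_topology: str = "random"  # "random" | "y"
    max_junctions_per_network: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError("image_size must be positive")
        if not self.pixels_per_micron > 0:
            raise ValueError("pixels_per_micron must be positive")
        lo, hi = self.branch_length_range
        if lo > hi or lo <= 0:
            raise ValueError("branch_length_range must satisfy 0 < min <= max")
        if not 0.0 <= self.branching_prob <= 1.0:
            raise ValueError("branching_prob must be in [0, 1]")
        if not 0.0 <= self.brightness_jitter < 1.0:
            raise ValueError("brightness_jitter must be in [0, 1)")
        if self.tube_radius < 1:
            raise ValueError("tube_radius must be >= 1")
        if min(self.n_networks, self.n_individuals, self.n_spheres) < 0:
            raise ValueError("object counts must be non-negative")
        if self.gaussian_sd < 0 or self.poisson_scale < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.network_topology not in ("random", "y"):
            raise ValueError("network_topology must be 'random' or 'y'")


@dataclass
class ObjectTruth:
    """Ground-truth record of one simulated object (pre-rasterization)."""

    object_id: int
    object_class: str  # network | individual | loop
    shape: str  # tree | rod | sphere | ring
    true_branch_lengths_um: list[float]
    true_junction_count: int
    true_endpoint_count: int
    centerline_pixels: list[tuple[int, int]]
    true_area_px: int = 0

    @property
    def branch_count(self) -> int:
        return len(self.true_branch_lengths_um)


@dataclass
class SceneGroundTruth:
    """All objects of one scene, for recovery tests and audits."""

    objects: list[ObjectTruth] = field(default_factory=list)

    def __post_init__(self) -> None:
        for obj in self.objects:
            if obj.object_class == "network":
                assert obj.branch_count > 1 and obj.true_junction_count >= 1
            elif obj.object_class == "individual":
                assert obj.branch_count == 1 and obj.true_junction_count == 0
            assert obj.true_area_px >= 0

    def by_class(self, object_class: str) -> list[ObjectTruth]:
        return [o for o in self.objects if o.object_class == object_class]

    def to_json(self, path: str | Path) -> None:
        records = []
        for o in self.objects:
            rec = asdict(o)
            rec["centerline_pixels"] = [
                [int(r), int(c)] for r, c in o.centerline_pixels
            ]
            rec["true_branch_lengths_um"] = [float(x) for x in o.true_branch_lengths_um]
            records.append(rec)
        Path(path).write_text(json.dumps(records, indent=1))

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "object_id": o.object_id,
                "object_class": o.object_class,
                "shape": o.shape,
                "n_branches": o.branch_count,
                "n_junctions": o.true_junction_count,
                "n_endpoints": o.true_endpoint_count,
                "total_length_um": float(np.sum(o.true_branch_lengths_um)),
                "area_px": o.true_area_px,
            }
            for o in self.objects
        ]
        return pd.DataFrame(rows)


@dataclass
class TraceSpec:
    """Parameters of one synthetic fluorescence trace.

    ``slope`` is in intensity units per frame; frames are ``dt`` seconds
    apart (5 s by default, the acquisition rate of the plate-reader
    recordings this emulates).  When ``fccp_frame`` is set, the trace
    drops by ``fccp_drop`` at that frame, emulating uncoupler addition.
    """

    n_frames: int = 120
    dt: float = 5.0
    baseline: float = 100.0
    slope: float = 0.0
    fccp_frame: int | None = None
    fccp_drop: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.fccp_frame is not None and not 0 < self.fccp_frame < self.n_frames:
            raise ValueError("fccp_frame must lie inside the trace")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _path_length_px(path: np.ndarray) -> float:
    """Geometric length of an 8-connected pixel path (1 / sqrt(2) steps)."""
    if len(path) < 2:
        return 1.0 if len(path) == 1 else 0.0
    steps = np.abs(np.diff(path, axis=0))
    return float(np.where(steps.max(axis=1) == 0, 0.0, np.where(steps.sum(axis=1) == 2, SQRT2, 1.0)).sum())


def _dilate_centerline(
    pixels: list[tuple[int, int]], shape: tuple[int, int], radius: int
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = zip(*pixels)
    mask[np.array(rr), np.array(cc)] = True
    return dilation(mask, disk(radius))


class _NetworkGrowth:
    """Self-avoiding lattice growth of one branched network.

    Branches keep a clearance distance from every non-adjacent part of
    the tree so that the rasterized tubes never touch or blur together;
    side branches leave junctions at >= 90 degrees for the same reason.
    """

    def __init__(self, spec: SceneSpec, rng: np.random.Generator, forbidden: np.ndarray):
        self.spec = spec
        self.rng = rng
        self.forbidden = forbidden
        self.shape = spec.image_size
        self.clearance = 2 * spec.tube_radius + 6
        self.exempt = self.clearance + 2
        self.margin = spec.tube_radius + int(math.ceil(3 * spec.psf_sigma)) + 2
        ppm = spec.pixels_per_micron
        self.len_range_px = (
            spec.branch_length_range[0] * ppm,
            spec.branch_length_range[1] * ppm,
        )
        self.min_branch_px = max(6.0, 0.8 * self.len_range_px[0])
        # branches are straight between junctions: thinning smooths sharp
        # lattice corners, which would bias recovered lengths low
        self.turn_prob = 0.0

    def _target_len(self) -> float:
        return float(self.rng.uniform(*self.len_range_px))

    def _in_bounds(self, p: np.ndarray) -> bool:
        h, w = self.shape
        return (
            self.margin <= p[0] < h - self.margin
            and self.margin <= p[1] < w - self.margin
        )

    def _clear(
        self,
        cand: np.ndarray,
        tree_pts: list[np.ndarray],
        own_tail: list[np.ndarray],
        start: np.ndarray,
    ) -> bool:
        if self.forbidden[cand[0], cand[1]]:
            return False
        if not tree_pts:
            return True
        pts = np.asarray(tree_pts)
        d2 = ((pts - cand) ** 2).sum(axis=1)
        # exempt the recent tail of the current branch and the junction vicinity
        start_d2 = ((pts - start) ** 2).sum(axis=1)
        exempt = start_d2 <= self.exempt**2
        if own_tail:
            tail = np.asarray(own_tail)
            for t in tail:
                exempt |= (pts == t).all(axis=1)
        return bool(np.all(d2[~exempt] >= self.clearance**2))

    def grow(self) -> dict | None:
        """One growth attempt; returns branches/junctions or None."""
        spec, rng = self.spec, self.rng
        h, w = self.shape
        if h - 2 * self.margin <= 2 or w - 2 * self.margin <= 2:
            raise SceneCrowdingError(
                f"image {self.shape} too small for margin {self.margin}"
            )
        start = np.array(
            [
                rng.integers(self.margin, h - self.margin),
                rng.integers(self.margin, w - self.margin),
            ]
        )
        if self.forbidden[start[0], start[1]]:
            return None

        branches: list[np.ndarray] = []
        junctions: list[tuple[int, int]] = []
        endpoints: list[tuple[int, int]] = []
        tree_pts: list[np.ndarray] = []
        n_events = 0
        forced_y = spec.network_topology == "y"

        if forced_y:
            dirs = [int(rng.integers(8))]
            dirs += [(dirs[0] + 3) % 8, (dirs[0] + 5) % 8]
            queue = [(start.copy(), d, self._target_len(), False) for d in dirs]
            junctions.append(tuple(start))
        else:
            queue = [(start.copy(), int(rng.integers(8)), self._target_len(), True)]
        endpoints_pending: list[tuple[int, int]] = []

        while queue:
            node, d, target, is_trunk = queue.pop()
            path = [node.copy()]
            cur = node.copy()
            length = 0.0
            steps = 0
            split_done = False
            while length < target:
                if (
                    not forced_y
                    and steps >= self.exempt
                    and target - length > 14
                    and n_events < spec.max_junctions_per_network
                    and rng.random() < spec.branching_prob
                ):
                    # mid-branch T event: terminate here, spawn continuation + side arm
                    junctions.append(tuple(cur))
                    side = (d + rng.choice([-2, 2])) % 8
                    queue.append((cur.copy(), d, target - length, False))
                    queue.append((cur.copy(), int(side), self._target_len(), False))
                    n_events += 1
                    split_done = True
                    break
                if steps > self.exempt and rng.random() < self.turn_prob:
                    d = (d + rng.choice([-1, 1])) % 8
                cand = cur + _DIRS[d]
                if not self._in_bounds(cand):
                    break
                tail = path[-(self.clearance + 2):]
                if not self._clear(cand, tree_pts, tail, node):
                    break
                length += _STEP_LEN[d]
                cur = cand
                path.append(cur.copy())
                steps += 1
            if len(path) < 2 or _path_length_px(np.asarray(path)) < self.min_branch_px:
                return None  # crowded or unlucky geometry: retry the whole tree
            branches.append(np.asarray(path))
            tree_pts.extend(path)
            if not split_done:
                if (
                    not forced_y
                    and is_trunk
                    and n_events == 0
                    and n_events < spec.max_junctions_per_network
                ):
                    # a network must contain a junction: fork at the trunk
                    # end into a perpendicular crossbar (acute forks would
                    # displace the thinned skeleton's fork point)
                    junctions.append(tuple(cur))
                    for t in (-2, 2):
                        queue.append((cur.copy(), (d + t) % 8, self._target_len(), False))
                    n_events += 1
                else:
                    endpoints_pending.append(tuple(cur))
        if not forced_y:
            endpoints.append(tuple(start))
        endpoints.extend(endpoints_pending)
        return {"branches": branches, "junctions": junctions, "endpoints": endpoints}


def _render(spec: SceneSpec, rng: np.random.Generator, truth_mask: np.ndarray,
            object_masks: list[np.ndarray], amplitudes: list[float]) -> np.ndarray:
    img = np.full(spec.image_size, spec.background_level, dtype=np.float64)
    for mask, amp in zip(object_masks, amplitudes):
        img[mask] = spec.background_level + amp
    if spec.psf_sigma > 0:
        img = gaussian_filter(img, spec.psf_sigma)
    if spec.poisson_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) * spec.poisson_scale) / spec.poisson_scale
    if spec.gaussian_sd > 0:
        img = img + rng.normal(0.0, spec.gaussian_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def generate_scene(
    spec: SceneSpec,
) -> tuple[Micrograph, BinaryMask, SceneGroundTruth]:
    """Generate one synthetic micrograph with full ground truth.

    Returns the rendered image, the noise-free ground-truth foreground
    mask (union of all dilated centerlines) and a
    :class:`SceneGroundTruth` with one record per object.  Placement uses
    rejection sampling with a clearance band around every existing
    object; if an object cannot be placed the function raises
    :class:`SceneCrowdingError` naming the crowding parameters.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    ppm = spec.pixels_per_micron
    tube_r = spec.tube_radius
    gap = 2 * tube_r + 6  # min centerline-to-foreign-mask distance margin
    margin = tube_r + int(math.ceil(3 * spec.psf_sigma)) + 2

    occupied = np.zeros((h, w), dtype=bool)  # union of object masks
    forbidden = np.zeros((h, w), dtype=bool)  # where new centerlines may not go
    objects: list[ObjectTruth] = []
    object_masks: list[np.ndarray] = []
    max_attempts = 150

    def commit(mask: np.ndarray) -> None:
        occupied_new = mask
        occupied[:] = occupied | occupied_new
        forbidden[:] = forbidden | dilation(occupied_new, disk(tube_r + gap))

    def fail(kind: str) -> SceneCrowdingError:
        return SceneCrowdingError(
            f"could not place {kind} after {max_attempts} attempts: "
            f"image_size={spec.image_size}, n_networks={spec.n_networks}, "
            f"n_individuals={spec.n_individuals}, tube_radius={tube_r}, "
            f"branch_length_range={spec.branch_length_range} um"
        )

    oid = 0
    # -- networks ---------------------------------------------------------
    for _ in range(spec.n_networks):
        growth = _NetworkGrowth(spec, rng, forbidden)
        tree = None
        for _ in range(max_attempts):
            tree = growth.grow()
            if tree is not None:
                break
        if tree is None:
            raise fail("network")
        centerline: list[tuple[int, int]] = []
        seen = set()
        for br in tree["branches"]:
            for p in map(tuple, br):
                if p not in seen:
                    seen.add(p)
                    centerline.append(p)
        mask = _dilate_centerline(centerline, (h, w), tube_r)
        lengths_um = [_path_length_px(br) / ppm for br in tree["branches"]]
        objects.append(
            ObjectTruth(
                object_id=oid,
                object_class="network",
                shape="tree",
                true_branch_lengths_um=lengths_um,
                true_junction_count=len(tree["junctions"]),
                true_endpoint_count=len(tree["endpoints"]),
                centerline_pixels=centerline,
                true_area_px=int(mask.sum()),
            )
        )
        object_masks.append(mask)
        commit(mask)
        oid += 1

    # -- individual rods --------------------------------------------------
    for _ in range(spec.n_individuals):
        placed = False
        for _ in range(max_attempts):
            length_px = rng.uniform(*spec.branch_length_range) * ppm
            # rods run along compass directions so the step-metric length
            # of the rasterized centerline equals the drawn length exactly
            d = int(rng.integers(8))
            n_steps = max(2, int(round(length_px / _STEP_LEN[d])))
            r0 = int(rng.integers(margin, h - margin))
            c0 = int(rng.integers(margin, w - margin))
            r1 = r0 + n_steps * int(_DIRS[d][0])
            c1 = c0 + n_steps * int(_DIRS[d][1])
            if not (margin <= r1 < h - margin and margin <= c1 < w - margin):
                continue
            rr, cc = draw_line(r0, c0, r1, c1)
            if forbidden[rr, cc].any():
                continue
            path = np.column_stack([rr, cc])
            mask = _dilate_centerline(list(map(tuple, path)), (h, w), tube_r)
            objects.append(
                ObjectTruth(
                    object_id=oid,
                    object_class="individual",
                    shape="rod",
                    true_branch_lengths_um=[_path_length_px(path) / ppm],
                    true_junction_count=0,
                    true_endpoint_count=2,
                    centerline_pixels=list(map(tuple, path)),
                    true_area_px=int(mask.sum()),
                )
            )
            object_masks.append(mask)
            commit(mask)
            oid += 1
            placed = True
            break
        if not placed:
            raise fail("individual rod")

    # -- spherical drops (degenerate individuals) -------------------------
    for _ in range(spec.n_spheres):
        placed = False
        for _ in range(max_attempts):
            r0 = int(rng.integers(margin, h - margin))
            c0 = int(rng.integers(margin, w - margin))
            if forbidden[r0, c0]:
                continue
            mask = _dilate_centerline([(r0, c0)], (h, w), tube_r)
            objects.append(
                ObjectTruth(
                    object_id=oid,
                    object_class="individual",
                    shape="sphere",
                    true_branch_lengths_um=[1.0 / ppm],
                    true_junction_count=0,
                    true_endpoint_count=1,
                    centerline_pixels=[(r0, c0)],
                    true_area_px=int(mask.sum()),
                )
            )
            object_masks.append(mask)
            commit(mask)
            oid += 1
            placed = True
            break
        if not placed:
            raise fail("spherical drop")

    # -- donut loops -------------------------------------------------------
    n_loops = spec.n_loops if spec.include_loops else 0
    for _ in range(n_loops):
        placed = False
        for _ in range(max_attempts):
            circ_px = rng.uniform(*spec.branch_length_range) * ppm
            radius = max(2 * tube_r + 3, int(round(circ_px / (2 * math.pi))))
            lo, hi_r, hi_c = margin + radius, h - margin - radius, w - margin - radius
            if hi_r <= lo or hi_c <= lo:
                continue
            r0 = int(rng.integers(lo, hi_r))
            c0 = int(rng.integers(lo, hi_c))
            rr, cc = circle_perimeter(r0, c0, radius)
            if forbidden[rr, cc].any():
                continue
            # order perimeter pixels by angle to get a closed path
            ang = np.arctan2(rr - r0, cc - c0)
            order = np.argsort(ang)
            path = np.column_stack([rr[order], cc[order]])
            closed = np.vstack([path, path[:1]])
            mask = _dilate_centerline(list(map(tuple, path)), (h, w), tube_r)
            objects.append(
                ObjectTruth(
                    object_id=oid,
                    object_class="loop",
                    shape="ring",
                    true_branch_lengths_um=[_path_length_px(closed) / ppm],
                    true_junction_count=0,
                    true_endpoint_count=0,
                    centerline_pixels=list(map(tuple, path)),
                    true_area_px=int(mask.sum()),
                )
            )
            object_masks.append(mask)
            commit(mask)
            oid += 1
            placed = True
            break
        if not placed:
            raise fail("loop")

    amplitudes = [
        spec.foreground_level
        * (1.0 + (rng.uniform(-spec.brightness_jitter, spec.brightness_jitter)
                  if spec.brightness_jitter > 0 else 0.0))
        for _ in objects
    ]
    img = _render(spec, rng, occupied, object_masks, amplitudes)
    micrograph = Micrograph(img, bit_depth=16, pixels_per_micron=ppm)
    truth_mask = BinaryMask(occupied, pixels_per_micron=ppm)
    return micrograph, truth_mask, SceneGroundTruth(objects)


def generate_trace(spec: TraceSpec, trace_id: str = "trace") -> FluorescenceTrace:
    """Generate one fluorescence time series.

    intensity(t) = baseline + slope * frame + N(0, noise_sd), with a step
    drop of ``fccp_drop`` from ``fccp_frame`` onward when present.
    """
    rng = np.random.default_rng(spec.seed)
    frames = np.arange(spec.n_frames)
    times = frames * spec.dt
    y = spec.baseline + spec.slope * frames.astype(float)
    if spec.fccp_frame is not None:
        y[spec.fccp_frame:] -= spec.fccp_drop
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
    return FluorescenceTrace(trace_id=trace_id, times=times, intensities=y)


def write_scene(
    out_dir: str | Path,
    name: str,
    micrograph: Micrograph,
    truth_mask: BinaryMask,
    truth: SceneGroundTruth,
) -> dict[str, Path]:
    """Write a scene as TIFF + truth JSON + object-summary CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / f"{name}.tif",
        "truth_json": out / f"{name}_truth.json",
        "truth_csv": out / f"{name}_truth.csv",
    }
    micrograph.to_tiff(paths["image"])
    truth.to_json(paths["truth_json"])
    truth.summary_frame().to_csv(paths["truth_csv"], index=False)
    return paths


def traces_to_frame(traces: list[FluorescenceTrace]) -> pd.DataFrame:
    """Long-format table: trace_id, frame, time_s, intensity."""
    rows = []
    for tr in traces:
        for i, (t, y) in enumerate(zip(tr.times, tr.intensities)):
            rows.append(
                {"trace_id": tr.trace_id, "frame": i, "time_s": float(t),
                 "intensity": float(y)}
            )
    return pd.DataFrame(rows)
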