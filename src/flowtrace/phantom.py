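"""Synthetic dynamic-CTA phantoms of vascular trees with known flow.

The phantom is a tree of straight cylindrical vessel segments through
which a gamma-variate contrast bolus propagates at a prescribed signed
velocity per segment.  Positive velocity means the bolus enters at the
segment end nearest the tree root and travels away from it (anterograde);
negative velocity means the bolus enters at the far (distal) end and
travels toward the root, emulating retrograde collateral supply.  Because
the arrival time of the bolus at every voxel is known in closed form, the
phantom provides exact ground truth — mask, centerlines, arrival times,
delay-versus-distance slopes — for every downstream stage.

An optional thrombus is modelled as a sub-interval of one segment whose
contrast enhancement is scaled by a permeability factor in [0, 1],
reproducing the reduced in-thrombus enhancement seen in patient data.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .preprocess import DynamicCTA

__all__ = [
    "BolusSpec", "VesselSegmentSpec", "ThrombusSpec", "PhantomSpec",
    "gamma_variate", "rasterize_tree", "arrival_time_field",
    "render_dynamic", "default_markers", "spec_from_json", "spec_to_json",
]


def gamma_variate(tau, amplitude: float, t_peak: float, alpha: float):
    """First-pass bolus model ``A (τ/tp)^α exp(α (1 − τ/tp))`` for τ>0.

    Peaks at exactly ``amplitude`` when τ = t_peak; zero for τ ≤ 0.
    """
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    x = tau[pos] / t_peak
    out[pos] = amplitude * x ** alpha * np.exp(alpha * (1.0 - x))
    return out


@dataclass(frozen=True)
class BolusSpec:
    """Gamma-variate contrast bolus: peak enhancement, time-to-peak, shape."""

    amplitude_hu: float = 400.0
    t_peak_s: float = 6.0
    shape_alpha: float = 3.0

    def __post_init__(self):
        if self.amplitude_hu <= 0 or self.t_peak_s <= 0 or self.shape_alpha <= 0:
            raise ValueError("bolus parameters must be positive")

    def curve(self, tau):
        return gamma_variate(tau, self.amplitude_hu, self.t_peak_s,
                             self.shape_alpha)


@dataclass(frozen=True)
class VesselSegmentSpec:
    """A straight cylindrical vessel segment.

    ``velocity_mm_s`` is signed: positive = contrast travels start→end
    (anterograde, away from the root), negative = end→start (retrograde).
    ``inlet_arrival_s`` is the bolus arrival time at the end where the
    contrast enters (start for anterograde, end for retrograde).  A
    ``static`` segment fills simultaneously at ``inlet_arrival_s``.
    """

    start_mm: tuple
    end_mm: tuple
    radius_mm: float
    velocity_mm_s: float
    inlet_arrival_s: float
    static: bool = False

    def __post_init__(self):
        object.__setattr__(self, "start_mm", tuple(float(v) for v in self.start_mm))
        object.__setattr__(self, "end_mm", tuple(float(v) for v in self.end_mm))
        if self.length_mm <= 0:
            raise ValueError("segment length must be positive")
        if self.radius_mm <= 0:
            raise ValueError("segment radius must be positive")
        if self.velocity_mm_s == 0 and not self.static:
            raise ValueError("zero velocity requires static=True")

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.subtract(self.end_mm, self.start_mm)))

    @property
    def unit(self) -> np.ndarray:
        v = np.subtract(self.end_mm, self.start_mm)
        return v / np.linalg.norm(v)


@dataclass(frozen=True)
class ThrombusSpec:
    """Permeability scaling of a sub-interval of one segment.

    Enhancement of voxels whose axial position falls in
    [start_frac, end_frac] of the segment is multiplied by
    ``permeability`` ∈ [0, 1].
    """

    segment: int = 0
    start_frac: float = 0.25
    end_frac: float = 0.5
    permeability: float = 0.5

    def __post_init__(self):
        if not 0 <= self.start_frac < self.end_frac <= 1:
            raise ValueError("need 0 <= start_frac < end_frac <= 1")
        if not 0 <= self.permeability <= 1:
            raise ValueError("permeability must be in [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic dynamic CTA acquisition."""

    grid_shape: tuple = (64, 64, 16)
    spacing: tuple = (1.0, 1.0, 1.0)
    dt: float = 2.0
    n_frames: int = 30
    segments: tuple = ()
    bolus: BolusSpec = field(default_factory=BolusSpec)
    noise_sigma: float = 10.0
    background_hu: float = 40.0
    seed: int = 0
    thrombus: Optional[ThrombusSpec] = None
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "segments", tuple(self.segments))
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for i, seg in enumerate(self.segments):
            if seg.radius_mm < max(self.spacing):
                raise ValueError(
                    f"segment {i}: radius {seg.radius_mm} mm is below the "
                    f"largest voxel spacing {max(self.spacing)} mm and would "
                    "not be resolvable")
        if self.thrombus is not None and self.segments:
            if not 0 <= self.thrombus.segment < len(self.segments):
                raise ValueError("thrombus.segment index out of range")
        self._tree_offsets()  # validates connectivity

    def _tree_offsets(self):
        """Arc-length from the tree root to each segment's start point.

        Segment 0 is the root.  Every later segment must start at the
        start or end point of an earlier segment (a connected tree).
        """
        offsets = []
        tol = 0.25 * min(self.spacing) if self.spacing else 1e-6
        for i, seg in enumerate(self.segments):
            if i == 0:
                offsets.append(0.0)
                continue
            start = np.asarray(seg.start_mm)
            found = None
            for j in range(i):
                parent = self.segments[j]
                if np.linalg.norm(start - np.asarray(parent.end_mm)) <= tol:
                    found = offsets[j] + parent.length_mm
                    break
                if np.linalg.norm(start - np.asarray(parent.start_mm)) <= tol:
                    found = offsets[j]
                    break
            if found is None:
                raise ValueError(
                    f"segment {i} does not start at an endpoint of any "
                    "earlier segment; the tree is disconnected")
            offsets.append(found)
        return offsets


# ---------------------------------------------------------------------------
# rasterization and ground truth

def _voxel_centers(spec, lo_idx, hi_idx):
    axes = [spec.origin[a] + np.arange(lo_idx[a], hi_idx[a]) * spec.spacing[a]
            for a in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _segment_bbox(spec, seg):
    lo = np.minimum(seg.start_mm, seg.end_mm) - seg.radius_mm - max(spec.spacing)
    hi = np.maximum(seg.start_mm, seg.end_mm) + seg.radius_mm + max(spec.spacing)
    lo_idx = np.floor((lo - np.asarray(spec.origin)) / spec.spacing).astype(int)
    hi_idx = np.ceil((hi - np.asarray(spec.origin)) / spec.spacing).astype(int) + 1
    lo_idx = np.clip(lo_idx, 0, spec.grid_shape)
    hi_idx = np.clip(hi_idx, 0, spec.grid_shape)
    return tuple(lo_idx), tuple(hi_idx)


def _check_inside(spec, seg, index):
    extent_lo = np.asarray(spec.origin)
    extent_hi = extent_lo + (np.asarray(spec.grid_shape) - 1) * np.asarray(spec.spacing)
    for p in (seg.start_mm, seg.end_mm):
        p = np.asarray(p)
        if np.any(p - seg.radius_mm < extent_lo) or np.any(p + seg.radius_mm > extent_hi):
            raise ValueError(
                f"segment {index} (radius {seg.radius_mm} mm) extends outside "
                f"the grid extent {extent_lo.tolist()}..{extent_hi.tolist()} mm")


def _rasterize_full(spec: PhantomSpec):
    """Voxel membership and per-voxel segment assignment.

    Returns (mask, seg_id, axial_mm) where seg_id is the index of the
    nearest segment axis (ties broken by lowest index) and axial_mm the
    arc-length of the voxel's axial projection from that segment's start.
    """
    shape = spec.grid_shape
    mask = np.zeros(shape, dtype=bool)
    axis_dist = np.full(shape, np.inf)
    seg_id = np.full(shape, -1, dtype=int)
    axial = np.zeros(shape)
    for i, seg in enumerate(spec.segments):
        _check_inside(spec, seg, i)
        lo, hi = _segment_bbox(spec, seg)
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        X, Y, Z = _voxel_centers(spec, lo, hi)
        s0 = np.asarray(seg.start_mm)
        u = seg.unit
        wx, wy, wz = X - s0[0], Y - s0[1], Z - s0[2]
        t = np.clip(wx * u[0] + wy * u[1] + wz * u[2], 0.0, seg.length_mm)
        d2 = ((wx - t * u[0]) ** 2 + (wy - t * u[1]) ** 2
              + (wz - t * u[2]) ** 2)
        d = np.sqrt(d2)
        inside = d <= seg.radius_mm
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        sub_mask = mask[sl]
        sub_dist = axis_dist[sl]
        closer = inside & (d < sub_dist - 1e-12)
        mask[sl] = sub_mask | inside
        seg_id[sl] = np.where(closer, i, seg_id[sl])
        axial[sl] = np.where(closer, t, axial[sl])
        axis_dist[sl] = np.where(closer, d, sub_dist)
    return mask, seg_id, axial


def rasterize_tree(spec: PhantomSpec):
    """Binary vessel mask plus exact per-segment centerline polylines.

    Returns
    -------
    (mask, truth) where ``mask`` is a boolean 3D array and ``truth`` is a
    list (one entry per segment) of dicts with keys ``points_mm`` (M, 3),
    ``arclength_mm`` (arc-length from the segment start), ``root_mm``
    (arc-length from the tree root), ``arrival_s`` and ``velocity_mm_s``.
    Centerlines are sampled at intervals no larger than the smallest
    voxel spacing.
    """
    mask, _, _ = _rasterize_full(spec)
    truth = []
    offsets = spec._tree_offsets()
    step = min(spec.spacing) if spec.spacing else 1.0
    for i, seg in enumerate(spec.segments):
        n = max(2, int(np.ceil(seg.length_mm / step)) + 1)
        t = np.linspace(0.0, seg.length_mm, n)
        pts = np.asarray(seg.start_mm)[None, :] + t[:, None] * seg.unit[None, :]
        truth.append({
            "segment": i,
            "points_mm": pts,
            "arclength_mm": t,
            "root_mm": offsets[i] + t,
            "arrival_s": _arrival_along(seg, t),
            "velocity_mm_s": seg.velocity_mm_s,
        })
    return mask, truth


def _arrival_along(seg: VesselSegmentSpec, t):
    """Bolus arrival time at axial position t (mm from the segment start)."""
    t = np.asarray(t, dtype=float)
    if seg.static:
        return np.full_like(t, seg.inlet_arrival_s)
    if seg.velocity_mm_s > 0:
        entry_dist = t
    else:
        entry_dist = seg.length_mm - t
    return seg.inlet_arrival_s + entry_dist / abs(seg.velocity_mm_s)


def arrival_time_field(spec: PhantomSpec):
    """Bolus arrival time (s) per mask voxel; NaN outside the mask.

    Each voxel inherits the arrival time of its axial projection onto the
    nearest segment axis, so along any segment the arrival gradient with
    respect to root distance is exactly 1/velocity (signed).
    """
    mask, seg_id, axial = _rasterize_full(spec)
    arrival = np.full(spec.grid_shape, np.nan)
    for i, seg in enumerate(spec.segments):
        sel = mask & (seg_id == i)
        if not sel.any():
            continue
        arrival[sel] = _arrival_along(seg, axial[sel])
    return arrival


def _enhancement_factor(spec, mask, seg_id, axial):
    factor = np.where(mask, 1.0, 0.0)
    th = spec.thrombus
    if th is not None and spec.segments:
        seg = spec.segments[th.segment]
        frac = axial / seg.length_mm
        in_th = mask & (seg_id == th.segment) & (frac >= th.start_frac) \
            & (frac <= th.end_frac)
        factor[in_th] = th.permeability
    return factor


def render_dynamic(spec: PhantomSpec) -> DynamicCTA:
    """Render the 4D HU series: background + bolus enhancement + noise.

    Frame k samples time k·dt.  The enhancement of an in-mask voxel with
    arrival time a is ``bolus(k·dt − a)``, scaled by the thrombus
    permeability factor where applicable.  Gaussian noise of standard
    deviation ``noise_sigma`` HU is added everywhere; the render is
    deterministic for a given ``spec.seed``.
    """
    mask, seg_id, axial = _rasterize_full(spec)
    arrival = arrival_time_field(spec)
    factor = _enhancement_factor(spec, mask, seg_id, axial)
    times = np.arange(spec.n_frames) * spec.dt
    data = np.full(spec.grid_shape + (spec.n_frames,), float(spec.background_hu))
    if mask.any():
        arr = arrival[mask]
        fac = factor[mask]
        tau = times[None, :] - arr[:, None]
        enh = fac[:, None] * spec.bolus.curve(tau)
        data[mask] += enh
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, data.shape)
    return DynamicCTA(data, spec.spacing, spec.dt, spec.origin)


def default_markers(spec: PhantomSpec, pullback_mm: float = 3.0):
    """Voxel-index markers derived from the ground-truth tree.

    proximal: on the root axis, ``pullback_mm`` from the root start;
    thrombus: mid-point of the thrombus interval (root mid-point if no
    thrombus is specified); distal: one marker per leaf segment,
    ``pullback_mm`` short of its far end.
    """
    if not spec.segments:
        raise ValueError("phantom has no segments")
    root = spec.segments[0]

    def to_vox(p):
        idx = np.round((np.asarray(p) - np.asarray(spec.origin))
                       / np.asarray(spec.spacing)).astype(int)
        return tuple(int(v) for v in np.clip(idx, 0, np.asarray(spec.grid_shape) - 1))

    def along(seg, t):
        return np.asarray(seg.start_mm) + np.clip(t, 0, seg.length_mm) * seg.unit

    proximal = to_vox(along(root, min(pullback_mm, 0.25 * root.length_mm)))
    if spec.thrombus is not None:
        th = spec.thrombus
        seg = spec.segments[th.segment]
        t_mid = 0.5 * (th.start_frac + th.end_frac) * seg.length_mm
        thrombus = to_vox(along(seg, t_mid))
    else:
        thrombus = to_vox(along(root, 0.5 * root.length_mm))
    # leaves: segments whose end is not the start anchor of any other segment
    tol = 0.25 * min(spec.spacing)
    distal = []
    for i, seg in enumerate(spec.segments):
        end = np.asarray(seg.end_mm)
        is_parent = any(
            np.linalg.norm(np.asarray(other.start_mm) - end) <= tol
            for j, other in enumerate(spec.segments) if j != i)
        if not is_parent:
            distal.append(to_vox(along(seg, seg.length_mm - pullback_mm)))
    return {"proximal": list(proximal), "thrombus": list(thrombus),
            "distal": [list(d) for d in distal]}


# ---------------------------------------------------------------------------
# JSON (de)serialization

def demo_spec_path(name: str):
    """Path to a bundled demo phantom spec ('pattern1' .. 'pattern3')."""
    from importlib.resources import files
    p = files("flowtrace") / "data" / f"{name}.json"
    if not p.is_file():
        raise ValueError(f"no bundled spec named {name!r}")
    return p

def spec_to_json(spec: PhantomSpec) -> str:
    d = asdict(spec)
    return json.dumps(d, indent=2, sort_keys=True)


def spec_from_json(text: str) -> PhantomSpec:
    d = json.loads(text)
    segments = tuple(VesselSegmentSpec(**s) for s in d.pop("segments", []))
    bolus = BolusSpec(**d.pop("bolus", {}))
    th = d.pop("thrombus", None)
    thrombus = ThrombusSpec(**th) if th is not None else None
    return PhantomSpec(segments=segments, bolus=bolus, thrombus=thrombus, **d)
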