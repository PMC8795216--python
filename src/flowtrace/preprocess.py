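"""Loading, alignment, denoising and temporal projection of dynamic CTA.

A dynamic CTA acquisition is a time series of CT volumes recorded while a
contrast bolus transits the cerebral vasculature.  Everything downstream
(segmentation, centerline tracing, delay estimation) works either on the
4D series itself or on its temporal maximum intensity projection (t-MIP),
in which every vessel appears at its peak enhancement.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage


@dataclass
class DynamicCTA:
    """A 4D dynamic CTA series.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, nt)
        Attenuation in Hounsfield units, spatial axes first, time last.
    spacing : tuple of float
        Voxel size (dx, dy, dz) in mm.
    dt : float
        Frame interval in seconds; frame k is acquired at time ``k * dt``.
    origin : tuple of float
        World coordinates (mm) of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple
    dt: float
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("dynamic CTA data must be 4D (x, y, z, t)")
        if self.data.shape[-1] < 2:
            raise ValueError("dynamic CTA needs at least 2 frames")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values")
        self.dt = float(self.dt)
        if self.dt <= 0:
            raise ValueError("frame interval dt must be positive")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds."""
        return np.arange(self.n_frames) * self.dt


@dataclass
class Volume3D:
    """A single 3D volume on the same grid as its source series."""

    data: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("Volume3D data must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)


def compute_tmip(dyn: DynamicCTA) -> Volume3D:
    """Temporal maximum intensity projection: voxelwise max over time."""
    return Volume3D(dyn.data.max(axis=-1), dyn.spacing, dyn.origin)


def register_frames(dyn: DynamicCTA, reference_frame: int = 0,
                    max_shift: int = 5, subvoxel: bool = False):
    """Translation-only alignment of every frame to a reference frame.

    Each frame is aligned by maximizing its cross-correlation with the
    reference over integer voxel shifts (FFT accelerated), optionally
    refined to sub-voxel precision.  Head motion between dynamic CTA
    frames is small, so translation is the dominant component.

    Returns
    -------
    (DynamicCTA, ndarray)
        The aligned series and the applied shift per frame, in voxels,
        shape (nt, 3).  A constant (degenerate) frame, including a
        constant reference, gets zero shift and a warning.
    """
    if not 0 <= reference_frame < dyn.n_frames:
        raise ValueError(f"reference_frame {reference_frame} out of range")
    ref = dyn.data[..., reference_frame]
    out = np.empty_like(dyn.data)
    shifts = np.zeros((dyn.n_frames, 3))
    ref_degenerate = ref.std() == 0
    if ref_degenerate:
        warnings.warn("reference frame is constant; registration is a no-op")
    for k in range(dyn.n_frames):
        frame = dyn.data[..., k]
        if k == reference_frame or ref_degenerate or frame.std() == 0:
            if frame.std() == 0 and not ref_degenerate and k != reference_frame:
                warnings.warn(f"frame {k} is constant; zero shift applied")
            out[..., k] = frame
            continue
        shift = _correlation_shift(ref, frame, max_shift, subvoxel)
        shifts[k] = shift
        if np.any(shift):
            order = 1 if subvoxel else 0
            out[..., k] = ndimage.shift(frame, shift, order=order,
                                        mode="nearest")
        else:
            out[..., k] = frame
    return DynamicCTA(out, dyn.spacing, dyn.dt, dyn.origin), shifts


def _correlation_shift(ref, moving, max_shift, subvoxel):
    """Shift (voxels) to apply to `moving` so it best matches `ref`.

    Argmax of the circular cross-correlation restricted to ±max_shift per
    axis, computed via FFT; sub-voxel refinement by a separable quadratic
    fit around the integer peak.
    """
    f_ref = np.fft.fftn(ref - ref.mean())
    f_mov = np.fft.fftn(moving - moving.mean())
    cc = np.fft.ifftn(f_ref * np.conj(f_mov)).real
    # candidate shifts are wrapped; build the ±max_shift window explicitly
    axes_idx = [np.r_[0:max_shift + 1, -max_shift:0] for _ in range(3)]
    best = None
    for di, dj, dk in product(*[range(2 * max_shift + 1)] * 3):
        i, j, k = axes_idx[0][di], axes_idx[1][dj], axes_idx[2][dk]
        val = cc[i % cc.shape[0], j % cc.shape[1], k % cc.shape[2]]
        cand = (val, (int(i), int(j), int(k)))
        if best is None or cand[0] > best[0] + 1e-12:
            best = cand
        elif abs(cand[0] - best[0]) <= 1e-12 and cand[1] < best[1]:
            best = cand
    shift = np.array(best[1], dtype=float)
    if subvoxel:
        for ax in range(3):
            lo = shift.copy(); lo[ax] -= 1
            hi = shift.copy(); hi[ax] += 1
            if abs(lo[ax]) > max_shift or abs(hi[ax]) > max_shift:
                continue
            ym = cc[tuple(int(s) % cc.shape[a] for a, s in enumerate(lo))]
            y0 = best[0]
            yp = cc[tuple(int(s) % cc.shape[a] for a, s in enumerate(hi))]
            denom = ym - 2 * y0 + yp
            if denom < 0:
                shift[ax] += 0.5 * (ym - yp) / denom
    return shift


def bilateral_denoise(obj, spatial_sigma: float = 1.0,
                      range_sigma: float = 30.0, truncate: float = 2.0):
    """Edge-preserving bilateral smoothing of a volume or a 4D series.

    The spatial kernel is an anisotropic Gaussian with ``spatial_sigma``
    given in mm (converted per axis using the voxel spacing); the range
    kernel is Gaussian in HU.  ``range_sigma=numpy.inf`` disables range
    weighting, reducing the filter to plain (truncated-kernel) Gaussian
    smoothing.  For a DynamicCTA the filter is applied frame by frame;
    temporal smoothing is handled separately during TAC conditioning.
    """
    if spatial_sigma <= 0 or range_sigma <= 0:
        raise ValueError("sigmas must be positive")
    if isinstance(obj, DynamicCTA):
        out = np.empty_like(obj.data)
        for k in range(obj.n_frames):
            out[..., k] = _bilateral3d(obj.data[..., k], obj.spacing,
                                       spatial_sigma, range_sigma, truncate)
        return DynamicCTA(out, obj.spacing, obj.dt, obj.origin)
    if isinstance(obj, Volume3D):
        out = _bilateral3d(obj.data, obj.spacing, spatial_sigma,
                           range_sigma, truncate)
        return Volume3D(out, obj.spacing, obj.origin)
    raise TypeError("expected DynamicCTA or Volume3D")


def _bilateral3d(img, spacing, spatial_sigma, range_sigma, truncate):
    sig_vox = [spatial_sigma / s for s in spacing]
    # radius matches scipy.ndimage.gaussian_filter so the range->inf limit
    # agrees with it exactly
    radii = [max(1, int(truncate * sv + 0.5)) for sv in sig_vox]
    pad = np.pad(img, [(r, r) for r in radii], mode="edge")
    num = np.zeros_like(img, dtype=float)
    den = np.zeros_like(img, dtype=float)
    inv2r2 = 0.0 if np.isinf(range_sigma) else 1.0 / (2 * range_sigma ** 2)
    n = img.shape
    for off in product(*[range(-r, r + 1) for r in radii]):
        w = np.exp(-sum((o ** 2) / (2 * sv ** 2)
                        for o, sv in zip(off, sig_vox)))
        view = pad[radii[0] + off[0]: radii[0] + off[0] + n[0],
                   radii[1] + off[1]: radii[1] + off[1] + n[1],
                   radii[2] + off[2]: radii[2] + off[2] + n[2]]
        if inv2r2:
            w = w * np.exp(-((view - img) ** 2) * inv2r2)
        num += w * view
        den += w
    return num / den
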