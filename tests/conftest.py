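import numpy as np
import pytest

from flowtrace import phantom
from flowtrace.geometry import CenterlinePath


def straight_tube_spec(velocity_mm_s, noise_sigma=0.0, seed=0,
                       length_mm=50.0, radius_mm=2.0, n_frames=30, dt=2.0,
                       inlet_arrival_s=4.0):
    """A single straight vessel along x, 50 mm by default, dt = 2 s."""
    x0 = 3.0
    seg = phantom.VesselSegmentSpec(
        (x0, 4.0, 4.0), (x0 + length_mm, 4.0, 4.0), radius_mm,
        velocity_mm_s, inlet_arrival_s)
    nx = int(x0 + length_mm + radius_mm + 2)
    return phantom.PhantomSpec(
        grid_shape=(nx, 9, 9), spacing=(1.0, 1.0, 1.0), dt=dt,
        n_frames=n_frames, segments=(seg,), noise_sigma=noise_sigma,
        seed=seed)


def y_tree_spec(v_mother=10.0, v_d1=5.0, v_d2=-5.0, noise_sigma=0.0,
                seed=0, thrombus=None):
    """Small bifurcating tree: mother along +y, daughters at 45 degrees.

    Daughter inlet arrivals are consistent with the mother junction
    arrival for anterograde daughters; retrograde daughters receive
    contrast at their distal tip at t = 6 s.
    """
    mother = phantom.VesselSegmentSpec((20, 4, 6), (20, 20, 6), 2.0,
                                       v_mother, 4.0)
    t_junction = 4.0 + mother.length_mm / abs(v_mother)
    segs = [mother]
    for vd, end in ((v_d1, (10, 30, 6)), (v_d2, (30, 30, 6))):
        inlet = t_junction if vd > 0 else 6.0
        segs.append(phantom.VesselSegmentSpec((20, 20, 6), end, 2.0, vd,
                                              inlet))
    return phantom.PhantomSpec(
        grid_shape=(40, 36, 12), spacing=(1.0, 1.0, 1.0), dt=2.0,
        n_frames=30, segments=tuple(segs), noise_sigma=noise_sigma,
        seed=seed, thrombus=thrombus)


def truth_centerline_path(spec, segment=0, path_id="truth"):
    """CenterlinePath built from a phantom's exact centerline polyline."""
    _, truth = phantom.rasterize_tree(spec)
    tr = truth[segment]
    voxels, arcs, last = [], [], None
    for p, r in zip(tr["points_mm"], tr["root_mm"]):
        v = tuple(int(round((c - o) / s)) for c, o, s in
                  zip(p, spec.origin, spec.spacing))
        if v != last:
            voxels.append(v)
            arcs.append(float(r))
            last = v
    n = len(voxels)
    return CenterlinePath(path_id, voxels, np.asarray(arcs), ["distal"] * n,
                          ["mother"] * n)


@pytest.fixture(scope="session")
def tube_plus5():
    return straight_tube_spec(5.0)


@pytest.fixture(scope="session")
def ytree():
    return y_tree_spec()


@pytest.fixture(scope="session")
def ytree_rendered(ytree):
    return phantom.render_dynamic(ytree)
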