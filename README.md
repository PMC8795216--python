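# flowtrace

Semi-automated quantification of blood (contrast) flow **direction and
velocity in arterial branches distal to an occluding thrombus** from 4D
dynamic CTA, for researchers studying residual perfusion in acute
ischemic stroke.

When a thrombus occludes an intracranial artery, tissue downstream may
still be perfused by two mechanisms: residual **anterograde** flow
through a permeable thrombus, or **retrograde** flow supplied by
leptomeningeal collaterals. The two can be told apart by the direction
of contrast transport in the branches beyond the occlusion.

## Method

From a dynamic CTA series `I(x, y, z, t)` (Hounsfield units, frame
interval Δt):

1. **Preprocess** — optional translation-only frame alignment, bilateral
   denoising, and the temporal maximum intensity projection
   `tMIP(x) = max_t I(x, t)`.
2. **Centerlines** — vessels are segmented on the t-MIP (threshold, or a
   supplied mask), thinned to a one-voxel skeleton, and turned into a
   graph with mm edge lengths. User markers (proximal, thrombus, distal
   branches) are snapped to the skeleton and connected by minimum-cost
   paths with edge cost `ℓ · (I_max − Ī + ε)`, so bright vessel cores
   are cheap.
3. **Delays** — each centerline voxel's time-attenuation curve (TAC) is
   upsampled, zero-phase Butterworth low-pass filtered and
   baseline-subtracted; TACs with peaks below 5% of the proximal peak
   are discarded; the delay τ(s) of each TAC relative to the proximal
   marker's TAC is the lag maximizing their normalized
   cross-correlation.
4. **Velocity and pattern** — per vessel segment, ordinary least squares
   of delay on arc-length gives a slope dτ/ds whose inverse is the
   signed average velocity, `v = 1/(dτ/ds)` mm/s (positive anterograde,
   negative retrograde). The daughter-segment directions classify the
   case: Pattern I (all anterograde), II (all retrograde), III (both).

A synthetic phantom module renders vascular trees with a gamma-variate
bolus `C(τ) = A (τ/t_p)^α e^{α(1−τ/t_p)}` propagating at prescribed
signed velocities, with exact ground truth (masks, centerlines, arrival
times) for validating every stage.

## Worked example

Run the bundled mixed-flow phantom (a Y-shaped tree whose daughters
carry +5 and −5 mm/s flow) end to end:

```sh
cat > cfg.json <<'JSON'
{"out_dir": "demo_out",
 "phantom_spec": "src/flowtrace/data/pattern3.json",
 "geometry": {"threshold_hu": 100.0},
 "seed": 7}
JSON
flowtrace -v run --config cfg.json
```

which prints

```
INFO skeleton: 57 nodes, 3 endpoints, 1 branch nodes
INFO pattern III
pattern: III
  daughter1: anterograde (+5.0 mm/s, n=14)
  daughter2: retrograde (-5.1 mm/s, n=14)
  mother: anterograde (+9.7 mm/s, n=15)
outputs in demo_out
```

The mother segment (ground truth +10 mm/s) and both daughters (+5 and
−5 mm/s) are recovered to within a few percent, and the opposing
daughter directions classify the case as Pattern III — mixed distal
flow, the signature of a permeable thrombus coexisting with collateral
supply. `demo_out/` contains per-voxel delays (`delays.csv`),
per-segment fits (`segments.json`), the pattern label (`pattern.json`),
conditioned TACs, and a manifest of every parameter used.
`flowtrace plot --results demo_out` renders the TAC waterfall and the
delay-versus-distance figure with the fitted regression lines.

Real data enter the same way: a 4D NIfTI volume plus a JSON sidecar
with the frame interval, a markers JSON in voxel indices, and
optionally a vessel mask / ROI NIfTI instead of the threshold.

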