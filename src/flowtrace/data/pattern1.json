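{
  "grid_shape": [64, 64, 16],
  "spacing": [1.0, 1.0, 1.0],
  "dt": 2.0,
  "n_frames": 30,
  "background_hu": 40.0,
  "noise_sigma": 10.0,
  "seed": 7,
  "bolus": {"amplitude_hu": 400.0, "t_peak_s": 6.0, "shape_alpha": 3.0},
  "thrombus": {"segment": 0, "start_frac": 0.25, "end_frac": 0.5, "permeability": 0.5},
  "segments": [
    {"start_mm": [32.0, 6.0, 8.0], "end_mm": [32.0, 30.0, 8.0],
     "radius_mm": 2.0, "velocity_mm_s": 10.0, "inlet_arrival_s": 4.0},
    {"start_mm": [32.0, 30.0, 8.0], "end_mm": [16.0, 46.0, 8.0],
     "radius_mm": 2.0, "velocity_mm_s": 5.0, "inlet_arrival_s": 6.4},
    {"start_mm": [32.0, 30.0, 8.0], "end_mm": [48.0, 46.0, 8.0],
     "radius_mm": 2.0, "velocity_mm_s": 8.0, "inlet_arrival_s": 6.4}
  ]
}
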