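"""Simulate one walking trial and run the full COP pipeline on it.

Generates a seeded 16-step barefoot walk on a virtual 240 Hz pressure mat,
detects the footfalls, estimates each foot's axis, finds the stance events
and prints the per-footfall COP parameters for the first footfalls.
"""

from copmat import analyze_recording
from copmat.synthetic import SynthConfig, generate_recording

cfg = SynthConfig(seed=1, n_steps=16)
rec, truth = generate_recording(cfg)
print(f"mat: {rec.grid_rows} x {rec.grid_cols} cells at {rec.cell_pitch} mm, "
      f"{rec.sampling_rate:.0f} Hz, {rec.n_frames} non-empty frames")

analysis = analyze_recording(rec)
print(f"footfalls detected: {len(analysis.footfalls)} "
      f"({len(analysis.parameters)} valid)")

cols = ["footfall", "side", "stance_ms", "MON_pct", "FFT_pct", "HOT_pct",
        "MOF_pct", "CbP_velAP_cms", "ICP_mlocML_pct"]
print(analysis.parameters[cols].head(4).round(2).to_string(index=False))
print(
    "\nstance_ms is the footfall's contact duration; MON/FFT/HOT/MOF are the\n"
    "midfoot-on, foot-flat, heel-off and midfoot-off times as % of stance;\n"
    "CbP_velAP_cms is the anteroposterior COP speed (cm/s) between midfoot-on\n"
    "and heel-off; ICP_mlocML_pct is the mean mediolateral COP position during\n"
    "initial contact as a signed % of foot width (negative = medial of the\n"
    "heel center)."
)
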