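"""Left/right imbalance parameters from an asymmetric recording.

Programs the right-side channels with 8% higher median frequencies than
the left, then computes the per-level symmetric ratio series and the two
global imbalance parameters.
"""

from semgfatigue import AngleProfile, default_channel_specs, generate_recording
from semgfatigue.pipeline import process_recording

rec = generate_recording(
    default_channel_specs(right_left_onset_ratio=1.08),
    AngleProfile(23.0, 0.0),
    duration=30.0,
    seed=7,
)
result = process_recording(rec)
imb = result.imbalance

for level in ("L1", "L2", "L5"):
    print(f"segmental imbalance {level}: {imb.segmental[level]:+.2f} %")
print(f"uncompensated imbalance: {imb.uncompensated:.2f} %")
print(f"compensated imbalance:   {imb.compensated:+.2f} %")
print("\nSegmental values are time-means of the corrected right/left ratio")
print("(positive = right > left).  The uncompensated parameter is the mean")
print("absolute segmental value (total asymmetry); the compensated one keeps")
print("the sign, so opposite lateralisation at different levels cancels.")
print("With an 8% right-shift programmed everywhere, both sit near +8%.")
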