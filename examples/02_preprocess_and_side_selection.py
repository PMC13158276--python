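"""Preprocess one scan and apply the severe-side selection rule.

Shows the chain: integral background subtraction -> Otsu contouring ->
midline-symmetric crop to 224x448 -> per-kidney 224x224 inputs, then the
label-informed rule that picks one kidney per patient for training.
"""

from scintivur.phantom import PhantomConfig, generate_patient
from scintivur.preprocess import preprocess_scan
from scintivur.sideselect import select_severe_side

scan = generate_patient(PhantomConfig(), grade_left=3, grade_right=1, patient_seed=7)
crop, left, right = preprocess_scan(scan.image, patient_id=scan.patient_id)

print(f"crop box (top, left, h, w) in source pixels: {crop.crop_box}")
print(f"standardised bilateral view: {crop.image.shape}, midline at column {crop.midline_column}")
print(f"mean tracer uptake  left: {left.mean_intensity:6.1f}   right: {right.mean_intensity:6.1f}")

decision = select_severe_side(
    scan.vur_grade_left,
    scan.vur_grade_right,
    left.mean_intensity,
    right.mean_intensity,
    scan.patient_id,
    seed=0,
)
print(f"severe side: {decision.chosen_side} (rule: {decision.rule_fired})")
print(
    "\nThe left kidney carries the higher VUR grade (3 vs 1), so the rule "
    "selects it regardless of intensity; its lower mean uptake reflects the "
    "planted cortical defects."
)
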