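"""Per-patient paired alterations: tumor-vs-adjacent-normal dPSI calls.

For every patient with both tissues, the within-patient dPSI of the top
event is computed and called altered when |dPSI| strictly exceeds 0.15.
"""

from splicescreen.paired import alteration_frequency, patient_deltas
from splicescreen.simulate import SimConfig, generate_bundles

cfg = SimConfig(seed=1)
bundles, truth = generate_bundles(cfg)

print("per-type paired alteration frequency of the planted event:")
for b in bundles[:5]:
    deltas = patient_deltas(b.psi, b.samples, truth.planted_event_id, threshold=0.15)
    freq, num, den = alteration_frequency(deltas, threshold=0.15)
    planted = "planted" if truth.true_delta[b.cancer_type] != 0 else "null   "
    print(f"  {b.cancer_type}  [{planted}]  {num:2d}/{den} patients altered "
          f"({100 * freq:.0f}%)")
# Types carrying the planted shift show ~50% altered patients (the planted
# fraction); null types stay near 0% because within-patient noise is small
# relative to the 0.15 threshold.
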