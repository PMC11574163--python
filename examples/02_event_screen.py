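"""Pan-cancer event screen: summarize, filter, and rank by mean |dPSI|.

For each cancer type every event gets tumor/normal mean PSI, dPSI and a
two-tailed pooled t-test; events quantified in >= 80% of types and detected
in >= 12 of them are retained and ranked by mean |dPSI| across types.
"""

from splicescreen.events import filter_events, rank_events, summarize_bundle
from splicescreen.simulate import SimConfig, generate_bundles

bundles, truth = generate_bundles(SimConfig(seed=1))

summaries = []
for b in bundles:
    summaries.extend(summarize_bundle(b, min_n=10))

retained = filter_events(summaries, quantified_frac=0.80, min_detected=12)
ranks = rank_events(summaries)  # full ranking, decoys included

print(f"{len(retained)} event(s) pass the cross-cancer filters")
print("top of the mean |dPSI| ranking:")
for r in ranks[:3]:
    print(f"  #{r.rank}  {r.event.event_id:24s} mean|dPSI|={r.mean_abs_dpsi:.3f} "
          f"(quantified in {r.n_types_quantified}, detected in {r.n_types_detected})")
print(f"\nplanted event recovered at rank 1: "
      f"{ranks[0].event.event_id == truth.planted_event_id}")
# A mean |dPSI| near 0.16 reflects the +0.2 shift planted in 12 of the 15
# types averaged over all quantified types; decoy events sit near 0.02.
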