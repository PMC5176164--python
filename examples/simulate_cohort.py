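"""Generate a synthetic captive-seal cohort and one labelled session.

Prints the subject table and the bout composition of one session: which
behaviours occurred, how long they lasted, and the five-category mix. In a
real deployment these labels would come from synchronised video coding.
"""

import pandas as pd

import ethoclass as ec

config = ec.SimulationConfig(n_subjects=6, session_length=300.0, seed=42)
profiles = ec.generate_cohort(config)
print(pd.DataFrame([vars(p) for p in profiles]).to_string(index=False))

trace, labels = ec.simulate_session(profiles[0], ec.default_behaviour_specs(), config)
print(f"\nsession for {profiles[0].subject_id}: {len(trace)} samples "
      f"({len(trace) / trace.sampling_rate:.0f} s at {trace.sampling_rate:.0f} Hz)")

bouts = (labels["behaviour"] != labels["behaviour"].shift()).cumsum()
per_bout = labels.groupby(bouts).agg(behaviour=("behaviour", "first"),
                                     category=("category", "first"),
                                     samples=("behaviour", "size"))
per_bout["seconds"] = per_bout["samples"] / trace.sampling_rate
print(f"\n{len(per_bout)} bouts; durations "
      f"{per_bout.seconds.min():.2f}-{per_bout.seconds.max():.1f} s")
print("\nper-category share of samples (duration-weighted):")
print(labels["category"].value_counts(normalize=True).round(3).to_string())
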