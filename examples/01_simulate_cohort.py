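"""Generate a small synthetic cohort and inspect its structure.

Builds a 6-subject cohort (wrist + ankle gyroscope streams at 64 Hz, three
rounds of seven activities each, OFF -> ON medication cycling) and prints
the cohort summary plus one round's activity segments with the two
simulated raters' total-mAIMS scores and the derived gold score.
"""

from dyskest.io import assemble_dataset
from dyskest.synth import CohortConfig, generate_cohort

config = CohortConfig(
    n_subjects=6, rounds_per_subject=3, short_round_subjects=0,
    activity_duration_s=(15.0, 30.0), seed=42,
)
recordings, annotations = generate_cohort(config)
dataset = assemble_dataset(recordings, annotations)

print("cohort:", dataset.summary())
first = annotations[0]
print(f"\nsubject {first.subject_id}, round {first.round_index} "
      f"({first.medication_state} state):")
for seg in first.segments:
    print(f"  {seg.activity:20s} {seg.duration_s:5.1f}s  "
          f"raters {seg.rater1:4.1f}/{seg.rater2:4.1f}  gold {seg.gold:4.1f}")
# A gold score is the mean of the two raters' 0-28 total-mAIMS ratings;
# this subject's first round is OFF, so only low-grade wearing-off
# dyskinesia remains while OFF-state rest tremor is added to the signal.
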