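"""Generate a synthetic gait study and inspect its structure.

Builds a typically developing reference cohort (56 children) and a
labeled cerebral-palsy dataset, then prints the cohort sizes, the
trials-per-session statistics and the empirical prevalence of the
sagittal-pelvis patterns.  The prevalences track the clinical ones
because pattern codes are quota-sampled from the printed frequencies.
"""

from collections import Counter

import numpy as np

from cpgait import (
    CLASS_FREQUENCIES,
    GeneratorConfig,
    compute_normative_band,
    generate_cp_dataset,
    generate_reference_cohort,
)

reference = generate_reference_cohort(56, seed=1)
band = compute_normative_band(reference)
dataset = generate_cp_dataset(GeneratorConfig(n_patients=100, seed=1))

sessions = Counter(t.session_id for t in dataset)
per_session = np.array(list(sessions.values()))
print(f"reference cohort: {len(reference)} children")
print(f"CP dataset: {len(dataset.patients)} patients, "
      f"{len(sessions)} sessions, {len(dataset)} trials")
print(f"trials per session: min {per_session.min()}, max {per_session.max()}, "
      f"mean {per_session.mean():.2f}  (target: 2..15, mean 4)")

ps = Counter(t.labels["PS"] for t in dataset)
print("\nsagittal pelvis pattern prevalence (trials, %):")
for cls in sorted(ps):
    obs = 100 * ps[cls] / len(dataset)
    print(f"  {cls}: {obs:5.1f}%   (clinical: {CLASS_FREQUENCIES['PS'][cls]:.1f}%)")
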