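"""Extract the 24 expert-defined gait features from one trial.

Prints every feature of a synthetic trial next to its expert bin.
Continuous features are angles (deg), timings (% of phase) or
band-exceedance percentages; composite features are pairs of
above/below band flags mapping to three states.
"""

from cpgait import (
    EXPERT_FEATURE_ORDER,
    EXPERT_FEATURES,
    EXPERT_SCHEMES,
    GeneratorConfig,
    compute_normative_band,
    extract_expert_features,
    generate_cp_dataset,
    generate_reference_cohort,
)
from cpgait.discretization import CompositeScheme

band = compute_normative_band(generate_reference_cohort(56, seed=1))
trial = generate_cp_dataset(GeneratorConfig(n_patients=1, seed=3)).trials[0]
features = extract_expert_features(trial, band)

print(f"trial {trial.trial_id}; true patterns: {trial.labels}\n")
print(f"{'feature':>20}  {'joint motion':>12}  {'value':>14}  bin")
for name in EXPERT_FEATURE_ORDER:
    scheme = EXPERT_SCHEMES[name]
    value = features[name]
    if isinstance(scheme, CompositeScheme):
        shown = f"above={value[0]}, below={value[1]}"
        b = scheme.apply(value)
    else:
        shown = f"{value:10.2f}"
        b = scheme.apply(value)
    jm = EXPERT_FEATURES[name].joint_motion
    print(f"{name:>20}  {jm:>12}  {shown:>14}  {b}")
print("\nbin indices follow the expert cut points; e.g. the second-rocker "
      "excursion bins are [-21,-5.5), [-5.5,19.4), [19.4,31].")
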