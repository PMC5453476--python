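"""Correlation-based feature selection on the full gait battery.

Discretizes the ~1000-feature battery for the swing-knee joint motion,
runs CFS with best-first search, and prints the selected subset with
its merit.  The selected features should concentrate on swing-phase
knee-flexion quantities.
"""

import numpy as np
import pandas as pd

from cpgait import (
    GeneratorConfig,
    cfs_merit,
    best_first_select,
    compute_normative_band,
    extract_full_matrix,
    generate_cp_dataset,
    generate_reference_cohort,
    mdl_discretize,
)

band = compute_normative_band(generate_reference_cohort(56, seed=1))
dataset = generate_cp_dataset(GeneratorConfig(n_patients=40, seed=5))
battery = extract_full_matrix(dataset, band)
labels = np.array([t.labels["KSWS"] for t in dataset])

binned = {}
for name in battery.columns:
    scheme = mdl_discretize(battery[name].to_numpy(), labels, feature=name)
    if scheme.n_bins >= 2:  # single-bin features carry no information
        binned[name] = scheme.apply(battery[name].to_numpy())
binned = pd.DataFrame(binned, index=battery.index)
print(f"battery: {battery.shape[1]} features, "
      f"{binned.shape[1]} informative after MDL discretization")

selected = best_first_select(binned, labels)
merit = cfs_merit(selected, binned, labels)
print(f"\nselected {len(selected)} features (merit {merit:.3f}):")
for name in selected:
    print(f"  {name}")
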