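"""CSV persistence for datasets and normative bands.

Formats (UTF-8, '.' decimal separator):

* curves: long table ``trial_id,patient_id,session_id,toe_off_pct,track,
  domain,sample_index,angle_deg`` with ``sample_index`` in 0..50;
* labels: ``trial_id,joint_motion,pattern_code``;
* band: ``track,domain,sample_index,mean_deg,sd_deg`` plus a scalar
  summary table ``track,cycle_mean_mean,cycle_mean_sd``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    N_SAMPLES,
    Dataset,
    Domain,
    GaitTrial,
    JOINT_MOTIONS,
    NormativeBand,
    PHASE_TRACKS,
    Track,
    ValidationError,
)

CURVE_COLUMNS = [
    "trial_id", "patient_id", "session_id", "toe_off_pct",
    "track", "domain", "sample_index", "angle_deg",
]
LABEL_COLUMNS = ["trial_id", "joint_motion", "pattern_code"]


def dataset_to_tables(dataset: Dataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a dataset into its long curve table and label table."""
    curve_rows = []
    label_rows = []
    idx = np.arange(N_SAMPLES)
    for t in dataset:
        for (track, domain), values in sorted(
            t.curves.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
        ):
            curve_rows.append(
                pd.DataFrame(
                    {
                        "trial_id": t.trial_id,
                        "patient_id": t.patient_id,
                        "session_id": t.session_id,
                        "toe_off_pct": t.toe_off_pct,
                        "track": track.value,
                        "domain": domain.value,
                        "sample_index": idx,
                        "angle_deg": values,
                    }
                )
            )
        for jm_code in sorted(t.labels):
            label_rows.append((t.trial_id, jm_code, t.labels[jm_code]))
    curves = pd.concat(curve_rows, ignore_index=True) if curve_rows else pd.DataFrame(
        columns=CURVE_COLUMNS
    )
    labels = pd.DataFrame(label_rows, columns=LABEL_COLUMNS)
    return curves, labels


def dataset_from_tables(curves: pd.DataFrame, labels: pd.DataFrame | None) -> Dataset:
    """Rebuild a dataset from its long curve table and label table."""
    missing = [c for c in CURVE_COLUMNS if c not in curves.columns]
    if missing:
        raise ValidationError(f"curve table is missing columns: {missing}")
    label_map: dict[str, dict[str, str]] = {}
    if labels is not None and len(labels):
        for row in labels.itertuples(index=False):
            jm = str(row.joint_motion)
            if jm not in JOINT_MOTIONS:
                raise ValidationError(
                    f"label table: unknown joint motion {jm!r} for trial "
                    f"{row.trial_id!r}"
                )
            if str(row.pattern_code) not in JOINT_MOTIONS[jm].classes:
                raise ValidationError(
                    f"label table: unknown pattern code {row.pattern_code!r} "
                    f"for joint motion {jm} (trial {row.trial_id!r})"
                )
            label_map.setdefault(str(row.trial_id), {})[jm] = str(row.pattern_code)

    trials = []
    for trial_id, group in curves.groupby("trial_id", sort=True):
        meta = group.iloc[0]
        curve_map = {}
        for (track, domain), sub in group.groupby(["track", "domain"]):
            try:
                track, domain = Track(track), Domain(domain)
            except ValueError as exc:
                raise ValidationError(f"trial {trial_id!r}: {exc}") from None
            sub = sub.sort_values("sample_index")
            if len(sub) != N_SAMPLES or not np.array_equal(
                sub["sample_index"].to_numpy(), np.arange(N_SAMPLES)
            ):
                raise ValidationError(
                    f"trial {trial_id!r}, {track.value}/{domain.value}: expected "
                    f"sample_index 0..{N_SAMPLES - 1}, got {len(sub)} rows"
                )
            curve_map[(track, domain)] = sub["angle_deg"].to_numpy(dtype=float)
        trials.append(
            GaitTrial(
                trial_id=str(trial_id),
                session_id=str(meta["session_id"]),
                patient_id=str(meta["patient_id"]),
                toe_off_pct=float(meta["toe_off_pct"]),
                curves=curve_map,
                labels=label_map.get(str(trial_id), {}),
            )
        )
    return Dataset(trials)


def write_dataset(dataset: Dataset, curve_path, label_path) -> None:
    curves, labels = dataset_to_tables(dataset)
    curves.to_csv(curve_path, index=False)
    labels.to_csv(label_path, index=False)


def read_dataset(curve_path, label_path=None) -> Dataset:
    curves = pd.read_csv(curve_path)
    labels = pd.read_csv(label_path) if label_path is not None else None
    return dataset_from_tables(curves, labels)


def band_to_tables(band: NormativeBand) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    idx = np.arange(N_SAMPLES)
    for (track, domain) in sorted(band.mean, key=lambda k: (k[0].value, k[1].value)):
        rows.append(
            pd.DataFrame(
                {
                    "track": track.value,
                    "domain": domain.value,
                    "sample_index": idx,
                    "mean_deg": band.mean[(track, domain)],
                    "sd_deg": band.sd[(track, domain)],
                }
            )
        )
    curves = pd.concat(rows, ignore_index=True)
    scalars = pd.DataFrame(
        {
            "track": [t.value for t in Track],
            "cycle_mean_mean": [band.cycle_mean_mean[t] for t in Track],
            "cycle_mean_sd": [band.cycle_mean_sd[t] for t in Track],
        }
    )
    return curves, scalars


def band_from_tables(curves: pd.DataFrame, scalars: pd.DataFrame) -> NormativeBand:
    mean, sd = {}, {}
    for (track, domain), sub in curves.groupby(["track", "domain"]):
        key = (Track(track), Domain(domain))
        sub = sub.sort_values("sample_index")
        if len(sub) != N_SAMPLES:
            raise ValidationError(
                f"band table for {track}/{domain}: expected {N_SAMPLES} rows"
            )
        mean[key] = sub["mean_deg"].to_numpy(dtype=float)
        sd[key] = sub["sd_deg"].to_numpy(dtype=float)
    cmm = {Track(r.track): float(r.cycle_mean_mean) for r in scalars.itertuples()}
    cms = {Track(r.track): float(r.cycle_mean_sd) for r in scalars.itertuples()}
    return NormativeBand(mean=mean, sd=sd, cycle_mean_mean=cmm, cycle_mean_sd=cms)


def write_band(band: NormativeBand, curve_path, scalar_path) -> None:
    curves, scalars = band_to_tables(band)
    curves.to_csv(curve_path, index=False)
    scalars.to_csv(scalar_path, index=False)


def read_band(curve_path, scalar_path) -> NormativeBand:
    return band_from_tables(pd.read_csv(curve_path), pd.read_csv(scalar_path))
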