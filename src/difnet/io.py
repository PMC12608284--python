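"""On-disk formats.

Cohorts are stored as one ``.npz`` array container per subject plus a
``demographics.csv`` table (columns ``subject_id,label,age,sex,
education_years``).  Epoch sets get a single ``.npz`` plus a JSON sidecar
recording provenance (stages applied, rejection counts).  EEG in EDF files
can be read through the optional mne adapter when mne is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .synthetic import RawRecording, SubjectProfile

__all__ = [
    "save_cohort",
    "load_cohort",
    "save_epochs",
    "load_epochs",
    "read_edf",
]

DEMOGRAPHICS_COLUMNS = ["subject_id", "label", "age", "sex", "education_years"]


def save_cohort(recordings: list[RawRecording], demographics: pd.DataFrame,
                out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        np.savez_compressed(
            out_dir / f"{rec.profile.subject_id}.npz",
            data=rec.data.astype(np.float32),
            channel_names=np.array(rec.channel_names),
            sampling_rate=rec.sampling_rate,
        )
    demographics[DEMOGRAPHICS_COLUMNS].to_csv(
        out_dir / "demographics.csv", index=False
    )
    return out_dir


def load_cohort(in_dir) -> tuple[list[RawRecording], pd.DataFrame]:
    in_dir = Path(in_dir)
    demographics = pd.read_csv(in_dir / "demographics.csv")
    recordings = []
    for row in demographics.itertuples():
        with np.load(in_dir / f"{row.subject_id}.npz") as npz:
            profile = SubjectProfile(
                subject_id=row.subject_id, label=row.label, age=int(row.age),
                sex=int(row.sex), education_years=int(row.education_years),
            )
            recordings.append(RawRecording(
                data=npz["data"].astype(np.float64),
                channel_names=tuple(str(c) for c in npz["channel_names"]),
                sampling_rate=float(npz["sampling_rate"]),
                profile=profile,
            ))
    return recordings, demographics


def save_epochs(epochs: EpochSet, path) -> Path:
    path = Path(path)
    np.savez_compressed(
        path,
        data=epochs.data.astype(np.float32),
        labels=epochs.labels,
        subject_ids=epochs.subject_ids.astype(str),
        channel_names=np.array(epochs.channel_names),
        sampling_rate=epochs.sampling_rate,
    )
    sidecar = {
        "stages": epochs.stages,
        "rejection_log": epochs.rejection_log,
        "n_epochs": int(epochs.n_epochs),
        "window_samples": epochs.window_samples,
        "step_samples": epochs.step_samples,
        "demographics": epochs.demographics.to_dict(orient="list"),
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh)
    return path


def load_epochs(path) -> EpochSet:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as npz:
        return EpochSet(
            data=npz["data"].astype(np.float64),
            sampling_rate=float(npz["sampling_rate"]),
            channel_names=tuple(str(c) for c in npz["channel_names"]),
            labels=npz["labels"],
            subject_ids=npz["subject_ids"],
            demographics=pd.DataFrame(sidecar["demographics"]),
            stages=list(sidecar["stages"]),
            rejection_log=sidecar["rejection_log"],
            window_samples=sidecar.get("window_samples"),
            step_samples=sidecar.get("step_samples"),
        )


def read_edf(path, profile: SubjectProfile) -> RawRecording:
    """Read one EDF recording via mne (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF files requires the optional 'mne' dependency "
            "(pip install difnet[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return RawRecording(
        data=raw.get_data() * 1e6,  # mne returns volts; the pipeline uses µV
        channel_names=tuple(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        profile=profile,
    )
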