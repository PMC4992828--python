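"""Reading and writing of cohort artifacts.

Tabular data go to CSV; epochs and source-map stacks go to a NumPy ``.npz``
container with a JSON sidecar holding axis metadata (channel names,
sampling rate, onset index, atlas labels).  Source maps can additionally be
exported to NIfTI with a JSON label dictionary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CohortConfig
from .synthgen import Atlas, Cohort, EpochArray, SourceMapSet


def save_epochs(epoch: EpochArray, path) -> None:
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=epoch.data)
    sidecar = {
        "channels": list(epoch.channels),
        "sampling_rate": epoch.sampling_rate,
        "onset_index": int(epoch.onset_index),
        "trial_conditions": [str(c) for c in epoch.trial_conditions],
        "task": epoch.task,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_epochs(path) -> EpochArray:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))["data"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return EpochArray(
        data=data,
        channels=meta["channels"],
        sampling_rate=meta["sampling_rate"],
        onset_index=meta["onset_index"],
        trial_conditions=np.asarray(meta["trial_conditions"]),
        task=meta["task"],
    )


def save_cohort(cohort: Cohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.subjects.to_csv(out / "subjects.csv", index=False)
    cohort.trials.to_csv(out / "trials.csv", index=False)
    if cohort.regional_erd is not None:
        cohort.regional_erd.to_csv(out / "regional_erd.csv", index=False)
    if cohort.maps:
        arrays = {f"{band}_{task}": ms.values for (band, task), ms in cohort.maps.items()}
        np.savez_compressed(out / "source_maps.npz", **arrays)
        atlas = cohort.atlas
        meta = {
            "subject_ids": cohort.subjects["subject_id"].tolist(),
            "groups": cohort.subjects["group"].tolist(),
            "labels": {str(k): v for k, v in atlas.names.items()},
            "voxel_size": atlas.voxel_size,
            "affine": atlas.affine.tolist(),
            "label_volume": atlas.label_volume.tolist(),
        }
        (out / "source_maps.json").write_text(json.dumps(meta))


def load_cohort(out_dir, config: CohortConfig | None = None) -> Cohort:
    out = Path(out_dir)
    subjects = pd.read_csv(out / "subjects.csv")
    trials = pd.read_csv(out / "trials.csv")
    regional = None
    reg_path = out / "regional_erd.csv"
    if reg_path.exists():
        regional = pd.read_csv(reg_path)
    cohort = Cohort(
        config=config or CohortConfig(),
        subjects=subjects,
        trials=trials,
        regional_erd=regional,
    )
    npz_path = out / "source_maps.npz"
    if npz_path.exists():
        meta = json.loads((out / "source_maps.json").read_text())
        atlas = Atlas(
            label_volume=np.asarray(meta["label_volume"], dtype=np.int16),
            names={int(k): v for k, v in meta["labels"].items()},
            affine=np.asarray(meta["affine"]),
            voxel_size=meta["voxel_size"],
        )
        cohort.atlas = atlas
        with np.load(npz_path) as npz:
            for key in npz.files:
                band, task = key.split("_", 1)
                cohort.maps[(band, task)] = SourceMapSet(
                    values=npz[key],
                    subject_ids=np.asarray(meta["subject_ids"]),
                    groups=np.asarray(meta["groups"]),
                    atlas=atlas,
                    band=band,
                    task=task,
                )
    return cohort


def export_map_nifti(mapset: SourceMapSet, path) -> None:
    """Write the per-subject map stack as a 4D NIfTI plus a JSON label map."""
    import nibabel as nib

    path = Path(path)
    img = nib.Nifti1Image(np.moveaxis(mapset.values, 0, -1), mapset.atlas.affine)
    nib.save(img, path.with_suffix(".nii"))
    labels = nib.Nifti1Image(mapset.atlas.label_volume.astype(np.int16), mapset.atlas.affine)
    nib.save(labels, path.with_name(path.stem + "_labels.nii"))
    path.with_suffix(".json").write_text(json.dumps({str(k): v for k, v in mapset.atlas.names.items()}))
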