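"""NIfTI/TSV/YAML round-tripping for datasets, designs and configs."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .simulate import AcquisitionParams, RoiSpec, VoxelDataset
from .stimulus import RunDesign


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def write_nifti(data: np.ndarray, voxel_size: float, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size))
    img.header.set_zooms((voxel_size,) * 3 + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def read_nifti(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    return np.asarray(img.dataobj, dtype=np.float32), float(zooms[0])


def write_events_tsv(design: RunDesign, path) -> Path:
    path = Path(path)
    design.to_events_table().to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path, tr: float, n_dummy: int, n_volumes: int,
                    seed=None) -> RunDesign:
    df = pd.read_csv(path, sep="\t")
    # onsets are tr-aligned by construction; snap to the grid so the
    # round trip is exact despite text formatting
    blocks = tuple((r.trial_type, round(float(r.onset) / tr) * tr, float(r.duration))
                   for r in df.itertuples())
    return RunDesign(blocks=blocks, tr=tr, n_dummy_volumes=n_dummy,
                     n_volumes=n_volumes, seed=seed)


def save_dataset(dataset: VoxelDataset, out_dir) -> Path:
    """4D NIfTI + ROI masks + per-run events TSVs + a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vs = dataset.acquisition.voxel_size
    write_nifti(dataset.data, vs, out / "bold.nii.gz")
    for roi in dataset.rois:
        write_nifti(roi.mask(dataset.acquisition.grid_shape).astype(np.float32),
                    vs, out / f"mask_{roi.name}.nii.gz")
    meta = {
        "tr": dataset.acquisition.tr,
        "voxel_size": vs,
        "grid_shape": list(dataset.acquisition.grid_shape),
        "run_labels": dataset.run_labels.tolist(),
        "rois": [r.name for r in dataset.rois],
        "runs": [{"n_dummy_volumes": d.n_dummy_volumes, "n_volumes": d.n_volumes,
                  "seed": d.seed} for d in dataset.designs],
    }
    (out / "dataset.json").write_text(json.dumps(meta, indent=2))
    for i, design in enumerate(dataset.designs):
        write_events_tsv(design, out / f"run-{i:02d}_events.tsv")
    return out


def load_dataset(in_dir) -> VoxelDataset:
    src = Path(in_dir)
    meta = json.loads((src / "dataset.json").read_text())
    data, vs = read_nifti(src / "bold.nii.gz")
    acq = AcquisitionParams(tr=meta["tr"], voxel_size=vs,
                            grid_shape=tuple(meta["grid_shape"]))
    rois = []
    for name in meta["rois"]:
        mask, _ = read_nifti(src / f"mask_{name}.nii.gz")
        rois.append(RoiSpec(name, np.argwhere(mask > 0.5)))
    designs = [
        read_events_tsv(src / f"run-{i:02d}_events.tsv", tr=meta["tr"],
                        n_dummy=run["n_dummy_volumes"], n_volumes=run["n_volumes"],
                        seed=run["seed"])
        for i, run in enumerate(meta["runs"])
    ]
    return VoxelDataset(data=np.asarray(data, dtype=float),
                        run_labels=np.asarray(meta["run_labels"], dtype=int),
                        designs=designs, rois=rois, acquisition=acq)


def save_config(config: dict, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config, sort_keys=False))
    return path


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
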