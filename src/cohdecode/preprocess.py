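"""Raw 4D data → decoder-ready samples, plus a minimal univariate GLM.

Pipeline order (asserted in config output): spatial smoothing → per-run
z-scoring → lag-shifted block averaging. Each 19.2 s stimulus block yields
one pattern ("sample"): the mean of its 6 volumes after shifting by one
volume (3.2 s) for haemodynamic lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .simulate import VoxelDataset, canonical_hrf, condition_regressors

PIPELINE_ORDER = ("smooth", "zscore", "extract")
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class SampleSet:
    """One pattern vector per stimulus block — the decoder's currency."""

    patterns: np.ndarray          # (n_samples, n_voxels)
    labels: np.ndarray            # condition label per sample
    run_index: np.ndarray
    block_index: np.ndarray
    voxel_order: np.ndarray       # (n_voxels, 3) ROI voxel coordinates

    def __post_init__(self):
        n = len(self.patterns)
        if not (len(self.labels) == len(self.run_index) == len(self.block_index) == n):
            raise ValueError("sample metadata lengths disagree")

    @property
    def n_samples(self) -> int:
        return len(self.patterns)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels)))

    def subset(self, mask) -> "SampleSet":
        mask = np.asarray(mask)
        return replace(self, patterns=self.patterns[mask], labels=self.labels[mask],
                       run_index=self.run_index[mask], block_index=self.block_index[mask])

    def relabel(self, mapping) -> "SampleSet":
        return replace(self, labels=np.array([mapping[l] for l in self.labels]))

    def to_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.patterns,
                          columns=[f"v{i}" for i in range(self.patterns.shape[1])])
        df.insert(0, "block", self.block_index)
        df.insert(0, "run", self.run_index)
        df.insert(0, "label", self.labels)
        return df


def drop_dummy_volumes(dataset: VoxelDataset) -> VoxelDataset:
    """Remove the leading dummy volumes of each run (T1 equilibration)."""
    keep = np.ones(dataset.data.shape[3], dtype=bool)
    start = 0
    for i, design in enumerate(dataset.designs):
        keep[start:start + design.n_dummy_volumes] = False
        start += design.n_volumes
    if start != dataset.data.shape[3]:
        raise ValueError("designs do not tile the time axis")
    return VoxelDataset(data=dataset.data[..., keep],
                        run_labels=dataset.run_labels[keep],
                        designs=dataset.designs, rois=dataset.rois,
                        acquisition=dataset.acquisition)


def smooth_volumes(data: np.ndarray, fwhm: float, voxel_size: float) -> np.ndarray:
    """Separable 3D Gaussian smoothing of every volume of a 4D array.

    Zero padding with kernel renormalisation at the edges, so constant
    volumes pass through unchanged and an isolated impulse keeps its mass.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return data.copy()
    sigma = fwhm / (voxel_size * FWHM_TO_SIGMA)
    norm = ndimage.gaussian_filter(np.ones(data.shape[:3]), sigma, mode="constant")
    out = ndimage.gaussian_filter(data, sigma=(sigma, sigma, sigma, 0), mode="constant")
    return out / norm[..., None]


def zscore_per_run(data: np.ndarray, run_labels: np.ndarray) -> np.ndarray:
    """Per voxel, per run: mean 0 and (sample) SD 1 over that run's volumes.

    Voxels with zero within-run variance are set to 0 for that run (neutral
    for the correlation classifier) and a warning is issued.
    """
    out = np.empty_like(data, dtype=float)
    for run in np.unique(run_labels):
        m = run_labels == run
        if m.sum() < 2:
            raise ValueError(f"run {run} has fewer than 2 volumes")
        seg = data[..., m]
        mu = seg.mean(axis=-1, keepdims=True)
        sd = seg.std(axis=-1, ddof=1, keepdims=True)
        bad = sd == 0
        if bad.any():
            warnings.warn(f"{int(bad.sum())} zero-variance voxel(s) in run {run}; set to 0")
            sd = np.where(bad, 1.0, sd)
        z = (seg - mu) / sd
        out[..., m] = np.where(bad, 0.0, z)
    return out


def extract_samples(dataset: VoxelDataset, roi_name: str,
                    lag_volumes: int = 1) -> SampleSet:
    """Average each stimulus block's volumes (shifted by ``lag_volumes``)
    into one pattern over the ROI's voxels. Expects dummy-free data."""
    if lag_volumes < 0:
        raise ValueError("lag_volumes must be non-negative")
    roi = dataset.roi(roi_name)
    ts = dataset.roi_timeseries(roi_name)  # (t, n_voxels)

    patterns, labels, runs, blocks = [], [], [], []
    start = 0
    for run_i, design in enumerate(dataset.designs):
        n_run = design.n_retained_volumes
        if (dataset.run_labels[start:start + n_run] != run_i).any():
            raise ValueError("run_labels inconsistent with designs")
        for b, (cond, onset, dur) in enumerate(design.stimulus_blocks):
            i0 = int(round(onset / design.tr)) + lag_volumes
            n_vols = int(round(dur / design.tr))
            if i0 + n_vols > n_run:
                raise ValueError(
                    f"shifted window of block {b} ({cond!r}) in run {run_i} "
                    f"extends past the end of the run")
            patterns.append(ts[start + i0:start + i0 + n_vols].mean(axis=0))
            labels.append(cond)
            runs.append(run_i)
            blocks.append(b)
        start += n_run
    return SampleSet(patterns=np.asarray(patterns), labels=np.asarray(labels),
                     run_index=np.asarray(runs), block_index=np.asarray(blocks),
                     voxel_order=roi.voxel_indices.copy())


def preprocess(dataset: VoxelDataset, fwhm: float = 5.0) -> VoxelDataset:
    """smooth → z-score (dummies dropped first); returns a new dataset."""
    ds = drop_dummy_volumes(dataset)
    data = smooth_volumes(ds.data, fwhm, ds.acquisition.voxel_size)
    data = zscore_per_run(data, ds.run_labels)
    return replace_data(ds, data)


def replace_data(dataset: VoxelDataset, data: np.ndarray) -> VoxelDataset:
    return VoxelDataset(data=data, run_labels=dataset.run_labels,
                        designs=dataset.designs, rois=dataset.rois,
                        acquisition=dataset.acquisition)


@dataclass
class GlmResult:
    betas: np.ndarray                 # (n_regressors, n_voxels)
    regressor_names: tuple[str, ...]
    residual_variance: np.ndarray     # per voxel, df-corrected
    df_residual: int
    design_matrix: np.ndarray

    def contrast(self, weights: dict | np.ndarray) -> np.ndarray:
        """Per-voxel estimate of a named linear combination of betas."""
        if isinstance(weights, dict):
            c = np.zeros(len(self.regressor_names))
            for name, w in weights.items():
                c[self.regressor_names.index(name)] = w
        else:
            c = np.asarray(weights, dtype=float)
        return c @ self.betas


def fit_glm(dataset: VoxelDataset, roi_name: str | None = None,
            hrf: np.ndarray | None = None,
            confounds: np.ndarray | None = None) -> GlmResult:
    """Per-voxel OLS on condition boxcars ⊗ canonical HRF + per-run intercepts.

    Expects dummy-free data (apply :func:`drop_dummy_volumes` first).
    No prewhitening: temporal autocorrelation is left unmodelled.
    """
    tr = dataset.acquisition.tr
    if hrf is None:
        hrf = canonical_hrf(tr)
    labels = tuple(dict.fromkeys(
        c for d in dataset.designs for c, *_ in d.stimulus_blocks))

    X_blocks, names = [], list(labels)
    n_runs = len(dataset.designs)
    for i, design in enumerate(dataset.designs):
        Xc, _ = condition_regressors(design, hrf, labels)
        run_cols = np.zeros((Xc.shape[0], n_runs))
        run_cols[:, i] = 1.0
        X_blocks.append(np.hstack([Xc, run_cols]))
    X = np.vstack(X_blocks)
    names += [f"intercept_run{i}" for i in range(n_runs)]
    if confounds is not None:
        X = np.hstack([X, np.asarray(confounds, dtype=float)])
        names += [f"confound{i}" for i in range(np.asarray(confounds).shape[1])]

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        dep = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-10]
        raise ValueError(f"rank-deficient design matrix; collinear columns: {dep}")

    if roi_name is None:
        Y = dataset.data.reshape(-1, dataset.data.shape[3]).T
    else:
        Y = dataset.roi_timeseries(roi_name)
    if Y.shape[0] != X.shape[0]:
        raise ValueError("design matrix rows do not match the time axis")

    betas, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ betas
    df = X.shape[0] - X.shape[1]
    return GlmResult(betas=betas, regressor_names=tuple(names),
                     residual_variance=(resid ** 2).sum(axis=0) / df,
                     df_residual=df, design_matrix=X)


def context_contrast(result: GlmResult) -> np.ndarray:
    """Per-voxel coherent − incoherent mean-amplitude contrast."""
    c = {}
    for name in result.regressor_names:
        if name.startswith("coh_"):
            c[name] = 0.5
        elif name.startswith("incoh_"):
            c[name] = -0.5
    if len(c) != 4:
        raise ValueError("expected the four direction-by-context regressors")
    return result.contrast(c)
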