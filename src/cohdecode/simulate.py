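"""Forward model for multi-run voxel time series.

The generator embodies the statistical structure the decoding analysis
assumes: every voxel in a stimulated ROI responds to each block with an
amplitude

    a_v(block) = mu_context + s_dir * beta_context * w_v,

where ``w_v`` is a per-voxel direction-preference weight drawn once per
simulated participant (standard normal) and ``s_dir`` is +1 for
anticlockwise and −1 for clockwise drift. ``mu`` sets the mean response
amplitude of a context and ``beta`` the standard deviation of its voxel
direction biases — the two can be varied independently, which is exactly
the dissociation the analysis tests (pattern information without a mean
signal change). The amplitude train is a block boxcar convolved with a
canonical double-gamma HRF; additive noise is temporally AR(1), spatially
independent (spatial correlation enters later through smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy import stats as st

from .stimulus import RunDesign, generate_run_schedule, parse_condition

CONTEXTS = ("coherent", "incoherent")


@dataclass(frozen=True)
class AcquisitionParams:
    tr: float = 3.2            # s
    voxel_size: float = 1.5    # mm, isotropic
    grid_shape: tuple[int, int, int] = (10, 10, 5)

    def __post_init__(self):
        if self.tr <= 0 or self.voxel_size <= 0:
            raise ValueError("tr and voxel_size must be positive")


@dataclass(frozen=True)
class RoiSpec:
    """Named voxel set; ``voxel_indices`` is an (n, 3) integer array."""

    name: str
    voxel_indices: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.voxel_indices, dtype=int)
        if idx.ndim != 2 or idx.shape[1] != 3:
            raise ValueError("voxel_indices must be (n, 3)")
        if len(np.unique(idx, axis=0)) != len(idx):
            raise ValueError(f"duplicate voxels in ROI {self.name!r}")
        object.__setattr__(self, "voxel_indices", idx)

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)

    def flat_indices(self, grid_shape) -> np.ndarray:
        idx = self.voxel_indices
        if (idx < 0).any() or (idx >= np.asarray(grid_shape)).any():
            raise ValueError(f"ROI {self.name!r} exceeds the grid")
        return np.ravel_multi_index(idx.T, grid_shape)

    def mask(self, grid_shape) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=bool)
        m.ravel()[self.flat_indices(grid_shape)] = True
        return m


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters; ``weights`` (per-ROI w_v) is drawn per participant."""

    mu: dict = field(default_factory=lambda: {"coherent": 1.0, "incoherent": 1.0})
    beta: dict = field(default_factory=lambda: {"coherent": 0.06, "incoherent": 0.0})
    noise_sd: float = 1.0
    noise_ar1: float = 0.3
    weights: dict | None = None

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 <= self.noise_ar1 < 1):
            raise ValueError("noise_ar1 must lie in [0, 1)")
        if any(self.beta[c] < 0 for c in CONTEXTS):
            raise ValueError("beta must be non-negative")

    def with_weights(self, rois, rng: np.random.Generator) -> "GroundTruth":
        w = {roi.name: rng.standard_normal(roi.n_voxels) for roi in rois}
        return replace(self, weights=w)


@dataclass
class VoxelDataset:
    """4D voxel data (x, y, z, t) plus run structure and named ROIs."""

    data: np.ndarray
    run_labels: np.ndarray
    designs: list
    rois: list
    acquisition: AcquisitionParams

    def __post_init__(self):
        if self.data.shape[:3] != tuple(self.acquisition.grid_shape):
            raise ValueError("data grid does not match acquisition grid_shape")
        if self.data.shape[3] != len(self.run_labels):
            raise ValueError("run_labels length must equal the time axis")

    @property
    def n_runs(self) -> int:
        return len(self.designs)

    def roi(self, name: str) -> RoiSpec:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(f"no ROI named {name!r}")

    def roi_timeseries(self, name: str) -> np.ndarray:
        """(t, n_voxels) time series for one ROI, in the ROI's voxel order."""
        flat = self.roi(name).flat_indices(self.acquisition.grid_shape)
        nxyz = int(np.prod(self.acquisition.grid_shape))
        return self.data.reshape(nxyz, -1)[flat].T


def canonical_hrf(tr: float, duration: float = 32.0, peak_delay: float = 6.0,
                  undershoot_delay: float = 16.0, peak_disp: float = 1.0,
                  undershoot_disp: float = 1.0, undershoot_ratio: float = 1.0 / 6.0,
                  ) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, sampled at ``tr``.

    Difference of two gamma densities (peak ≈ 5 s, undershoot ≈ 15 s with
    the defaults), scaled to unit peak on the sampled grid; value 0 at t=0.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, duration + 1e-9, tr)
    h = (st.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
         - undershoot_ratio * st.gamma.pdf(t, undershoot_delay / undershoot_disp,
                                           scale=undershoot_disp))
    return h / h.max()


def condition_regressors(design: RunDesign, hrf: np.ndarray | None = None,
                         labels: tuple[str, ...] | None = None) -> tuple[np.ndarray, tuple[str, ...]]:
    """Boxcar-convolved-with-HRF regressor matrix (n_retained_volumes, n_conditions)."""
    if hrf is None:
        hrf = canonical_hrf(design.tr)
    if labels is None:
        labels = tuple(dict.fromkeys(c for c, *_ in design.stimulus_blocks))
    n_t = design.n_retained_volumes
    X = np.zeros((n_t, len(labels)))
    for j, lab in enumerate(labels):
        box = np.zeros(n_t)
        for cond, onset, dur in design.stimulus_blocks:
            if cond == lab:
                i0 = int(round(onset / design.tr))
                box[i0:i0 + int(round(dur / design.tr))] = 1.0
        X[:, j] = np.convolve(box, hrf)[:n_t]
    return X, labels


def _ar1_noise(rng: np.random.Generator, n_t: int, n_vox: int,
               sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) Gaussian noise, variance sd² per voxel."""
    e = rng.standard_normal((n_t, n_vox)) * sd * np.sqrt(1.0 - phi ** 2)
    e[0] = rng.standard_normal(n_vox) * sd
    if phi == 0:
        return e
    return sps.lfilter([1.0], [1.0, -phi], e, axis=0)


def _check_disjoint(rois, grid_shape):
    seen = {}
    for roi in rois:
        for f in roi.flat_indices(grid_shape):
            if f in seen:
                raise ValueError(f"ROIs {seen[f]!r} and {roi.name!r} overlap")
            seen[f] = roi.name


def simulate_run(design: RunDesign, truth: GroundTruth, rois,
                 acquisition: AcquisitionParams, seed) -> VoxelDataset:
    """Simulate one run; dummy volumes carry noise only."""
    if truth.weights is None:
        raise ValueError("truth.weights missing; draw them with GroundTruth.with_weights")
    for cond, *_ in design.stimulus_blocks:
        parse_condition(cond)
    _check_disjoint(rois, acquisition.grid_shape)

    rng = np.random.default_rng(seed)
    grid = acquisition.grid_shape
    n_vox = int(np.prod(grid))
    n_total = design.n_volumes
    n_dummy = design.n_dummy_volumes

    X, labels = condition_regressors(design)
    # amplitude matrix A[condition, voxel] per ROI
    data = _ar1_noise(rng, n_total, n_vox, truth.noise_sd, truth.noise_ar1)
    for roi in rois:
        w = truth.weights[roi.name]
        if len(w) != roi.n_voxels:
            raise ValueError(f"weight length mismatch for ROI {roi.name!r}")
        A = np.empty((len(labels), roi.n_voxels))
        for j, lab in enumerate(labels):
            context, sign = parse_condition(lab)
            A[j] = truth.mu[context] + sign * truth.beta[context] * w
        data[n_dummy:, roi.flat_indices(grid)] += X @ A

    return VoxelDataset(data=np.ascontiguousarray(data.T.reshape(grid + (n_total,))),
                        run_labels=np.zeros(n_total, dtype=int),
                        designs=[design], rois=list(rois), acquisition=acquisition)


def simulate_participant(n_runs: int = 8, truth: GroundTruth | None = None,
                         rois=None, acquisition: AcquisitionParams | None = None,
                         seed=0, schedule_kwargs: dict | None = None) -> VoxelDataset:
    """Concatenate ``n_runs`` independent runs sharing one draw of the
    per-voxel direction weights (one simulated participant)."""
    if n_runs < 2:
        raise ValueError("need at least 2 runs for leave-one-run-out CV")
    acquisition = acquisition or AcquisitionParams()
    rois = rois if rois is not None else default_rois(acquisition.grid_shape)
    truth = truth or GroundTruth()

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    weight_seed, *run_seeds = ss.spawn(1 + n_runs)
    if truth.weights is None:
        truth = truth.with_weights(rois, np.random.default_rng(weight_seed))

    kw = dict(tr=acquisition.tr)
    kw.update(schedule_kwargs or {})
    runs = []
    for i, rs in enumerate(run_seeds):
        child = rs.spawn(2)
        sched_seed = int(np.random.default_rng(child[0]).integers(2 ** 31))
        design = generate_run_schedule(rng_seed=sched_seed, **kw)
        runs.append(simulate_run(design, truth, rois, acquisition, child[1]))

    data = np.concatenate([r.data for r in runs], axis=3)
    run_labels = np.concatenate([np.full(r.data.shape[3], i, dtype=int)
                                 for i, r in enumerate(runs)])
    return VoxelDataset(data=data, run_labels=run_labels,
                        designs=[r.designs[0] for r in runs],
                        rois=list(rois), acquisition=acquisition)


def default_rois(grid_shape=(10, 10, 5)) -> list[RoiSpec]:
    """Default disjoint ROI layout on the simulation grid.

    Two 200-voxel visual-field-quadrant ROIs (curve and distractor
    quadrants; the 150-voxel cutoff must be reachable) and two 50-voxel
    single-element ROIs (decoded with the 28-voxel cutoff).
    """
    nx, ny, nz = grid_shape
    if nx < 10 or ny < 10 or nz < 5:
        raise ValueError("default layout needs a grid of at least 10x10x5")

    def box(xs, ys, zs):
        g = np.mgrid[xs[0]:xs[1], ys[0]:ys[1], zs[0]:zs[1]]
        return g.reshape(3, -1).T

    return [
        RoiSpec("quadrant_curve", box((0, 5), (0, 8), (0, 5))),
        RoiSpec("quadrant_distractor", box((5, 10), (0, 8), (0, 5))),
        RoiSpec("element_curve", box((0, 5), (8, 10), (0, 5))),
        RoiSpec("element_distractor", box((5, 10), (8, 10), (0, 5))),
    ]
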