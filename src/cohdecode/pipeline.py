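"""End-to-end seeded pipeline: simulate → preprocess → decode → stats.

A single master seed deterministically spawns per-participant seeds via
``numpy.random.SeedSequence(master_seed).spawn(n_participants)``; each
participant seed in turn spawns per-run schedule and noise streams, so any
participant can be re-simulated in isolation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding, preprocess, stats
from .simulate import AcquisitionParams, GroundTruth, default_rois, simulate_participant

PIPELINE_VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    n_participants: int = 9
    n_runs: int = 8
    seed: int = 0
    fwhm: float = 5.0
    lag_volumes: int = 1
    mu_coherent: float = 1.0
    mu_incoherent: float = 1.0
    beta_coherent: float = 0.06
    beta_incoherent: float = 0.0
    noise_sd: float = 1.0
    noise_ar1: float = 0.3
    tr: float = 3.2
    voxel_size: float = 1.5
    grid_shape: tuple = (10, 10, 5)
    roi_names: tuple = ("quadrant_curve",)
    comparisons: tuple = decoding.COMPARISONS
    alpha: float = 0.05
    pipeline_order: tuple = preprocess.PIPELINE_ORDER

    def ground_truth(self) -> GroundTruth:
        return GroundTruth(
            mu={"coherent": self.mu_coherent, "incoherent": self.mu_incoherent},
            beta={"coherent": self.beta_coherent, "incoherent": self.beta_incoherent},
            noise_sd=self.noise_sd, noise_ar1=self.noise_ar1)

    def acquisition(self) -> AcquisitionParams:
        return AcquisitionParams(tr=self.tr, voxel_size=self.voxel_size,
                                 grid_shape=tuple(self.grid_shape))


def participant_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(master_seed).spawn(n)


def analyse_participant(config: PipelineConfig, seed) -> dict:
    """Simulate and analyse one participant; returns tidy pieces."""
    ds = simulate_participant(
        n_runs=config.n_runs, truth=config.ground_truth(),
        rois=default_rois(tuple(config.grid_shape)),
        acquisition=config.acquisition(), seed=seed)
    pp = preprocess.preprocess(ds, fwhm=config.fwhm)

    acc = decoding.run_decoding_suite(pp, roi_names=list(config.roi_names),
                                      comparisons=config.comparisons,
                                      lag_volumes=config.lag_volumes)

    glm = preprocess.fit_glm(pp, roi_name=config.roi_names[0])
    contrast = float(preprocess.context_contrast(glm).mean())

    samples = preprocess.extract_samples(pp, config.roi_names[0],
                                         lag_volumes=config.lag_volumes)
    bias = {
        ctx: stats.proportion_biased(stats.voxel_bias_map(samples, ctx), config.alpha)
        for ctx in ("coherent", "incoherent")
    }
    return {"accuracy": acc, "context_contrast": contrast, "bias_proportions": bias}


def run_full_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Simulate a cohort and run the full analysis suite.

    Returns (and optionally writes) the per-participant accuracy table,
    group tests vs. chance per comparison, the group GLM context contrast,
    and bias-map proportions, plus a provenance manifest.
    """
    seeds = participant_seeds(config.seed, config.n_participants)
    acc_tables, contrasts, bias_rows = [], [], []
    for p, seed in enumerate(seeds):
        res = analyse_participant(config, seed)
        t = res["accuracy"].copy()
        t.insert(0, "participant", p)
        acc_tables.append(t)
        contrasts.append(res["context_contrast"])
        for ctx, prop in res["bias_proportions"].items():
            bias_rows.append({"participant": p, "context": ctx, "proportion": prop})

    accuracy = pd.concat(acc_tables, ignore_index=True)
    per_participant = (accuracy
                       .groupby(["participant", "roi", "comparison"], as_index=False)
                       ["accuracy"].mean())

    group_tests = []
    for (roi, comp), grp in per_participant.groupby(["roi", "comparison"]):
        r = stats.one_sample_t_vs_chance(grp["accuracy"].to_numpy(), chance=0.5)
        group_tests.append({"roi": roi, "comparison": comp,
                            "mean_accuracy": float(grp["accuracy"].mean()),
                            "t": r.statistic, "df": r.df, "p_one_tailed": r.p,
                            "significant": bool(r.p < config.alpha)})
    group = pd.DataFrame(group_tests)

    contrast_test = stats.one_sample_t_vs_chance(np.asarray(contrasts), chance=0.0,
                                                 tail="two-sided")
    bias = pd.DataFrame(bias_rows)

    results = {
        "accuracy": accuracy,
        "per_participant_accuracy": per_participant,
        "group_tests": group,
        "glm_context_contrast": {
            "mean": float(np.mean(contrasts)), "t": contrast_test.statistic,
            "df": contrast_test.df, "p_two_sided": contrast_test.p},
        "bias_proportions": bias,
        "manifest": {
            "config": asdict(config),
            "pipeline_version": PIPELINE_VERSION,
            "pipeline_order": list(config.pipeline_order),
            "n_participants": config.n_participants,
            "master_seed": config.seed,
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        accuracy.to_csv(out / "accuracy_per_fold.tsv", sep="\t", index=False)
        per_participant.to_csv(out / "accuracy_per_participant.tsv", sep="\t", index=False)
        group.to_csv(out / "group_tests.tsv", sep="\t", index=False)
        bias.to_csv(out / "bias_proportions.tsv", sep="\t", index=False)

        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, (tuple, np.ndarray)):
                return list(o)
            raise TypeError(type(o))

        (out / "manifest.json").write_text(
            json.dumps({**results["manifest"],
                        "glm_context_contrast": results["glm_context_contrast"]},
                       indent=2, default=_default))
    return results
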