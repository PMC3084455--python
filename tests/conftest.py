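import numpy as np
import pytest

from cohdecode import preprocess as pp
from cohdecode.simulate import GroundTruth, simulate_participant


@pytest.fixture(scope="session")
def default_participant():
    """One simulated participant with the default ground truth (coherent
    direction bias present, no mean-amplitude difference), preprocessed."""
    ds = simulate_participant(seed=42)
    return pp.preprocess(ds, fwhm=5.0)


@pytest.fixture(scope="session")
def null_participant():
    """One participant with no direction bias anywhere (beta = 0)."""
    truth = GroundTruth(beta={"coherent": 0.0, "incoherent": 0.0})
    ds = simulate_participant(truth=truth, seed=43)
    return pp.preprocess(ds, fwhm=5.0)


@pytest.fixture(scope="session")
def null_simulations():
    """Null-calibration Monte Carlo shared by the acceptance tests.

    200 participants simulated with beta = 0 everywhere; for each, coherent-
    and incoherent-context direction decoding from the curve-quadrant ROI
    with the 150-voxel cutoff, once with nested (training-only) voxel
    selection and once with the deliberately biased variant that ranks
    voxels on all runs.
    """
    from cohdecode import decoding

    rows = {"nested": [], "peeking": []}
    truth = GroundTruth(beta={"coherent": 0.0, "incoherent": 0.0})
    for s in range(200):
        ds = simulate_participant(truth=truth, seed=100_000 + s)
        d = pp.preprocess(ds, fwhm=5.0)
        samples = pp.extract_samples(d, "quadrant_curve")
        for sel in rows:
            accs = [
                decoding.decode_comparison(samples, comp, 150, selection=sel).mean_accuracy
                for comp in ("direction_coherent", "direction_incoherent")
            ]
            rows[sel].append(np.mean(accs))
    return {k: np.asarray(v) for k, v in rows.items()}
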