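import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pairswitch as ps

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_ensemble():
    """A quick, fully classified synthetic ensemble (two temperatures)."""
    config = ps.GeneratorConfig(
        temperatures_K=(530.0, 580.0), total_time_ns=50.0, seed=7
    )
    return ps.simulate_ensemble(config)


@pytest.fixture(scope="session")
def scaled_study():
    """The scaled-down study: 4 temperatures, 400 ns each, full pipeline.

    Returns the generator config, the ensemble, per-temperature state
    sequences/statistics, the van't Hoff fit and ground-truth frame
    agreement; shared by the recovery and self-consistency tests.
    """
    config = ps.GeneratorConfig(total_time_ns=400.0, seed=1)
    ensemble = ps.simulate_ensemble(config)
    per_T = {}
    agreement = {}
    points = []
    for T in ensemble.temperatures():
        run = ensemble[T]
        seq = ps.classify_trajectory(run.trajectory)
        segs = ps.segment(seq)
        occ = ps.occupancy(segs, seq.total_time_ns)
        lifetimes = ps.mean_lifetimes(segs, n_boot=200, seed=2)
        tpt = ps.transition_path_times(segs, n_boot=200, seed=3)
        truth = run.path.frame_labels(config.frame_dt_ps)
        agreement[T] = float((seq.labels == truth).mean())
        per_T[T] = {
            "seq": seq,
            "segments": segs,
            "occupancy": occ,
            "lifetimes": lifetimes,
            "tpt": tpt,
        }
        points.append((T, occ.p_a, occ.p_d))
    thermo = ps.vant_hoff_fit(points)
    return {
        "config": config,
        "ensemble": ensemble,
        "per_T": per_T,
        "agreement": agreement,
        "thermo": thermo,
    }
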