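import numpy as np
import pytest

from memassoc import (
    AnalysisParams,
    SimConfig,
    Topology,
    Trajectory,
    analyze_trajectory,
    run_ensemble,
    subsample_frames,
)
from memassoc.model import Frame


@pytest.fixture
def params():
    return AnalysisParams()


@pytest.fixture
def small_cfg():
    """Desk-scale membrane patch at the default areal lipid density."""
    return SimConfig(n_lipids=100, box=(5.5, 5.5, 17.0), n_frames=120)


def make_trajectory(coords_per_frame, box, bead_names, residue_indices,
                    residue_names, groups, times=None):
    """Hand-build a trajectory from explicit coordinates."""
    n = len(bead_names)
    top = Topology(bead_names, residue_indices, residue_names, groups, list(range(n)))
    if times is None:
        times = [2.0 * (i + 1) for i in range(len(coords_per_frame))]
    frames = [
        Frame(time=t, box=np.asarray(box, float), coords=np.asarray(c, float))
        for t, c in zip(times, coords_per_frame)
    ]
    return Trajectory(topology=top, frames=frames)


@pytest.fixture(scope="session")
def anchored_ensemble_small():
    """Shared small anchored ensemble with its analysis records."""
    cfg = SimConfig(n_lipids=100, box=(5.5, 5.5, 17.0), n_frames=200)
    params = AnalysisParams()
    trajs, logs = run_ensemble(cfg, 8, 42)
    sub = [subsample_frames(t, params.frame_interval) for t in trajs]
    recs = [
        analyze_trajectory(t, params, trajectory_id=g.trajectory_id)
        for t, g in zip(sub, logs)
    ]
    return sub, recs, logs, params
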