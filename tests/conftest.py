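import math
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from wormstate.behavior_decoder import WormTrack


def make_scripted_track(script, fps=2.0, forward_speed=30.0, backward_speed=28.0,
                        heading_sd_deg=3.0, seed=None):
    """Build a WormTrack from a list of (state, duration_s) segments with
    scripted kinematics: forward along a drifting heading, backward along
    its reverse, stationary jitter, omega drift + reorientation."""
    rng = np.random.default_rng(seed) if seed is not None else None
    pos = [np.zeros(2)]
    omega = []
    truth = []
    h = 0.0 if rng is None else rng.uniform(0, 2 * math.pi)
    for state, dur in script:
        nf = max(1, int(round(dur * fps)))
        for _ in range(nf):
            if state == "forward":
                if rng is not None:
                    h += rng.normal(0, math.radians(heading_sd_deg))
                step = forward_speed / fps * np.array([math.cos(h), math.sin(h)])
            elif state == "backward":
                step = -backward_speed / fps * np.array([math.cos(h), math.sin(h)])
            elif state == "stationary":
                step = (rng.normal(0, 0.2, 2) if rng is not None else np.zeros(2))
            else:  # omega
                ang = rng.uniform(0, 2 * math.pi) if rng is not None else 0.0
                step = 2.0 / fps * np.array([math.cos(ang), math.sin(ang)])
            truth.append(state)
            omega.append(state == "omega")
            pos.append(pos[-1] + step)
        if state == "omega":
            h += (rng.uniform(math.radians(90), math.radians(150))
                  if rng is not None else math.radians(120))
    pos = np.asarray(pos[:-1])
    n = len(pos)
    track = WormTrack(
        times=np.arange(n) / fps,
        centroids=pos,
        fps=fps,
        omega_flags=np.asarray(omega, bool),
    )
    return track, np.asarray(truth, object)


@pytest.fixture(scope="session")
def small_movie():
    """One mixed-schedule synthetic movie shared across tests."""
    from wormstate.synthetic_data import StateSchedule, gen_worm_movie

    schedule = StateSchedule(
        [
            ("forward", 12.0),
            ("backward", 3.0),
            ("omega", 2.0),
            ("forward", 10.0),
            ("stationary", 4.0),
            ("forward", 8.0),
        ]
    )
    return gen_worm_movie(schedule, seed=42)


@pytest.fixture(scope="session")
def clean_stack():
    """Wandering-spot two-channel stack at high SNR with a stage log."""
    from wormstate.synthetic_data import gen_imaging_stack, smooth_random_path

    path = smooth_random_path(120, step_px=4.0, seed=5)
    return gen_imaging_stack(path, 0.6, noise_sd=2.0, seed=6)
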