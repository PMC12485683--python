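import numpy as np
import pandas as pd
import pytest

from replidyn.io_bed import ForkRecord
from replidyn.simulate import SimulationConfig, simulate_dataset


def make_fork(chrom="chr1", direction="R", edu=(10_000, 17_000), brdu=(17_000, 32_000),
              read=(5_000, 40_000), stall_score=0.5, read_id="r0", strand="+"):
    """Hand-built fork record; BrdU 3' of EdU for R forks, mirrored for L."""
    if direction == "L":
        edu, brdu = edu, brdu
    return ForkRecord(
        chrom=chrom,
        fork_start=min(edu[0], brdu[0]), fork_end=max(edu[1], brdu[1]),
        read_id=read_id, read_start=read[0], read_end=read[1],
        direction=direction, strand=strand,
        edu_start=edu[0], edu_end=edu[1], brdu_start=brdu[0], brdu_end=brdu[1],
        stall_score=stall_score)


@pytest.fixture(scope="session")
def default_sim():
    """Default toy-genome simulation (2 x 5 Mb) with standard defect rates."""
    cfg = SimulationConfig(seed=11)
    return cfg, simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """No injected defects, negligible speed noise: exact kinematics checks."""
    cfg = SimulationConfig(
        seed=3,
        per_state_fork_speed={s: 1000.0 for s in range(10)},
        speed_noise_sd=0.0,
        stall_code_rates={-1: 0.0, -2: 0.0, -3: 0.0, -4: 0.0},
        truncation_rate=0.0,
        origin_rate_per_bp=1.0 / 200_000,
        origin_rate_timing_multiplier={g: 1.0 for g in range(4)},
    )
    return cfg, simulate_dataset(cfg)


@pytest.fixture(scope="session")
def toy_genome():
    return {"chrA": 1_000_000, "chrB": 600_000}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_intervals(rng, genome, n, min_len=500, max_len=20_000):
    chroms = list(genome)
    rows = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, genome[c] - length))
        rows.append((c, start, start + length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
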