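import math

import numpy as np
import pytest

from virextend import SimConfig, make_genome, simulate_reads


@pytest.fixture(scope="session")
def circ12():
    """12 kb circular genome with error-free paired 30x reads."""
    cfg = SimConfig(genome_length=12000, circular=True, seed=3, error_rate=0.0)
    genome = make_genome(cfg)
    return cfg, genome, simulate_reads(genome, cfg)


@pytest.fixture(scope="session")
def lin10():
    """10 kb linear genome with error-free paired 30x reads."""
    cfg = SimConfig(genome_length=10000, circular=False, seed=5, error_rate=0.0)
    genome = make_genome(cfg)
    return cfg, genome, simulate_reads(genome, cfg)


def brute_force_suspicious(depth, lower_pct=15.0, upper_pct=85.0, min_len=1000):
    """Independent oracle: nearest-rank percentile bounds + per-base compare +
    run-length filter, all by direct enumeration."""
    n = len(depth)
    s = sorted(depth)
    lo = s[max(1, math.ceil(lower_pct / 100.0 * n)) - 1]
    up = s[max(1, math.ceil(upper_pct / 100.0 * n)) - 1]
    mask = [(d < lo or d > up or d == 0) for d in depth]
    regions = []
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i > min_len:
                regions.append((i, j))
            i = j
        else:
            i += 1
    return regions


@pytest.fixture(scope="session")
def coverage_oracle():
    return brute_force_suspicious


def random_profile(rng):
    """A random depth profile mixing flat coverage, noise, dips and zero blocks."""
    n = int(rng.integers(200, 5001))
    kind = rng.integers(0, 4)
    if kind == 0:
        depth = np.full(n, int(rng.integers(0, 100)))
    elif kind == 1:
        depth = rng.poisson(rng.uniform(1, 80), size=n)
    else:
        depth = rng.poisson(40, size=n)
        for _ in range(int(rng.integers(1, 4))):
            w = int(rng.integers(1, max(2, n // 2)))
            s = int(rng.integers(0, n - w + 1))
            depth[s : s + w] = rng.integers(0, 5) if kind == 2 else rng.integers(100, 200)
    return depth.astype(np.int64)
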