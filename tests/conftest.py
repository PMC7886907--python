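import numpy as np
import pandas as pd
import pytest

from loopcomp import SyntheticConfig, generate_labels, generate_sites
from loopcomp.model import ModelParams


def make_sites(positions, orientations, xs, chrom="chr1"):
    """Minimal site table from parallel lists."""
    positions = list(positions)
    return pd.DataFrame(
        {
            "site_id": [f"s{k}" for k in range(len(positions))],
            "chrom": chrom,
            "peak_start": [p - 100 for p in positions],
            "peak_end": [p + 100 for p in positions],
            "pos": positions,
            "orientation": list(orientations),
            "signal_raw": list(xs),
            "x": list(xs),
        }
    )


def dense_fixed_point(left, right, q, s=0.0, b=0.5, tol=1e-12, p0=None, max_iter=100_000):
    """Independent damped fixed-point oracle with explicit O(P^2) overlap products."""
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    q = np.asarray(q, float)
    n = len(q)
    p = q.copy() if p0 is None else np.asarray(p0, float).copy()
    for _ in range(max_iter):
        fresh = np.empty(n)
        for i in range(n):
            f = 1.0
            for m in range(n):
                if m != i and left[m] < right[i] and left[i] < right[m]:
                    f *= 1.0 - (1.0 - s) * p[m]
            fresh[i] = q[i] * f
        p_next = (fresh + b * p) / (1.0 + b)
        if np.max(np.abs(p_next - p)) < tol:
            return p_next
        p = p_next
    raise RuntimeError("dense oracle did not converge")


@pytest.fixture(scope="session")
def default_landscape():
    """The default-scale synthetic landscape with Bernoulli labels (seeded)."""
    cfg = SyntheticConfig(seed=11)
    sites = generate_sites(cfg)
    pairs = generate_labels(sites, cfg)
    return cfg, sites, pairs


@pytest.fixture(scope="session")
def small_landscape():
    """One 500-site chromosome, cheap enough for iterative-LC tests."""
    cfg = SyntheticConfig(seed=7, n_chromosomes=1, n_sites=500, chrom_length=13_000_000)
    sites = generate_sites(cfg)
    return cfg, sites


@pytest.fixture
def no_decay_params():
    return ModelParams(a=8.5, w=3.0, lam=None, decay_kind="none")
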