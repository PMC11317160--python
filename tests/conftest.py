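"""Shared fixtures: small tracks, tetrads, and simulated datasets."""

import numpy as np
import pytest

from forkrestart import (
    AnalysisWindows,
    CountTetrad,
    SimConfig,
    Track,
    UsageTracks,
)


@pytest.fixture
def small_track():
    return Track(ref_name="chrS", bin_width=50, start=0, values=[3.0, 7.0, 1.0, 4.0])


@pytest.fixture
def default_windows():
    return AnalysisWindows.default(30_000)


def make_tetrad(d_w, d_c, e_w, e_c, bin_width=50, start=0):
    mk = lambda v: Track(ref_name="chrS", bin_width=bin_width, start=start, values=v)
    return CountTetrad(d_watson=mk(d_w), d_crick=mk(d_c), e_watson=mk(e_w), e_crick=mk(e_c))


def mixture_usage(r: float, n_bins: int = 1200, bin_width: int = 50,
                  barrier_bin: int = 600) -> UsageTracks:
    """Noiseless usage for an r : (1-r) mix of restarted and canonical forks.

    Upstream of the barrier all forks move rightward canonically
    (Watson = epsilon, Crick = delta). Downstream, a fraction r of cells
    carry a delta/delta restarted fork while the rest keep bias 0.5.
    """
    u_w = np.zeros(n_bins)           # canonical rightward: Pol delta usage 0 on Watson
    u_c = np.ones(n_bins)            # ... and 1 on Crick
    u_w[barrier_bin:] = r * 1.0      # restarted cells put delta on Watson too
    u_c[barrier_bin:] = r * 1.0 + (1 - r) * 1.0  # delta stays delta on Crick
    mk = lambda v: Track(ref_name="chrS", bin_width=bin_width, start=0, values=v)
    return UsageTracks(
        u_delta_watson=mk(u_w),
        u_delta_crick=mk(u_c),
        u_epsilon_watson=mk(1.0 - u_w),
        u_epsilon_crick=mk(1.0 - u_c),
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated dataset at generator defaults (cached for the session)."""
    from forkrestart import sample_counts, simulate_locus

    cfg = SimConfig(seed=1)
    prov = simulate_locus(cfg)
    tetrad = sample_counts(prov, cfg)
    return cfg, prov, tetrad
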