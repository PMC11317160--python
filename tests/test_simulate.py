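"""Replication simulator: kinematics, provenance, counts, dataset output."""

import json

import numpy as np
import pytest

from forkrestart import (
    ConfigError,
    SimConfig,
    SimulationError,
    bias_to_restart_fraction,
    generate_dataset,
    load_tetrad,
    sample_counts,
    simulate_cell,
    simulate_locus,
)
from forkrestart.simulate import POL_DELTA, POL_EPSILON


def det_cfg(**kw):
    """Deterministic firing times (sd=0), no noise unless overridden."""
    base = dict(
        seed=0,
        origins=((5_000, 10.0, 0.0), (55_000, 50.0, 0.0)),
        background=0.0,
        n_cells=1,
    )
    base.update(kw)
    return SimConfig(**base)


def phi_at(track, pos):
    return track.values[track.bin_index(pos)]


class TestSimulateCell:
    def test_barrier_off_is_purely_directional(self):
        cfg = det_cfg(p_block=0.0)
        w, c, arrested, restarted = simulate_cell(cfg, np.random.default_rng(0))
        assert not arrested and not restarted
        assert (w >= 0).all() and (c >= 0).all()
        # rightward forks meet leftward at 50 kb; left flank is leftward-replicated
        idx = lambda pos: int(pos // cfg.bin_width)
        assert (w[idx(6_000):idx(49_000)] == POL_EPSILON).all()
        assert (c[idx(6_000):idx(49_000)] == POL_DELTA).all()
        assert (w[idx(0):idx(4_900)] == POL_DELTA).all()
        assert (w[idx(51_000):idx(54_900)] == POL_DELTA).all()
        assert (w[idx(56_000):] == POL_EPSILON).all()

    def test_forced_instant_restart_is_delta_delta_downstream(self):
        cfg = det_cfg(p_block=1.0, p_restart=1.0, restart_delay=0.0, resection_len=0)
        w, c, arrested, restarted = simulate_cell(cfg, np.random.default_rng(0))
        assert arrested and restarted
        idx = lambda pos: int(pos // cfg.bin_width)
        # restarted delta/delta synthesis runs from the barrier to the
        # meeting point with the converging fork (50 kb here)
        assert (w[idx(30_100):idx(49_900)] == POL_DELTA).all()
        assert (c[idx(30_100):idx(49_900)] == POL_DELTA).all()
        assert (c[idx(51_000):idx(54_000)] == POL_EPSILON).all()

    def test_no_restart_leaves_downstream_to_converging_fork(self):
        cfg = det_cfg(p_block=1.0, p_restart=0.0)
        w, c, arrested, restarted = simulate_cell(cfg, np.random.default_rng(0))
        assert arrested and not restarted
        idx = lambda pos: int(pos // cfg.bin_width)
        # everything right of the barrier is leftward-canonical:
        # Watson = delta, Crick = epsilon (the Crick Pol eps signature)
        assert (w[idx(30_100):idx(54_900)] == POL_DELTA).all()
        assert (c[idx(30_100):idx(54_900)] == POL_EPSILON).all()

    def test_resection_resynthesized_delta_delta(self):
        cfg = det_cfg(p_block=1.0, p_restart=1.0, resection_len=1_000)
        w, c, _, restarted = simulate_cell(cfg, np.random.default_rng(0))
        assert restarted
        idx = lambda pos: int(pos // cfg.bin_width)
        # the 1 kb behind the barrier is re-synthesized by the restarted fork
        assert (w[idx(29_100):idx(29_900)] == POL_DELTA).all()
        assert (c[idx(29_100):idx(29_900)] == POL_DELTA).all()
        # further upstream stays canonical rightward
        assert (w[idx(25_000):idx(28_900)] == POL_EPSILON).all()

    def test_polar_barrier_ignores_leftward_forks(self):
        # single origin right of the barrier: its leftward fork must cross
        # the barrier unimpeded (otherwise the left half stays unreplicated)
        cfg = det_cfg(p_block=1.0, p_restart=0.0, origins=((55_000, 10.0, 0.0),))
        w, c, arrested, _ = simulate_cell(cfg, np.random.default_rng(0))
        assert not arrested
        assert (w[: int(54_000 // cfg.bin_width)] == POL_DELTA).all()

    def test_every_bin_assigned_on_both_strands(self):
        cfg = SimConfig(seed=3, n_cells=1)
        for i in range(25):
            w, c, _, _ = simulate_cell(cfg, np.random.default_rng(i))
            assert (w >= 0).all() and (c >= 0).all()

    def test_unrescuable_arrest_reports_uncovered_interval(self):
        cfg = det_cfg(p_block=1.0, p_restart=0.0, origins=((5_000, 10.0, 0.0),))
        with pytest.raises(SimulationError, match="unreplicated"):
            simulate_cell(cfg, np.random.default_rng(0))


class TestSimulateLocus:
    def test_single_cell_summary_is_indicator(self):
        prov = simulate_locus(det_cfg(seed=5))
        vals = prov.phi_delta_watson.values
        assert set(np.unique(vals)) <= {0.0, 1.0}

    def test_strand_conservation(self, default_dataset):
        _, prov, _ = default_dataset
        np.testing.assert_allclose(
            prov.phi_delta_watson.values + prov.phi_epsilon_watson.values, 1.0)
        np.testing.assert_allclose(
            prov.phi_delta_crick.values + prov.phi_epsilon_crick.values, 1.0)

    def test_restart_bookkeeping_matches_binomial_rates(self, default_dataset):
        cfg, prov, _ = default_dataset
        n = cfg.n_cells
        sd_arrest = np.sqrt(cfg.p_block * (1 - cfg.p_block) / n)
        assert abs(prov.n_arrested / n - cfg.p_block) < 3 * sd_arrest
        sd_cond = np.sqrt(cfg.p_restart * (1 - cfg.p_restart) / prov.n_arrested)
        assert abs(prov.conditional_restart_fraction - cfg.p_restart) < 3 * sd_cond
        pr = cfg.p_block * cfg.p_restart
        sd_unc = np.sqrt(pr * (1 - pr) / n)
        assert abs(prov.realized_restart_fraction - pr) < 3 * sd_unc

    def test_seed_determinism(self):
        cfg = SimConfig(seed=9, n_cells=50)
        a = simulate_locus(cfg)
        b = simulate_locus(cfg)
        np.testing.assert_array_equal(a.phi_delta_watson.values, b.phi_delta_watson.values)
        assert a.n_restarted == b.n_restarted

    @pytest.mark.parametrize("r", [0.0, 0.6, 1.0])
    def test_analytic_bias_limit_immediately_downstream(self, r):
        # deterministic firing, forced arrest, instant restart at full
        # speed: expected bias just past the barrier is 0.5 + 0.5 r, and
        # the mapping recovers r
        cfg = det_cfg(p_block=1.0, p_restart=r, restart_delay=0.0,
                      resection_len=0, n_cells=1_500)
        prov = simulate_locus(cfg)
        b = 0.5 * (phi_at(prov.phi_delta_watson, 31_000)
                   + phi_at(prov.phi_delta_crick, 31_000))
        sd = np.sqrt(max(r * (1 - r), 1e-9) / cfg.n_cells)
        assert abs(b - (0.5 + 0.5 * r)) <= 3 * 0.5 * sd + 1e-9
        assert bias_to_restart_fraction(b, 0.5) == pytest.approx(r, abs=3 * sd + 1e-9)


class TestSampleCounts:
    def test_zero_depth_gives_zero_counts(self, default_dataset):
        cfg, prov, _ = default_dataset
        cfg0 = SimConfig(**{**cfg.to_dict(), "depth": 1e-12})
        tet = sample_counts(prov, cfg0)
        assert tet.d_watson.values.sum() == 0

    def test_pure_delta_bin_silences_epsilon_library(self):
        cfg = det_cfg(p_block=1.0, p_restart=1.0, restart_delay=0.0,
                      resection_len=0, depth=200.0)
        prov = simulate_locus(cfg)
        tet = sample_counts(prov, cfg)
        i = tet.e_watson.bin_index(35_000)  # delta/delta region, beta = 0
        assert tet.e_watson.values[i] == 0
        assert tet.e_crick.values[i] == 0

    def test_law_of_large_numbers_at_high_depth(self, default_dataset):
        cfg, prov, _ = default_dataset
        cfg_hi = SimConfig(**{**cfg.to_dict(), "depth": 10_000.0, "background": 0.0})
        tet = sample_counts(prov, cfg_hi)
        rel = np.abs(tet.d_watson.values / cfg_hi.depth - prov.phi_delta_watson.values)
        denom = np.maximum(prov.phi_delta_watson.values, 1e-2)
        assert np.mean(rel / denom) < 3 / np.sqrt(cfg_hi.depth)


class TestGenerateDataset:
    def test_outputs_and_byte_determinism(self, tmp_path):
        cfg = SimConfig(seed=21, n_cells=120)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        m1 = generate_dataset(cfg, d1)
        generate_dataset(cfg, d2)
        names = sorted(p.name for p in d1.iterdir())
        assert "manifest.json" in names and "truth.json" in names
        assert sum(n.startswith("counts_") for n in names) == 4
        assert sum(n.startswith("phi_") for n in names) == 4
        for name in names:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
        # a different seed changes counts but not the binning
        d3 = tmp_path / "c"
        generate_dataset(SimConfig(seed=22, n_cells=120), d3)
        assert (d1 / "counts_delta_watson.bedgraph").read_bytes() != \
               (d3 / "counts_delta_watson.bedgraph").read_bytes()
        tet1 = load_tetrad({k: str(d1 / v) for k, v in m1["roles"].items()},
                           bin_width=cfg.bin_width)
        tet3 = load_tetrad({k: str(d3 / v) for k, v in m1["roles"].items()},
                           bin_width=cfg.bin_width)
        assert tet1.d_watson.n_bins == tet3.d_watson.n_bins
        truth = json.loads((d1 / "truth.json").read_text())
        assert 0.0 <= truth["realized_restart_fraction"] <= 1.0

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            SimConfig(seed=0, p_block=1.5)
        with pytest.raises(ConfigError):
            SimConfig(seed=0, barrier_pos=70_000)
        with pytest.raises(ConfigError):
            SimConfig.from_dict({"seed": 0, "no_such_key": 1})
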