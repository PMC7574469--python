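"""ΔF/F, responsiveness gating, and SU/SD modulation identities."""

import numpy as np
import pytest

from visiomod import synthetic, twophoton
from visiomod.isoi_fourier import ImagingStack
from visiomod.twophoton import (
    CellROI,
    CellTrace,
    delta_f_over_f,
    extract_traces,
    modulation,
    population_summary,
    responsive_cells,
)


def trace_from_cycle(cycle, protocol, n_cycles=None, cell_id="c"):
    n_cycles = n_cycles or protocol.n_cycles - 1
    return CellTrace(cell_id=cell_id, dff=np.tile(cycle, n_cycles), protocol=protocol,
                     n_cycles_retained=n_cycles, f0=1.0, baseline_method="direct")


class TestExtractTraces:
    def test_constant_stack_constant_traces(self):
        stack = ImagingStack(frames=np.full((30, 8, 8), 42.0), frame_rate_hz=3.74,
                             bit_depth="float", modality="twophoton")
        m = np.zeros((8, 8), dtype=bool)
        m[2:4, 2:4] = True
        out = extract_traces(stack, [CellROI(cell_id="a", mask=m)])
        assert np.allclose(out["a"], 42.0)

    def test_disjoint_cells_recover_generated_signals(self, twop_protocol):
        cells = synthetic.make_population("WT-like", "excitatory", 2, seed=0)
        sim = synthetic.simulate_calcium(cells, twop_protocol, seed=1)
        masks = []
        for i in range(2):
            m = np.zeros((16, 16), dtype=bool)
            m[4 * i: 4 * i + 3, 2:5] = True
            masks.append(m)
        movie = synthetic.render_cells_movie(sim.fluorescence, masks, (16, 16))
        rois = [CellROI(cell_id=c.cell_id, mask=m) for c, m in zip(cells, masks)]
        out = extract_traces(movie, rois)
        for i, c in enumerate(cells):
            assert np.allclose(out[c.cell_id], sim.fluorescence[i])

    def test_single_pixel_mask_equals_pixel_series(self):
        rng = np.random.default_rng(0)
        frames = rng.random((20, 6, 6))
        stack = ImagingStack(frames=frames, frame_rate_hz=3.74, bit_depth="float")
        m = np.zeros((6, 6), dtype=bool)
        m[3, 4] = True
        out = extract_traces(stack, [CellROI(cell_id="p", mask=m)])
        assert np.array_equal(out["p"], frames[:, 3, 4])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            CellROI(cell_id="x", mask=np.zeros((4, 4), dtype=bool))


class TestDeltaFOverF:
    def test_constant_trace_gives_zero_dff(self, twop_protocol):
        raw = np.full(twop_protocol.total_frames, 250.0)
        for method in ("percentile", "slow_epoch_mean", "global_mean"):
            trace = delta_f_over_f(raw, twop_protocol, baseline_method=method)
            assert np.allclose(trace.dff, 0.0)

    def test_first_of_21_cycles_removed(self, twop_protocol):
        raw = np.full(twop_protocol.total_frames, 100.0)
        raw[: twop_protocol.cycle_frames] = 999.0  # poison the first cycle
        trace = delta_f_over_f(raw, twop_protocol)
        assert trace.n_cycles_retained == 20
        assert len(trace.dff) == 20 * twop_protocol.cycle_frames
        assert trace.dff.max() < 1.0  # poisoned cycle is gone

    def test_known_modulation_recovered_with_percentile_baseline(self, twop_protocol):
        # trace spends 80% of its time at baseline, so the 10th percentile is F0
        T = twop_protocol.total_frames
        m = np.zeros(T)
        idx = np.arange(T) % twop_protocol.cycle_frames
        m[idx >= 80] = 0.5  # modulated only in the last fifth of each cycle
        raw = 200.0 * (1 + m)
        trace = delta_f_over_f(raw, twop_protocol)
        expect = m[twop_protocol.cycle_frames:]
        assert np.allclose(trace.dff, expect, atol=0.025)

    def test_non_positive_baseline_excludes_cell(self, twop_protocol):
        raw = np.zeros(twop_protocol.total_frames)
        with pytest.raises(ValueError, match="excluded"):
            delta_f_over_f(raw, twop_protocol, cell_id="bad")

    def test_short_trace_rejected(self, twop_protocol):
        with pytest.raises(ValueError, match="two stimulus cycles"):
            delta_f_over_f(np.ones(150), twop_protocol)


class TestResponsiveCells:
    def test_epoch_locked_modulation_is_detected(self, twop_protocol):
        cycle = np.zeros(100)
        cycle[50:] = 1.0
        rng = np.random.default_rng(0)
        dff = np.tile(cycle, 20) + rng.normal(0, 0.05, 2000)
        trace = CellTrace(cell_id="c", dff=dff, protocol=twop_protocol,
                          n_cycles_retained=20, f0=1.0, baseline_method="x")
        flag, p = responsive_cells([trace])["c"]
        assert flag and p < 1e-6

    def test_identical_epoch_means_not_responsive(self, twop_protocol):
        trace = trace_from_cycle(np.zeros(100), twop_protocol)
        flag, p = responsive_cells([trace])[trace.cell_id]
        assert not flag and p == 1.0

    def test_null_false_positive_rate_near_alpha(self, twop_protocol):
        rng = np.random.default_rng(42)
        traces = [
            CellTrace(cell_id=f"c{i}", dff=rng.normal(0, 0.1, 2000), protocol=twop_protocol,
                      n_cycles_retained=20, f0=1.0, baseline_method="x")
            for i in range(400)
        ]
        calls = responsive_cells(traces, alpha=0.05)
        rate = np.mean([f for f, _ in calls.values()])
        assert rate == pytest.approx(0.05, abs=0.03)

    def test_f_equals_t_squared_for_two_groups(self, twop_protocol):
        from scipy import stats as sps

        rng = np.random.default_rng(7)
        cyc = rng.normal(0, 0.2, (20, 100))
        trace = CellTrace(cell_id="c", dff=cyc.ravel(), protocol=twop_protocol,
                          n_cycles_retained=20, f0=1.0, baseline_method="x")
        slow = cyc[:, :50].mean(axis=1)
        fast = cyc[:, 50:].mean(axis=1)
        f_stat, p_anova = sps.f_oneway(slow, fast)
        t_stat, p_t = sps.ttest_ind(slow, fast)
        assert f_stat == pytest.approx(t_stat ** 2, rel=1e-10)
        assert responsive_cells([trace])["c"][1] == pytest.approx(p_anova, rel=1e-10)
        assert p_anova == pytest.approx(p_t, rel=1e-10)


class TestModulation:
    def test_square_wave_gives_epoch_difference(self, twop_protocol):
        a, b = 0.1, 0.7
        cycle = np.full(100, a)
        cycle[50:] = b
        res = modulation(trace_from_cycle(cycle, twop_protocol))
        assert res.su_mod == pytest.approx(b - a)
        assert res.sd_mod == pytest.approx(a - b)

    def test_fundamental_cosine_su_plus_sd_is_zero(self, twop_protocol):
        cycle = 0.3 * np.cos(2 * np.pi * np.arange(100) / 100 + 1.1)
        res = modulation(trace_from_cycle(cycle, twop_protocol))
        assert res.su_mod + res.sd_mod == pytest.approx(0.0, abs=1e-12)

    def test_quarter_bin_identity_for_arbitrary_cycle(self, twop_protocol):
        rng = np.random.default_rng(5)
        cycle = rng.normal(0, 1, 100)
        res = modulation(trace_from_cycle(cycle, twop_protocol))
        b1, b2, b3, b4 = (cycle[i * 25:(i + 1) * 25].mean() for i in range(4))
        # su = b3 - b2 and sd = b1 - b4 by definition, so the sum telescopes
        assert res.su_mod + res.sd_mod == pytest.approx((b1 + b3) - (b2 + b4), abs=1e-12)
        assert res.su_mod == pytest.approx(b3 - b2, abs=1e-12)
        assert res.sd_mod == pytest.approx(b1 - b4, abs=1e-12)

    def test_mean_of_differences_equals_difference_of_means(self, twop_protocol):
        rng = np.random.default_rng(8)
        cycles = rng.normal(0, 1, (20, 100))
        trace = CellTrace(cell_id="c", dff=cycles.ravel(), protocol=twop_protocol,
                          n_cycles_retained=20, f0=1.0, baseline_method="x")
        res = modulation(trace)
        per_cycle_su = cycles[:, 50:75].mean(axis=1) - cycles[:, 25:50].mean(axis=1)
        assert res.su_mod == pytest.approx(per_cycle_su.mean(), abs=1e-12)

    def test_constant_offset_invariance(self, twop_protocol):
        rng = np.random.default_rng(9)
        cycle = rng.normal(0, 1, 100)
        r1 = modulation(trace_from_cycle(cycle, twop_protocol))
        r2 = modulation(trace_from_cycle(cycle + 5.0, twop_protocol))
        assert r2.su_mod == pytest.approx(r1.su_mod, abs=1e-9)
        assert r2.sd_mod == pytest.approx(r1.sd_mod, abs=1e-9)

    def test_oversized_bin_rejected(self, twop_protocol):
        with pytest.raises(ValueError, match="bin"):
            modulation(trace_from_cycle(np.zeros(100), twop_protocol), bin_frames=30)

    def test_sd_locked_inhibitory_cell_signs(self, twop_protocol):
        cells = synthetic.make_population("WT-like", "inhibitory", 1, step_jitter_sd=0.0,
                                          noise_sd=0.0, seed=0)
        sim = synthetic.simulate_calcium(cells, twop_protocol, seed=0)
        trace = delta_f_over_f(sim.fluorescence[0], twop_protocol, cell_id="c")
        res = modulation(trace)
        assert res.sd_mod > 0 and res.su_mod < 0


class TestPopulationSummary:
    def res(self, su, sd, genotype="WT", cls="excitatory"):
        return twophoton.ModulationResult(cell_id="c", su_mod=su, sd_mod=sd,
                                          responsive=True, p_responsive=0.01,
                                          genotype=genotype, cell_class=cls)

    def test_identical_cells_zero_sem(self):
        out = population_summary([self.res(0.3, -0.1) for _ in range(5)])
        assert out[0].su_mean == pytest.approx(0.3)
        assert out[0].su_sem == 0.0
        assert out[0].n_cells == 5

    def test_pooled_grouping_concatenates_classes(self):
        results = [self.res(0.1, 0.0, cls="excitatory")] * 3 + [
            self.res(0.5, 0.0, cls="inhibitory")
        ] * 2
        pooled = population_summary(results, grouping_keys=())
        assert pooled[0].n_cells == 5
        assert pooled[0].su_mean == pytest.approx((3 * 0.1 + 2 * 0.5) / 5)

    def test_recovered_means_near_ground_truth(self, twop_protocol):
        cells = synthetic.make_population("WT-like", "inhibitory", 150, seed=10)
        sim = synthetic.simulate_calcium(cells, twop_protocol, seed=11)
        traces = [delta_f_over_f(sim.fluorescence[i], twop_protocol, cell_id=c.cell_id)
                  for i, c in enumerate(cells)]
        results = twophoton.analyze_cells(
            traces, labels={c.cell_id: {"genotype": "WT", "cell_class": "inhibitory"}
                            for c in cells})
        summ = population_summary(results)[0]
        # ground truth: same modulation statistic on the noiseless traces
        n = twop_protocol.cycle_frames
        clean = sim.dff_clean[:, n:].reshape(len(cells), -1, n).mean(axis=1)
        gt_su = (clean[:, 50:75].mean(axis=1) - clean[:, 25:50].mean(axis=1)).mean()
        gt_sd = (clean[:, 0:25].mean(axis=1) - clean[:, 75:100].mean(axis=1)).mean()
        assert summ.su_mean == pytest.approx(gt_su, abs=2.5 * summ.su_sem)
        assert summ.sd_mean == pytest.approx(gt_sd, abs=2.5 * summ.sd_sem)
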