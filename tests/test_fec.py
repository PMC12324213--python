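import numpy as np
import pytest

from smtether.fec import (
    AnalysisError,
    ForceExtensionTrace,
    analyze_trace,
    delta_lc,
    detect_transitions,
    dlc_distribution,
    downsample,
    fit_branch_lc,
    validate_tether,
)
from smtether.polymer import expected_full_dlc, tether_extension
from smtether.synth import make_preset, simulate_fec

from conftest import gap_to_dlc, make_trap_trace


def _flat_trace(n=200, rate=78000.0, force=5.0):
    t = np.arange(n) / rate
    return ForceExtensionTrace("m", 1, "stretch", t, np.linspace(0, 10, n),
                               np.full(n, force), rate)


class TestDownsample:
    def test_78khz_to_100hz_sample_count(self):
        n = 78000
        rate = 78000.0
        tr = ForceExtensionTrace(
            "m", 1, "stretch", np.arange(n) / rate,
            np.linspace(0, 500, n), np.linspace(0, 15, n), rate,
        )
        out = downsample(tr, 100.0)
        assert len(out) == 100
        assert out.sample_rate == pytest.approx(100.0)

    def test_constant_trace_unchanged(self):
        tr = _flat_trace()
        out = downsample(tr, 7800.0)
        assert np.allclose(out.force, 5.0)

    def test_grand_mean_preserved(self):
        rng = np.random.default_rng(0)
        n, rate = 7800, 78000.0
        tr = ForceExtensionTrace("m", 1, "stretch", np.arange(n) / rate,
                                 rng.normal(size=n), rng.normal(size=n), rate)
        out = downsample(tr, 100.0)
        assert out.force.mean() == pytest.approx(tr.force.mean(), abs=1e-12)

    def test_target_rate_above_sample_rate_rejected(self):
        with pytest.raises(ValueError):
            downsample(_flat_trace(), 1e6)


class TestDetectTransitions:
    def test_smooth_curve_has_no_transitions(self, tether):
        trace, _ = make_trap_trace(tether, 0.0, 0.0, switch_force=7.0)
        assert detect_transitions(trace) == []

    def test_injected_15nm_jump_found_at_index(self, tether, protein_unit):
        dlc = gap_to_dlc(15.0, 7.0, protein_unit)
        trace, rip = make_trap_trace(tether, 0.0, dlc, switch_force=7.0)
        found = detect_transitions(trace)
        assert len(found) == 1
        assert abs(found[0].index - rip) <= 1
        # screening estimate is conservative (local linear extrapolation of
        # a curved branch); the WLC-refined jump must hit the gap exactly
        assert 8.0 < found[0].jump_nm <= 16.0
        assert found[0].direction == "unfold"
        analyzed = analyze_trace(trace, tether)
        assert len(analyzed.transitions) == 1
        assert analyzed.transitions[0].jump_nm == pytest.approx(15.0, abs=1.0)
        assert analyzed.transitions[0].dlc_nm == pytest.approx(dlc, abs=2.0)

    def test_9nm_jump_below_threshold_ignored(self, tether, protein_unit):
        dlc = gap_to_dlc(9.0, 7.0, protein_unit)
        trace, _ = make_trap_trace(tether, 0.0, dlc, switch_force=7.0)
        assert detect_transitions(trace) == []

    @pytest.mark.parametrize("gap,expected_n", [(8.0, 0), (12.0, 1)])
    def test_threshold_sharpness(self, tether, protein_unit, gap, expected_n):
        # jumps of min_jump * (1 +/- 0.2) on noiseless traces
        dlc = gap_to_dlc(gap, 7.0, protein_unit)
        trace, _ = make_trap_trace(tether, 0.0, dlc, switch_force=7.0)
        analyzed = analyze_trace(trace, tether)
        assert len(analyzed.transitions) == expected_n

    def test_relax_direction_yields_refold(self, tether, protein_unit):
        dlc = gap_to_dlc(20.0, 6.0, protein_unit)
        trace, _ = make_trap_trace(tether, 0.0, dlc, switch_force=6.0,
                                   direction="relax")
        found = detect_transitions(trace)
        assert len(found) == 1
        assert found[0].direction == "refold"

    def test_short_trace_rejected(self):
        tr = _flat_trace(n=8)
        with pytest.raises(AnalysisError):
            detect_transitions(tr)

    def test_detection_is_deterministic(self, tether, protein_unit):
        dlc = gap_to_dlc(15.0, 7.0, protein_unit)
        trace, _ = make_trap_trace(tether, 0.0, dlc, switch_force=7.0,
                                   noise_sd=1.0, seed=5)
        a = detect_transitions(trace)
        b = detect_transitions(trace)
        assert [(t.index, t.jump_nm) for t in a] == [(t.index, t.jump_nm) for t in b]


class TestFitBranchLc:
    def _branch(self, tether, lc, noise_sd=0.0, n=50, seed=0):
        f = np.linspace(3.0, 10.0, n)
        ext = tether_extension(f, tether.with_unfolded_lc(lc))
        if noise_sd:
            ext = ext + np.random.default_rng(seed).normal(0, noise_sd, n)
        return ext, f

    def test_noiseless_recovery(self, tether):
        ext, f = self._branch(tether, 120.0)
        fit = fit_branch_lc(ext, f, tether)
        assert not fit.flagged
        assert fit.lc_nm == pytest.approx(120.0, abs=0.1)
        assert fit.rms_residual < 0.01

    def test_noisy_recovery_within_3nm(self, tether):
        errs = []
        for seed in range(100):
            ext, f = self._branch(tether, 120.0, noise_sd=2.0, seed=seed)
            fit = fit_branch_lc(ext, f, tether)
            errs.append(fit.lc_nm - 120.0)
        assert np.max(np.abs(errs)) <= 3.0

    def test_fully_folded_branch(self, tether):
        ext, f = self._branch(tether, 0.0)
        fit = fit_branch_lc(ext, f, tether)
        assert fit.lc_nm <= 5.0

    def test_too_short_branch_flagged(self, tether):
        ext, f = self._branch(tether, 50.0, n=3)
        fit = fit_branch_lc(ext, f, tether)
        assert fit.flagged and "few" in fit.reason

    def test_narrow_force_range_flagged(self, tether):
        f = np.linspace(5.0, 5.2, 30)
        ext = tether_extension(f, tether.with_unfolded_lc(50.0))
        fit = fit_branch_lc(ext, f, tether)
        assert fit.flagged and "force range" in fit.reason


class TestDeltaLc:
    def test_two_rip_trace_total(self, cfg):
        from smtether.synth import DomainKinetics, EnsembleSpec

        domains = (
            DomainKinetics(80.0, 2.6e-4, 6.0, 1000.0, 6.0),
            DomainKinetics(118.0, 8.7e-5, 6.0, 1000.0, 6.0),
        )
        spec = EnsembleSpec(domains=domains, n_molecules=5, seed=11,
                            include_relax=False, tether_cfg=cfg)
        traces, labels = simulate_fec(spec)
        from smtether.polymer import make_tether

        tether = make_tether(cfg)
        totals = []
        for tr in traces:
            a = analyze_trace(tr, tether)
            totals.append(delta_lc(a)["total_dlc"])
        assert np.median(totals) == pytest.approx(198.0, abs=4.0)

    def test_no_transition_trace_near_zero(self, tether):
        trace, _ = make_trap_trace(tether, 0.0, 0.0, switch_force=7.0,
                                   noise_sd=1.0, seed=3)
        a = analyze_trace(trace, tether)
        d = delta_lc(a)
        assert abs(d["total_dlc"]) < 5.0
        assert d["per_rip"] == []

    def test_per_rip_conservation(self, cfg, tether, small_ensemble):
        # per-rip dLc telescopes to the branch-difference total on every
        # analysable simulated sweep
        _, traces, _ = small_ensemble
        checked = 0
        for tr in traces:
            a = analyze_trace(tr, tether)
            try:
                d = delta_lc(a)
            except AnalysisError:
                continue
            assert abs(sum(d["per_rip"]) - d["total_dlc"]) < 2.0
            checked += 1
        assert checked >= 90

    def test_analysis_idempotent(self, cfg, tether, small_ensemble):
        _, traces, _ = small_ensemble
        tr = traces[0]
        a1 = analyze_trace(tr, tether)
        a2 = analyze_trace(tr, tether)
        assert [(t.index, t.dlc_nm) for t in a1.transitions] == \
               [(t.index, t.dlc_nm) for t in a2.transitions]


class TestDlcDistribution:
    def test_normal_sample_single_peak(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(198.0, 8.0, 100)
        dist = dlc_distribution(vals, seed=1)
        assert len(dist.peaks_nm) == 1
        assert dist.mode_nm == pytest.approx(198.0, abs=2.0)

    def test_bimodal_mixture_two_peaks(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(0.0, 2.0, 33),
                               rng.normal(198.0, 8.0, 67)])
        dist = dlc_distribution(vals, seed=2)
        assert len(dist.peaks_nm) == 2
        positions = sorted(dist.peaks_nm)
        assert abs(positions[0]) < 10.0
        assert abs(positions[1] - 198.0) < 10.0

    def test_identical_values_degenerate(self):
        dist = dlc_distribution([42.0] * 20)
        assert dist.peaks_nm == [42.0]
        assert dist.mode_nm == 42.0
        assert dist.mode_se_nm == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dlc_distribution([])

    def test_histogram_counts_sum(self):
        vals = [10.0, 20.0, 30.0, 200.0]
        dist = dlc_distribution(vals)
        assert dist.counts.sum() == len(vals)


class TestValidateTether:
    @pytest.fixture
    def expected(self, cfg):
        return expected_full_dlc(int(cfg["residues"]), cfg["nm_per_residue"],
                                 cfg["folded_core_nm"])

    def _molecule(self, cfg, rupture, seed=9):
        spec = make_preset("no_smap", cfg, n_molecules=1,
                           cycles_per_molecule=1, seed=seed,
                           include_relax=False, rupture=rupture)
        traces, _ = simulate_fec(spec)
        return traces

    def test_single_tether_accepted(self, cfg, tether, expected):
        res = validate_tether(self._molecule(cfg, "single"), tether, expected,
                              tol=cfg["single_tether_tol_nm"])
        assert res["single_tether"] is True

    def test_double_tether_rejected(self, cfg, tether, expected):
        res = validate_tether(self._molecule(cfg, "double"), tether, expected,
                              tol=cfg["single_tether_tol_nm"])
        assert res["single_tether"] is False
        assert "multi-step rupture" in res["reasons"]

    def test_no_rupture_undetermined(self, cfg, tether, expected):
        res = validate_tether(self._molecule(cfg, None), tether, expected,
                              tol=cfg["single_tether_tol_nm"])
        assert res["single_tether"] is None
        assert "no rupture observed" in res["reasons"]
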