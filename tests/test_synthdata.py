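import numpy as np
import pandas as pd
import pytest

from synchrosep import synthdata as sd
from synchrosep.chromops import detect_peaks, total_ion_chromatogram
from synchrosep.drtmodel import PSMRecord


class TestSimulateLibrary:
    def test_zero_entrapment_all_targets(self):
        lib = sd.simulate_library(100, 20, 5, 35, 0.0, 7)
        assert len(lib) == 100
        assert all(e.species == "target" for e in lib)

    def test_entrapment_count_is_floor(self):
        lib = sd.simulate_library(1000, 100, 5, 35, 0.2, 7)
        assert sum(e.species == "entrapment" for e in lib) == 200

    def test_same_seed_identical(self):
        a = sd.simulate_library(50, 10, seed=3)
        b = sd.simulate_library(50, 10, seed=3)
        for x, y in zip(a, b):
            assert x.precursor_id == y.precursor_id
            assert x.peptide == y.peptide
            assert np.array_equal(x.fragment_mzs, y.fragment_mzs)
            assert x.ref_rt == y.ref_rt
            assert x.abundance == y.abundance

    def test_entry_invariants(self):
        lib = sd.simulate_library(200, 40, 5, 35, 0.1, 1)
        for e in lib:
            assert abs(e.fragment_rel_intensities.sum() - 1.0) <= 1e-9
            assert np.all(np.diff(e.fragment_mzs) > 0)
            assert 5 <= e.ref_rt <= 35
            assert e.charge >= 1
            assert len(e.fragment_mzs) >= 3

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_precursors=0, n_proteins=5),
            dict(n_precursors=10, n_proteins=5, entrapment_fraction=1.0),
            dict(n_precursors=10, n_proteins=5, entrapment_fraction=-0.1),
            dict(n_precursors=10, n_proteins=5, gradient_start_min=30,
                 gradient_end_min=5),
            dict(n_precursors=10, n_proteins=5, gradient_end_min=float("nan")),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(sd.ParameterError):
            sd.simulate_library(**kwargs)


class TestSimulateRun:
    def test_tic_additivity_at_zero_suppression(self, small_library, constant_profile):
        kw = dict(delta_rt_profile=constant_profile, suppression=0.0, seed=5)
        dual, _ = sd.simulate_run(
            small_library, sd.RunDesign("d", 200.0, 200.0, **kw))
        one, _ = sd.simulate_run(
            small_library, sd.RunDesign("1", 200.0, 0.0, **kw))
        two, _ = sd.simulate_run(
            small_library, sd.RunDesign("2", 0.0, 200.0, **kw))
        tic_d = total_ion_chromatogram(dual).intensity
        tic_s = (total_ion_chromatogram(one).intensity
                 + total_ion_chromatogram(two).intensity)
        assert np.abs(tic_d - tic_s).max() <= 1e-6 * tic_s.max()

    def test_suppression_bounds_dual_tic(self, small_library, constant_profile):
        s = 0.06
        kw = dict(delta_rt_profile=constant_profile, seed=5)
        dual, _ = sd.simulate_run(
            small_library, sd.RunDesign("d", 200.0, 200.0, suppression=s, **kw))
        one, _ = sd.simulate_run(
            small_library, sd.RunDesign("1", 200.0, 0.0, suppression=s, **kw))
        two, _ = sd.simulate_run(
            small_library, sd.RunDesign("2", 0.0, 200.0, suppression=s, **kw))
        sum_single = (total_ion_chromatogram(one).intensity.sum()
                      + total_ion_chromatogram(two).intensity.sum())
        ratio = total_ion_chromatogram(dual).intensity.sum() / sum_single
        assert 1.0 - s - 1e-6 <= ratio <= 1.0 + 1e-6

    def test_blank_column_has_no_ground_truth_peaks(self, small_library,
                                                    constant_profile):
        _, gt = sd.simulate_run(
            small_library,
            sd.RunDesign("b", 200.0, 0.0, delta_rt_profile=constant_profile, seed=1))
        assert (gt.table["column"] == 2).sum() == 0

    def test_blank_run_is_valid_and_empty(self, small_library, constant_profile):
        traces, gt = sd.simulate_run(
            small_library,
            sd.RunDesign("bb", 0.0, 0.0, delta_rt_profile=constant_profile, seed=1))
        assert traces == []
        assert gt.table.empty

    def test_negative_load_rejected(self, constant_profile):
        with pytest.raises(sd.ParameterError):
            sd.RunDesign("x", -1.0, 0.0, delta_rt_profile=constant_profile)

    def test_apex_offset_fidelity_constant_profile(self, dual_run, small_library):
        """Noise-free dual run: the two apexes of every dual-detected
        fragment channel differ by the 4.0 min offset within half a
        sampling step."""
        design, traces, gt = dual_run
        det = gt.table[gt.table["detected"]]
        both = set(det[det["column"] == 1].precursor_id) & set(
            det[det["column"] == 2].precursor_id)
        half_step = (design.sample_step_s / 60.0) / 2
        frag0 = {e.fragment_mzs[0]: e.precursor_id for e in small_library}
        checked = 0
        for t in traces:
            pid = frag0.get(t.mz)
            if pid is None or pid not in both:
                continue
            peaks = sorted(detect_peaks(t), key=lambda p: -p.area)[:2]
            if len(peaks) < 2:
                continue
            lo, hi = sorted(p.apex_rt for p in peaks)
            assert hi - lo == pytest.approx(4.0, abs=2 * half_step + 1e-9)
            checked += 1
        assert checked >= 50

    def test_detection_monotone_in_load(self, small_library, constant_profile):
        """Raising the load never decreases the expected number of
        detected precursors (averaged over seeds)."""
        means = []
        for load in (10.0, 50.0, 200.0):
            counts = [
                sd.simulate_run(
                    small_library,
                    sd.RunDesign("m", load, 0.0, delta_rt_profile=constant_profile,
                                 seed=s),
                    render_traces=False,
                )[1].detected(1).shape[0]
                for s in range(5)
            ]
            means.append(np.mean(counts))
        assert means[0] <= means[1] <= means[2]

    def test_determinism(self, small_library, constant_profile):
        d = sd.RunDesign("r", 200.0, 100.0, delta_rt_profile=constant_profile, seed=9)
        t1, g1 = sd.simulate_run(small_library, d)
        t2, g2 = sd.simulate_run(small_library, d)
        assert g1.table.equals(g2.table)
        assert all(np.array_equal(a.intensity, b.intensity) for a, b in zip(t1, t2))

    def test_missing_detections_are_low_intensity(self, small_library,
                                                  constant_profile):
        """Undetected precursors sit lower in abundance than detected
        ones (logistic missingness model)."""
        _, gt = sd.simulate_run(
            small_library,
            sd.RunDesign("r", 10.0, 0.0, delta_rt_profile=constant_profile, seed=2),
            render_traces=False)
        t = gt.table
        det = t[t["detected"]]["true_area"]
        mis = t[~t["detected"]]["true_area"]
        assert len(det) and len(mis)
        assert np.median(mis) < np.median(det)


class TestOffsetProfile:
    def test_constant_everywhere(self):
        p = sd.OffsetProfile("constant", 4.0)
        assert p.evaluate(7.0) == 4.0 and p.evaluate(30.0) == 4.0

    def test_smooth_drift_range(self):
        p = sd.OffsetProfile("smooth_drift", 4.0, (0.3, 30.0, 5.0))
        t = np.linspace(5, 35, 100)
        v = p.evaluate(t)
        assert np.all(v >= 3.7 - 1e-12) and np.all(v <= 4.3 + 1e-12)

    def test_nonpositive_offset_rejected(self):
        with pytest.raises(sd.ParameterError):
            sd.OffsetProfile("linear_drift", 0.5, (-0.1, 0.0)).evaluate(
                np.linspace(5, 35, 10))


class TestDilutionSeries:
    def test_direct_triplicate_run_count(self, small_library, constant_profile):
        base = sd.RunDesign("b", 200.0, 200.0, delta_rt_profile=constant_profile,
                            seed=3)
        runs = sd.simulate_dilution_series(
            small_library, "direct", 3, base, render_traces=False)
        assert len(runs) == 12

    def test_inverted_first_point_loads(self, constant_profile):
        base = sd.RunDesign("b", 200.0, 200.0, delta_rt_profile=constant_profile)
        designs = sd.dilution_designs("inverted", 1, base)
        assert (designs[0].load_col1, designs[0].load_col2) == (200.0, 10.0)

    def test_direct_loads_equal(self, constant_profile):
        base = sd.RunDesign("b", 200.0, 200.0, delta_rt_profile=constant_profile)
        for d in sd.dilution_designs("direct", 1, base):
            assert d.load_col1 == d.load_col2

    def test_replicates_get_distinct_seeds(self, constant_profile):
        base = sd.RunDesign("b", 200.0, 200.0, delta_rt_profile=constant_profile,
                            seed=3)
        seeds = [d.seed for d in sd.dilution_designs("direct", 3, base)]
        assert len(set(seeds)) == len(seeds)

    def test_unknown_scheme_rejected(self, constant_profile):
        base = sd.RunDesign("b", 1.0, 1.0, delta_rt_profile=constant_profile)
        with pytest.raises(sd.ParameterError):
            sd.dilution_designs("sideways", 1, base)


class TestPSMTable:
    def test_dual_detection_yields_two_records(self, dual_run, small_library):
        _, traces, gt = dual_run
        psms = sd.simulate_psm_table(traces, gt, small_library, seed=1)
        counts = pd.Series([p.precursor_id for p in psms]).value_counts()
        det = gt.table[gt.table["detected"]]
        both = set(det[det["column"] == 1].precursor_id) & set(
            det[det["column"] == 2].precursor_id)
        for pid in both:
            assert counts[pid] == 2

    def test_blank_column_produces_no_offset_records(self, small_library,
                                                     constant_profile):
        _, gt = sd.simulate_run(
            small_library,
            sd.RunDesign("s", 200.0, 0.0, delta_rt_profile=constant_profile, seed=4),
            render_traces=False)
        psms = sd.simulate_psm_table([], gt, small_library, seed=1)
        refs = {e.precursor_id: e.ref_rt for e in small_library}
        for p in psms:
            assert abs(p.rt - refs[p.precursor_id]) < 1.0  # never near ref+4

    def test_fixed_seed_identical_table(self, dual_run, small_library):
        _, traces, gt = dual_run
        a = sd.simulate_psm_table(traces, gt, small_library, seed=5)
        b = sd.simulate_psm_table(traces, gt, small_library, seed=5)
        assert a == b


class TestIO:
    def test_library_roundtrip(self, tmp_path, small_library):
        path = tmp_path / "lib.tsv"
        sd.write_library(small_library, path)
        back = sd.read_library(path)
        assert len(back) == len(small_library)
        for a, b in zip(small_library, back):
            assert a.precursor_id == b.precursor_id
            assert b.ref_rt == pytest.approx(a.ref_rt, abs=1e-4)
            assert abs(b.fragment_rel_intensities.sum() - 1.0) <= 1e-9

    def test_traces_roundtrip(self, tmp_path, dual_run):
        _, traces, _ = dual_run
        path = tmp_path / "run.json"
        sd.write_traces(traces[:20], path, meta={"run_id": "dual"})
        back, meta = sd.read_traces(path)
        assert meta["run_id"] == "dual"
        assert len(back) == 20
        for a, b in zip(traces[:20], back):
            assert b.mz == pytest.approx(a.mz, abs=1e-4)
            assert np.allclose(a.intensity, b.intensity, atol=5e-4, rtol=1e-3)

    def test_ground_truth_roundtrip(self, tmp_path, dual_run):
        _, _, gt = dual_run
        path = tmp_path / "gt.tsv"
        gt.to_tsv(path)
        back = sd.GroundTruth.from_tsv(path)
        assert back.loads == gt.loads
        assert len(back.table) == len(gt.table)
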