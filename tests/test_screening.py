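"""Tiered identification: gates, scores, batch screening and SDL logic."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import residuescreen as rs
from residuescreen.screening import STATUS_ORDER

from conftest import perfect_feature


CFG = rs.ScreeningConfig()


def shift_ppm(f, ppm):
    """Shift a feature's whole mass axis by a relative offset (keeps invariants)."""
    scale = 1 + ppm * 1e-6
    return dataclasses.replace(
        f,
        mz=f.mz * scale,
        isotope_cluster=tuple((mz * scale, i) for mz, i in f.isotope_cluster),
    )


class TestPrecursorRtGate:
    def test_exact_feature_passes_with_zero_errors(self, atrazine):
        f = perfect_feature(atrazine)
        passed, ppm, drt = rs.match_precursor_rt(f, atrazine, CFG)
        assert passed and ppm == pytest.approx(0.0, abs=1e-9) and drt == 0.0

    @pytest.mark.parametrize("ppm_off,expected", [(6.0, False), (4.999, True), (-4.999, True), (-6.0, False)])
    def test_ppm_tolerance_five_ppm(self, atrazine, ppm_off, expected):
        f = perfect_feature(atrazine)
        f = dataclasses.replace(
            f, mz=f.mz * (1 + ppm_off * 1e-6), isotope_cluster=(), ms2=None
        )
        assert rs.match_precursor_rt(f, atrazine, CFG)[0] is expected

    def test_ppm_boundary_is_closed(self, atrazine):
        # a feature sitting exactly on the tolerance passes; any tightening fails it
        f = shift_ppm(perfect_feature(atrazine), 5.0)
        achieved = abs(rs.ppm_error(f.mz, atrazine.precursor_mz))
        at = dataclasses.replace(CFG, precursor_tol=achieved)
        just_under = dataclasses.replace(CFG, precursor_tol=achieved * (1 - 1e-12))
        assert rs.match_precursor_rt(f, atrazine, at)[0]
        assert not rs.match_precursor_rt(f, atrazine, just_under)[0]

    @pytest.mark.parametrize("rt_off,expected", [(0.099, True), (-0.099, True), (0.11, False)])
    def test_rt_window_tenth_of_minute(self, atrazine, rt_off, expected):
        f = perfect_feature(atrazine)
        f = dataclasses.replace(f, rt=f.rt + rt_off)
        assert rs.match_precursor_rt(f, atrazine, CFG)[0] is expected

    def test_rt_boundary_is_closed(self, atrazine):
        f = perfect_feature(atrazine)
        f = dataclasses.replace(f, rt=f.rt + 0.1)
        achieved = abs(f.rt - atrazine.expected_rt)
        at = dataclasses.replace(CFG, rt_tol=achieved)
        just_under = dataclasses.replace(CFG, rt_tol=achieved * (1 - 1e-12))
        assert rs.match_precursor_rt(f, atrazine, at)[0]
        assert not rs.match_precursor_rt(f, atrazine, just_under)[0]

    def test_weak_precursor_fails_intensity_trigger(self, atrazine):
        f = perfect_feature(atrazine, area=4.9e4)
        assert not rs.match_precursor_rt(f, atrazine, CFG)[0]

    def test_polarity_mismatch_fails_without_raising(self, atrazine):
        f = perfect_feature(atrazine)
        f = dataclasses.replace(f, polarity="negative")
        assert not rs.match_precursor_rt(f, atrazine, CFG)[0]


class TestMatchFragments:
    def test_all_library_fragments_recovered(self, atrazine):
        ms2 = tuple((mz, 1e5) for mz in atrazine.fragments)
        n, matches = rs.match_fragments(ms2, atrazine, CFG)
        assert n == len(atrazine.fragments)
        assert all(abs(m[2]) < 1e-9 for m in matches)

    def test_empty_spectrum_matches_nothing(self, atrazine):
        assert rs.match_fragments((), atrazine, CFG) == (0, [])
        assert rs.match_fragments(None, atrazine, CFG) == (0, [])

    def test_one_observed_peak_between_two_close_fragments_matches_once(self, panel):
        lib, _, _ = panel
        c = dataclasses.replace(lib["Atrazine"], fragments=(200.000, 200.001))
        # observed peak ~2.5 ppm from both library fragments: the one-to-one
        # greedy rule matches it exactly once, to the smaller-|ppm| fragment
        # (the higher m/z, since the Da offset is shared)
        n, matches = rs.match_fragments(((200.0005, 1e5),), c, CFG)
        assert n == 1
        assert matches[0][0] == 200.001

    def test_weak_product_ions_ignored(self, atrazine):
        ms2 = tuple((mz, 999.0) for mz in atrazine.fragments)
        assert rs.match_fragments(ms2, atrazine, CFG)[0] == 0


class TestIsotopeScore:
    def test_cluster_identical_to_envelope_scores_100(self, atrazine):
        env = rs.isotope_envelope(atrazine.formula, atrazine.adduct)
        cluster = tuple((mz, rel * 5e6) for mz, rel in env)
        score, n, n_exp = rs.isotope_score(cluster, env, CFG)
        assert score == pytest.approx(100.0)
        assert n == n_exp == len(env)

    def test_base_peak_only_scores_its_abundance_share(self):
        # Cl2: envelope shares 1 : 0.639916 : 0.102373 (enumeration oracle)
        env = rs.isotope_envelope(rs.parse_formula("Cl2"), prune=0.01)
        score, n, n_exp = rs.isotope_score(((env.peaks[0][0], 1e6),), env, CFG)
        assert n == 1 and n_exp == 3
        assert score == pytest.approx(100.0 / (1 + 0.639916 + 0.102373), abs=0.01)

    def test_empty_cluster_scores_zero(self, atrazine):
        env = rs.isotope_envelope(atrazine.formula, atrazine.adduct)
        assert rs.isotope_score((), env, CFG) == (0.0, 0, len(env))

    def test_wrong_relative_intensity_fails_deviation_gate(self, atrazine):
        env = rs.isotope_envelope(atrazine.formula, atrazine.adduct)
        base_mz = env.peaks[0][0]
        a1_mz, a1_rel = env.peaks[1]
        cluster = ((base_mz, 1e6), (a1_mz, 1e6 * (a1_rel + 0.3)))
        _, n, _ = rs.isotope_score(cluster, env, CFG)
        assert n == 1  # A+1 intensity off by > 0.25 of base


class TestMs2Similarity:
    def test_identical_spectra_score_100(self):
        spec = ((100.0, 10.0), (150.0, 5.0), (200.0, 1.0))
        assert rs.ms2_similarity(spec, spec) == pytest.approx(100.0)

    def test_disjoint_spectra_score_zero(self):
        assert rs.ms2_similarity(((100.0, 1.0),), ((300.0, 1.0),)) == pytest.approx(0.0)

    def test_half_coverage_scores_50(self):
        # hand oracle: (sqrt(1*1))^2 / (1 * 2) = 0.5
        ref = ((100.0, 1.0), (200.0, 1.0))
        obs = ((100.0, 1.0),)
        assert rs.ms2_similarity(obs, ref) == pytest.approx(50.0)

    def test_empty_side_gives_absent_result(self):
        assert rs.ms2_similarity((), ((100.0, 1.0),)) is None
        assert rs.ms2_similarity(((100.0, 1.0),), None) is None

    def test_agrees_with_matchms_squared_cosine(self):
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(7)
        mzs = np.sort(rng.uniform(80, 400, 12))
        ref = tuple(zip(mzs.tolist(), rng.uniform(1, 100, 12).tolist()))
        obs = tuple(zip(mzs[:8].tolist(), rng.uniform(1, 100, 8).tolist()))
        ours = rs.ms2_similarity(obs, ref)
        s_obs = matchms.Spectrum(
            mz=np.array([m for m, _ in obs]),
            intensities=np.sqrt([i for _, i in obs]),
            metadata={"precursor_mz": 500.0},
        )
        s_ref = matchms.Spectrum(
            mz=np.array([m for m, _ in ref]),
            intensities=np.sqrt([i for _, i in ref]),
            metadata={"precursor_mz": 500.0},
        )
        cosine = CosineGreedy(tolerance=0.005).pair(s_obs, s_ref)
        assert ours == pytest.approx(100.0 * float(cosine["score"]) ** 2, rel=1e-6)


class TestClassifyMatch:
    def test_perfect_feature_is_confirmed(self, atrazine):
        res = rs.classify_match(perfect_feature(atrazine), atrazine, CFG)
        assert res.status == "confirmed"
        assert res.isotope_score == pytest.approx(100.0)
        assert res.n_fragments_matched == len(atrazine.fragments)

    def test_no_ms2_caps_at_screened(self, atrazine):
        f = dataclasses.replace(perfect_feature(atrazine), ms2=None)
        assert rs.classify_match(f, atrazine, CFG).status == "screened"

    def test_isotope_score_threshold_is_strict(self, atrazine):
        f = perfect_feature(atrazine)  # scores exactly 100
        at_boundary = dataclasses.replace(CFG, isotope_score_min=100.0)
        assert rs.classify_match(f, atrazine, at_boundary).status == "screened"
        below = dataclasses.replace(CFG, isotope_score_min=99.9)
        assert rs.classify_match(f, atrazine, below).status == "confirmed"

    def test_missing_feature_reports_none(self, atrazine):
        res = rs.classify_match(None, atrazine, CFG)
        assert res.status == "none"
        assert math.isnan(res.precursor_ppm)


class TestScreenBatch:
    def test_blank_sample_yields_all_none(self, panel):
        lib, _, _ = panel
        small = lib.subset([c.name for c in list(lib)[:5]])
        f = perfect_feature(small.records[0], sample_id="blank")
        weak = dataclasses.replace(f, area=1.0, height=1.0)
        results = rs.screen_batch([weak], small, CFG)
        assert len(results) == 5
        assert all(r.status == "none" for r in results)

    def test_two_passing_features_yield_single_best_result(self, atrazine):
        lib = rs.SuspectLibrary([atrazine])
        good = perfect_feature(atrazine)
        worse = dataclasses.replace(
            good, mz=good.mz * (1 + 3e-6), isotope_cluster=(), ms2=None
        )
        for order in ([good, worse], [worse, good]):
            results = rs.screen_batch(order, lib, CFG)
            assert len(results) == 1
            assert abs(results[0].precursor_ppm) < 1e-6  # the closer feature won

    def test_ppm_tie_breaks_on_delta_rt_then_area(self, atrazine):
        lib = rs.SuspectLibrary([atrazine])
        f0 = perfect_feature(atrazine)
        near = dataclasses.replace(f0, rt=f0.rt + 0.01)
        far = dataclasses.replace(f0, rt=f0.rt + 0.05)
        res = rs.screen_batch([far, near], lib, CFG)[0]
        assert res.delta_rt == pytest.approx(0.01)
        big = dataclasses.replace(f0, area=2e7, height=2e7,
                                  isotope_cluster=tuple((m, 2 * i) for m, i in f0.isotope_cluster))
        res = rs.screen_batch([f0, big], lib, CFG)[0]
        assert res.area == pytest.approx(2e7)

    def test_matches_exhaustive_assignment_on_small_batch(self, panel):
        lib, _, _ = panel
        names = [c.name for c in list(lib)[:5]]
        small = lib.subset(names)
        feats = [perfect_feature(c, sample_id="s") for c in small]
        results = rs.screen_batch(feats, small, CFG)
        # exhaustive oracle: per compound, best passing feature by the tie key
        for r in results:
            c = small[r.compound]
            best = None
            for f in feats:
                ok, ppm, drt = rs.match_precursor_rt(f, c, CFG)
                if ok:
                    key = (abs(ppm), abs(drt), -f.area)
                    if best is None or key < best:
                        best = key
            assert (best is not None) == (r.status != "none")

    def test_noiseless_synthetic_batch_fully_confirmed(self, panel, noiseless):
        lib, frame, curves = panel
        names = [c.name for c in list(lib)[:20] if curves[c.name].predict(10.0) > 2e5]
        small = lib.subset(names)
        tables = rs.simulate_spike_experiment(
            rs.SpikeDesign(levels=(10.0,), n_reps=1), small, curves, noiseless, 0
        )
        results = rs.screen_batch(tables[10.0][0], small, CFG)
        assert all(r.status == "confirmed" for r in results)
        # envelope centroid and direct mass sum agree to float rounding
        assert all(abs(r.precursor_ppm) < 1e-6 for r in results)


class TestTierMonotonicity:
    @settings(max_examples=25, deadline=None)
    @given(
        ppm_off=st.floats(-8, 8),
        rt_off=st.floats(-0.15, 0.15),
        tight=st.floats(0.3, 1.0),
    )
    def test_tightening_never_promotes(self, panel, ppm_off, rt_off, tight):
        lib, _, _ = panel
        c = lib["Atrazine"]
        f = shift_ppm(perfect_feature(c), ppm_off)
        f = dataclasses.replace(f, rt=f.rt + rt_off)
        loose = rs.ScreeningConfig()
        tighter = dataclasses.replace(
            loose,
            precursor_tol=loose.precursor_tol * tight,
            rt_tol=loose.rt_tol * tight,
            fragment_tol=loose.fragment_tol * tight,
            isotope_score_min=loose.isotope_score_min + (1 - tight) * 20,
        )
        s_loose = STATUS_ORDER[rs.classify_match(f, c, loose).status]
        s_tight = STATUS_ORDER[rs.classify_match(f, c, tighter).status]
        assert s_tight <= s_loose


class TestDetermineSdl:
    def test_full_detection_everywhere_gives_lowest_level(self):
        det = {0.5: [True] * 20, 1.0: [True] * 20, 2.0: [True] * 20}
        assert rs.determine_sdl(det) == 0.5

    def test_partial_detection_pushes_sdl_up(self):
        det = {1.0: [True] * 10 + [False] * 10, 2.0: [True] * 20}
        assert rs.determine_sdl(det) == 2.0

    def test_no_level_qualifies_gives_none(self):
        det = {1.0: [False] * 20, 2.0: [True] * 10 + [False] * 10}
        assert rs.determine_sdl(det) is None

    def test_ragged_replicates_rejected(self):
        with pytest.raises(ValueError):
            rs.determine_sdl({1.0: [True] * 5, 2.0: [True] * 4})

    @given(st.integers(0, 19))
    def test_adding_detections_never_raises_sdl(self, k):
        base = {1.0: [True] * k + [False] * (20 - k), 2.0: [True] * 20}
        more = {1.0: [True] * min(k + 1, 20) + [False] * (20 - min(k + 1, 20)), 2.0: [True] * 20}
        a, b = rs.determine_sdl(base), rs.determine_sdl(more)
        assert b <= a
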