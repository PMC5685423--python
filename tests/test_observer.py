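"""Model-observer components: front end, registration, shift-and-add,
4AFC decision, and trial dispatch."""

import dataclasses

import numpy as np
import pytest

import perisr as P
from perisr.errors import (
    ConfigurationError,
    ParameterError,
    UndefinedCorrelationError,
    UsageError,
)
from perisr.observer import _choose, decide_4afc, front_end


class TestFrontEnd:
    def test_identity_with_degenerate_params(self, rng):
        img = rng.random((40, 40)) * 40 + 45
        par = P.ObserverParams(blur_sigma=0.0, noise_sd=0.0)
        out = front_end(img, par, 0)
        assert np.array_equal(out, img)

    def test_noise_variance_matches(self):
        par = P.ObserverParams(blur_sigma=0.0, noise_sd=3.0)
        flat = np.full((320, 320), 45.0)  # ~1e5 pixels
        out = front_end(flat, par, 42)
        assert np.var(out - flat) == pytest.approx(9.0, rel=0.05)

    def test_blur_preserves_interior_mean(self, rng):
        par = P.ObserverParams(blur_sigma=3.0, noise_sd=0.0)
        img = rng.random((80, 80)) + 50.0
        out = front_end(img, par, 0)
        interior = slice(20, 60)
        assert out[interior, interior].mean() == pytest.approx(
            img[interior, interior].mean(), rel=1e-3)

    def test_negative_params_rejected(self):
        with pytest.raises(ParameterError):
            P.ObserverParams(blur_sigma=-1.0)
        with pytest.raises(ParameterError):
            P.ObserverParams(noise_sd=-0.1)
        with pytest.raises(ParameterError):
            P.ObserverParams(strategy="telepathy")


class TestEstimateShift:
    def test_identical_frames_zero_shift(self, rng):
        a = rng.normal(size=(64, 64))
        est = P.estimate_shift(a, a)
        assert est.shift[0] == pytest.approx(0.0, abs=1e-12)
        assert est.shift[1] == pytest.approx(0.0, abs=1e-12)
        assert est.confidence == pytest.approx(1.0)

    @pytest.mark.parametrize("offset", [(1, 0), (0, 3), (2, 3), (-4, 5)])
    def test_integer_translation_recovered_exactly(self, offset, rng):
        a = rng.normal(size=(64, 64))
        drow, dcol = offset
        b = np.roll(a, (drow, dcol), axis=(0, 1))
        est = P.estimate_shift(a, b, arcmin_per_pixel=1.0)
        assert est.shift[0] == pytest.approx(dcol, abs=1e-9)
        assert est.shift[1] == pytest.approx(-drow, abs=1e-9)
        assert est.confidence == pytest.approx(1.0)

    def test_subpixel_translation_approximate(self):
        # smooth pattern shifted by a fractional amount via Fourier phase
        y, x = np.mgrid[0:64, 0:64]
        a = np.sin(2 * np.pi * x / 11.0) + np.cos(2 * np.pi * y / 7.0)
        import scipy.fft as sfft
        shift = (0.0, 1.4)  # columns
        ramp = np.exp(-2j * np.pi * (np.fft.fftfreq(64)[:, None] * shift[0]
                                     + np.fft.rfftfreq(64)[None, :] * shift[1]))
        b = sfft.irfft2(sfft.rfft2(a) * ramp, s=a.shape)
        est = P.estimate_shift(a, b)
        assert est.shift[0] == pytest.approx(1.4, abs=0.2)

    def test_independent_noise_low_confidence(self):
        rng = np.random.default_rng(0)
        confs = []
        for _ in range(100):
            a = rng.normal(size=(100, 100))
            b = rng.normal(size=(100, 100))
            confs.append(P.estimate_shift(a, b).confidence)
        assert max(confs) < 0.2

    def test_zero_variance_errors(self):
        with pytest.raises(UndefinedCorrelationError):
            P.estimate_shift(np.zeros((16, 16)), np.ones((16, 16)))

    def test_shape_mismatch(self):
        with pytest.raises(UsageError):
            P.estimate_shift(np.zeros((8, 8)), np.zeros((9, 9)))


class TestAccumulateSR:
    def test_zero_shifts_identity(self, rng):
        f = rng.random((32, 32))
        comp, counts = P.accumulate_sr([f, f, f], np.zeros((3, 2)))
        assert np.allclose(comp, f)
        assert np.all(counts == 3)

    def test_single_frame_identity(self, rng):
        f = rng.random((32, 32))
        comp, _ = P.accumulate_sr([f], np.zeros((1, 2)))
        assert np.allclose(comp, f)

    def test_mismatched_lengths(self, rng):
        with pytest.raises(UsageError):
            P.accumulate_sr([rng.random((8, 8))], np.zeros((2, 2)))

    def test_registration_aligns_translated_frames(self, rng):
        base = np.zeros((40, 40))
        base[18:22, 18:22] = 1.0
        # frame shifted 3 px right = target displaced dx=+3 arcmin (app=1)
        moved = np.roll(base, 3, axis=1)
        comp, _ = P.accumulate_sr([base, moved], [(0.0, 0.0), (3.0, 0.0)],
                                  arcmin_per_pixel=1.0)
        assert comp[20, 20] == pytest.approx(1.0, abs=1e-6)

    def test_motion_reveals_occluded_target_regions(self, display):
        """Behind a fixed density-0.75 mask, the registered multi-frame
        composite leaves far fewer target pixels never-seen than any
        single frame leaves occluded."""
        cond = P.condition("smooth-target/static-mask", 0.75)
        seq = P.compose_sequence(cond, 10.0, "upper-left", seed=21,
                                 display=display, direction="ccw")
        bg = display.background_luminance
        mid = 12
        # target-region pixel mask from an unmasked render, per frame
        clean = P.compose_sequence(P.condition("smooth-target/static-mask", 0.0),
                                   10.0, "upper-left", seed=21,
                                   display=display, direction="ccw")
        pos = seq.target_positions
        seen_any = None
        occluded_mid = None
        for i in range(seq.n_frames):
            tgt = np.asarray(clean.frames[i]) > bg + 1.0
            vis = np.asarray(seq.frames[i]) > bg + 1.0
            # register to middle frame by integer-pixel shift of indices
            dxy = pos[i] - pos[mid]
            dr = int(round(dxy[1] / display.arcmin_per_pixel))
            dc = int(round(-dxy[0] / display.arcmin_per_pixel))
            tgt_r = np.roll(tgt, (dr, dc), axis=(0, 1))
            vis_r = np.roll(vis, (dr, dc), axis=(0, 1))
            if seen_any is None:
                seen_any = np.zeros_like(vis_r)
                ref_tgt = np.roll(np.asarray(clean.frames[mid]) > bg + 1.0,
                                  (0, 0), axis=(0, 1))
            seen_any |= vis_r & tgt_r
            if i == mid:
                occluded_mid = 1.0 - vis[tgt].mean()
        never_seen = 1.0 - seen_any[ref_tgt].mean()
        assert occluded_mid > 0.5  # single frame mostly occluded
        assert never_seen < occluded_mid / 3.0


class TestDecide4AFC:
    def test_noiseless_composite_always_correct(self, display, quiet_observer):
        for ori in P.ORIENTATIONS:
            cond = P.condition("static-target/static-mask", 0.0)
            seq = P.compose_sequence(cond, 8.0, ori, seed=5, display=display)
            resp = P.simulate_trial(seq, quiet_observer, seed=5)
            assert resp.correct
            assert resp.chosen_orientation == ori

    def test_four_way_symmetry_of_decision_variables(self, display,
                                                     quiet_observer):
        """Rotating the gap through the four obliques permutes the
        decision-variable matrix identically (up to rasterization)."""
        names = list(P.ORIENTATIONS)
        cond = P.condition("static-target/static-mask", 0.0)
        M = np.zeros((4, 4))
        for i, ori in enumerate(names):
            seq = P.compose_sequence(cond, 8.0, ori, seed=13, display=display)
            M[i] = P.simulate_trial(seq, quiet_observer, seed=1).decision_variables
        # self-match dominates and is the same for every orientation
        assert np.allclose(np.diag(M), M.max(axis=1))
        assert np.ptp(np.diag(M)) < 0.02
        # the confusion structure is shared: each row is the same pattern
        # up to the relabeling that maps its true orientation to the others
        for i in range(1, 4):
            row_sorted = np.sort(M[i])
            assert np.allclose(row_sorted, np.sort(M[0]), atol=0.05)

    def test_flat_composite_uniform_choice(self, display):
        par = P.ObserverParams(blur_sigma=0, noise_sd=0, fixed_pattern_sd=0)
        flat = np.full((61, 61), display.background_luminance)
        counts = {o: 0 for o in P.ORIENTATIONS}
        for s in range(400):
            r = decide_4afc(flat, 4.0, (30.0, 30.0), par, s, display)
            counts[r.chosen_orientation] += 1
        freqs = np.array(list(counts.values())) / 400
        assert np.all(np.abs(freqs - 0.25) < 0.08)

    def test_tie_break_uniform_between_tied_maxima(self):
        dv = np.array([0.4, 0.4, 0.1, 0.0])
        picks = [_choose(dv, list("abcd"), np.random.default_rng(s))
                 for s in range(600)]
        frac_a = picks.count("a") / 600
        assert 0.4 < frac_a < 0.6
        assert set(picks) == {"a", "b"}

    def test_empty_window_errors(self, display):
        par = P.ObserverParams()
        with pytest.raises(UsageError):
            decide_4afc(np.zeros((10, 10)), 8.0, (5.0, 5.0), par, 0, display)

    def test_nonpositive_gap_errors(self, display):
        par = P.ObserverParams()
        with pytest.raises(ParameterError):
            decide_4afc(np.zeros((99, 99)), 0.0, (50.0, 50.0), par, 0, display)


class TestSimulateTrial:
    def test_determinism(self, display):
        cond = P.condition("smooth-target/updating-mask", 0.75)
        seq = P.compose_sequence(cond, 6.0, "lower-left", seed=9,
                                 display=display)
        par = P.ObserverParams(strategy="super_resolution")
        a = P.simulate_trial(seq, par, seed=4)
        b = P.simulate_trial(seq, par, seed=4)
        assert a.chosen_orientation == b.chosen_orientation
        assert np.array_equal(a.decision_variables, b.decision_variables)

    def test_prob_summation_equals_single_frame_when_noiseless(self, display):
        """On a static sequence with no internal noise every look is
        identical, so max-rule pooling and a single look decide alike."""
        cond = P.condition("static-target/static-mask", 0.5)
        seq = P.compose_sequence(cond, 7.0, "upper-right", seed=2,
                                 display=display)
        base = dict(blur_sigma=2.5, noise_sd=0.0, fixed_pattern_sd=0.0)
        r_sf = P.simulate_trial(seq, P.ObserverParams(strategy="single_frame",
                                                      **base), seed=1)
        r_ps = P.simulate_trial(seq, P.ObserverParams(strategy="prob_summation",
                                                      **base), seed=1)
        assert r_sf.chosen_orientation == r_ps.chosen_orientation
        assert np.allclose(r_sf.decision_variables, r_ps.decision_variables,
                           atol=1e-12)

    def test_unmasked_static_all_strategies_at_ceiling(self, display):
        """Far above threshold with no mask, every strategy is ~perfect."""
        cond = P.condition("static-target/static-mask", 0.0)
        rng = np.random.default_rng(0)
        for strategy in ("single_frame", "prob_summation", "super_resolution"):
            par = P.ObserverParams(strategy=strategy)
            n_ok = 0
            for _ in range(40):
                ori = list(P.ORIENTATIONS)[rng.integers(4)]
                s = int(rng.integers(2**31))
                seq = P.compose_sequence(cond, 12.0, ori, s, display=display)
                n_ok += P.simulate_trial(seq, par, s + 1).correct
            assert n_ok >= 38

    def test_misregistration_cannot_help(self, display):
        """SR with no motion knowledge on a moving target does no better
        than the same observer with oracle registration."""
        cond = P.condition("smooth-target/static-mask", 0.75)
        rng = np.random.default_rng(3)
        acc = {}
        for know in ("oracle", "none"):
            par = P.ObserverParams(strategy="super_resolution",
                                   motion_knowledge=know)
            n_ok = 0
            for _ in range(60):
                ori = list(P.ORIENTATIONS)[rng.integers(4)]
                s = int(rng.integers(2**31))
                seq = P.compose_sequence(cond, 8.0, ori, s, display=display)
                n_ok += P.simulate_trial(seq, par, s + 1).correct
            acc[know] = n_ok / 60
        assert acc["none"] <= acc["oracle"]

    def test_oracle_requires_path_metadata(self, display):
        cond = P.condition("static-target/static-mask", 0.5)
        seq = P.compose_sequence(cond, 8.0, "upper-left", seed=1,
                                 display=display)
        broken = dataclasses.replace(seq, target_positions=None)
        par = P.ObserverParams(strategy="super_resolution",
                               motion_knowledge="oracle")
        with pytest.raises(ConfigurationError):
            P.simulate_trial(broken, par, seed=0)


class TestLogisticResponder:
    def test_probability_formula(self):
        r = P.LogisticResponder(8.0, 2.0)
        assert r.p_correct(8.0) == pytest.approx(0.625)
        assert r.p_correct(100.0) == pytest.approx(1.0, abs=1e-6)
        assert r.p_correct(-100.0) == pytest.approx(0.25, abs=1e-6)

    def test_respond_matches_probability(self):
        r = P.LogisticResponder(8.0, 2.0)
        hits = sum(r.respond(None, 9.94, "upper-left", s) for s in range(4000))
        assert hits / 4000 == pytest.approx(0.794, abs=0.02)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ParameterError):
            P.LogisticResponder(8.0, 0.0)
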