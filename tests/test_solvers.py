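"""Recursive candidate selection (RAP/TRAP/FLEX) and wMNE reconstruction."""

import numpy as np
import pytest

from flexmusic import (
    LeadField,
    add_noise,
    apply_solver,
    build_smoothness_dictionary,
    colored_time_course,
    flex_music,
    load_estimate,
    music_oneshot,
    out_projector,
    rap_music,
    save_estimate,
    trap_music,
    wmne_reconstruct,
)


class TestOutProjector:
    def test_empty_gives_identity(self):
        assert np.allclose(out_projector(np.empty((5, 0))), np.eye(5))

    def test_unit_vector_gives_coordinate_projector(self):
        e1 = np.zeros(4)
        e1[0] = 1
        assert np.allclose(out_projector(e1), np.diag([0, 1, 1, 1]))

    def test_annihilation_and_idempotence(self):
        rng = np.random.default_rng(0)
        b = rng.standard_normal((5, 2))
        q = out_projector(b)
        # least-squares oracle: residual of projecting b onto its own span
        resid = b - b @ np.linalg.lstsq(b, b, rcond=None)[0]
        assert np.linalg.norm(q @ b) < 1e-10
        assert np.linalg.norm(resid) < 1e-10
        assert np.linalg.norm(q @ q - q) < 1e-10
        assert np.allclose(q, q.T)
        assert np.isclose(np.trace(q), 5 - 2)


def _noiseless_dipole(lead, j, t=20, seed=0):
    tc = np.sin(np.linspace(0, 3 * np.pi, t)) + 0.1
    return np.outer(lead.gain[:, j], tc)


class TestTrapMusic:
    def test_noiseless_single_dipole_exact(self, icosphere_forward):
        space, lead = icosphere_forward
        data = _noiseless_dipole(lead, 50)
        cs = trap_music(data, lead)
        assert len(cs) == 1
        assert cs.candidates[0].center_index == 50
        assert cs.candidates[0].order == 1
        assert cs.candidates[0].peak_score > 1 - 1e-9
        # exhaustive check: 50 is the unique localizer maximizer
        from flexmusic import data_covariance, decompose, localizer
        model = decompose(data_covariance(data))
        mu = localizer(model.projector, None, lead.gain)
        assert int(np.argmax(mu)) == 50

    def test_noiseless_two_dipoles_recovered(self, icosphere_forward):
        space, lead = icosphere_forward
        rng = np.random.default_rng(1)
        data = (
            np.outer(lead.gain[:, 10], rng.standard_normal(20))
            + np.outer(lead.gain[:, 150], rng.standard_normal(20))
        )
        cs = trap_music(data, lead)
        assert sorted(c.center_index for c in cs.candidates) == [10, 150]
        # residual subspace explains nothing further
        from flexmusic import data_covariance
        resid = cs.out_projector @ data_covariance(data) @ cs.out_projector
        assert np.trace(resid) < 1e-8 * np.trace(data_covariance(data))

    def test_pure_noise_yields_empty_candidates(self, icosphere_forward):
        """Median candidate count over 20 noise seeds is zero."""
        _, lead = icosphere_forward
        counts = []
        for s in range(20):
            rng = np.random.default_rng(s)
            noise = (rng.standard_normal((64, 64)) / 8.0) @ rng.standard_normal(
                (64, 20)
            )
            cs = trap_music(noise, lead)
            counts.append(len(cs))
            if len(cs) == 0:
                assert cs.stop_reason == "below_threshold"
        assert np.median(counts) == 0

    def test_all_zero_data_rejected(self, icosphere_forward):
        _, lead = icosphere_forward
        with pytest.raises(ValueError):
            trap_music(np.zeros((64, 20)), lead)

    def test_out_projector_annihilates_topographies(self, icosphere_forward):
        _, lead = icosphere_forward
        rng = np.random.default_rng(2)
        data = sum(
            np.outer(lead.gain[:, j], rng.standard_normal(20))
            for j in (5, 80, 130)
        )
        data, _ = add_noise(data, 50, rng)
        cs = trap_music(data, lead)
        assert len(cs) >= 1
        assert np.linalg.norm(cs.out_projector @ cs.topographies) < 1e-8


class TestFlexMusic:
    def test_noiseless_single_dipole_stays_order_one(
        self, icosphere_forward, icosphere_dictionary
    ):
        _, lead = icosphere_forward
        data = _noiseless_dipole(lead, 33)
        cs = flex_music(data, icosphere_dictionary)
        assert len(cs) == 1
        assert (cs.candidates[0].center_index, cs.candidates[0].order) == (33, 1)
        assert np.array_equal(
            np.flatnonzero(cs.candidates[0].patch_weights), [33]
        )

    def test_noiseless_patch_recovers_center_and_order(
        self, icosphere_forward, icosphere_dictionary
    ):
        _, lead = icosphere_forward
        w = icosphere_dictionary.operator(2)[:, 80]
        tc = np.cos(np.linspace(0, 4, 20)) + 0.2
        data = lead.gain @ np.outer(w, tc)
        cs = flex_music(data, icosphere_dictionary)
        assert len(cs) == 1
        assert (cs.candidates[0].center_index, cs.candidates[0].order) == (80, 2)
        assert cs.candidates[0].peak_score > 1 - 1e-9

    def test_noiseless_mixture_dipole_plus_patch(
        self, icosphere_forward, icosphere_dictionary
    ):
        _, lead = icosphere_forward
        rng = np.random.default_rng(3)
        w = icosphere_dictionary.operator(3)[:, 120]
        j = np.zeros((162, 20))
        j[10] = 5 * rng.standard_normal(20)
        j += 3 * np.outer(w / w.max(), rng.standard_normal(20))
        cs = flex_music(lead.gain @ j, icosphere_dictionary)
        found = {(c.center_index, c.order) for c in cs.candidates}
        assert found == {(10, 1), (120, 3)}

    def test_source_cov_accumulates_patch_columns(
        self, icosphere_forward, icosphere_dictionary
    ):
        _, lead = icosphere_forward
        w = icosphere_dictionary.operator(2)[:, 80]
        data = lead.gain @ np.outer(w, np.sin(np.linspace(0, 5, 20)) + 0.2)
        cs = flex_music(data, icosphere_dictionary)
        assert np.allclose(cs.source_cov_diag, w)
        s = cs.source_cov
        assert np.allclose(s, np.diag(w))

    def test_reduces_to_rap_music_with_max_order_one(self, icosphere_forward):
        space, lead = icosphere_forward
        d1 = build_smoothness_dictionary(lead, space, max_order=1)
        rng = np.random.default_rng(4)
        j = np.zeros((162, 20))
        for c in (20, 90, 140):
            j[c] = rng.uniform(1, 5) * rng.standard_normal(20)
        data, _ = add_noise(lead.gain @ j, 10, rng)
        a = flex_music(data, d1)
        b = rap_music(data, lead)
        assert [(c.center_index, c.order) for c in a.candidates] == [
            (c.center_index, c.order) for c in b.candidates
        ]
        assert np.allclose(a.topographies, b.topographies)
        assert a.stop_reason == b.stop_reason

    def test_high_snr_single_dipoles_never_pick_patches(
        self, icosphere_forward, icosphere_dictionary
    ):
        """Order > 1 selected in < 5% of 50 seeded single-dipole runs."""
        _, lead = icosphere_forward
        bad = 0
        for s in range(50):
            rng = np.random.default_rng(100 + s)
            c = int(rng.integers(162))
            j = np.zeros((162, 20))
            j[c] = rng.uniform(1, 10) * colored_time_course(20, 1.0, rng)
            data, _ = add_noise(lead.gain @ j, 100, rng)
            cs = flex_music(data, icosphere_dictionary)
            if any(cand.order > 1 for cand in cs.candidates):
                bad += 1
        assert bad <= 2

    def test_peak_history_nonincreasing_noiseless(
        self, icosphere_forward, icosphere_dictionary
    ):
        _, lead = icosphere_forward
        rng = np.random.default_rng(5)
        data = (
            np.outer(lead.gain[:, 10], rng.standard_normal(20))
            + np.outer(lead.gain[:, 150], rng.standard_normal(20))
        )
        cs = flex_music(data, icosphere_dictionary)
        peaks = cs.peak_history
        assert all(peaks[i] >= peaks[i + 1] - 1e-6 for i in range(len(peaks) - 1))


class TestMusicOneshot:
    def test_noiseless_dipole_in_mask(self, icosphere_forward):
        _, lead = icosphere_forward
        mu, mask = music_oneshot(_noiseless_dipole(lead, 42), lead)
        assert mask[42]
        assert np.isclose(mu[42], 1.0)

    def test_unattainable_criterion_empty_mask(self, icosphere_forward):
        _, lead = icosphere_forward
        rng = np.random.default_rng(0)
        data, _ = add_noise(_noiseless_dipole(lead, 42), 2, rng)
        _, mask = music_oneshot(data, lead, criterion=1 + 1e-9)
        assert not mask.any()

    def test_exact_column_scores_one(self, icosphere_forward):
        _, lead = icosphere_forward
        data = lead.gain[:, [7]]
        mu, _ = music_oneshot(data, lead)
        assert np.isclose(mu[7], 1.0)


class TestWmneReconstruct:
    def test_orthonormal_rows_minimum_norm_limit(self):
        rng = np.random.default_rng(0)
        l, _ = np.linalg.qr(rng.standard_normal((10, 4)))
        lead = LeadField(gain=l.T)  # 4 channels, 10 dipoles, orthonormal rows
        m = rng.standard_normal((4, 6))
        est = wmne_reconstruct(np.ones(10), lead, m, ridge=1e-14)
        assert np.allclose(est.currents, lead.gain.T @ m, atol=1e-6)

    def test_zero_data_gives_zero_estimate(self, icosphere_forward):
        _, lead = icosphere_forward
        est = wmne_reconstruct(np.ones(162), lead, np.zeros((64, 5)))
        assert not est.currents.any()

    def test_noiseless_data_fit_on_support(self, icosphere_forward):
        _, lead = icosphere_forward
        rng = np.random.default_rng(1)
        support = [3, 77, 150]
        j = np.zeros((162, 20))
        for c in support:
            j[c] = rng.standard_normal(20)
        m = lead.gain @ j
        s = np.zeros(162)
        s[support] = 1.0
        est = wmne_reconstruct(s, lead, m, ridge=1e-10)
        assert np.linalg.norm(lead.gain @ est.currents - m) < 1e-6 * np.linalg.norm(m)
        # rows off the support are exactly zero
        off = np.setdiff1d(np.arange(162), support)
        assert not est.currents[off].any()

    def test_all_zero_source_cov_warns(self, icosphere_forward):
        _, lead = icosphere_forward
        with pytest.warns(UserWarning, match="all zero"):
            est = wmne_reconstruct(np.zeros(162), lead, np.ones((64, 5)))
        assert not est.currents.any()


class TestApplySolver:
    def test_unknown_solver_rejected(self, icosphere_forward):
        _, lead = icosphere_forward
        with pytest.raises(ValueError, match="unknown solver"):
            apply_solver("eloreta", np.ones((64, 5)), lead)

    @pytest.mark.parametrize("name", ["trap", "rap", "flex", "music"])
    def test_estimate_shape_and_provenance(
        self, name, icosphere_forward, icosphere_dictionary
    ):
        _, lead = icosphere_forward
        data = _noiseless_dipole(lead, 100)
        est, cset = apply_solver(name, data, lead, icosphere_dictionary)
        assert est.currents.shape == (162, 20)
        if name != "music":
            assert len(cset) == 1
            assert cset.candidates[0].center_index == 100
            # reconstruction concentrates on the found dipole
            assert int(np.argmax(np.abs(est.currents).mean(axis=1))) == 100

    def test_estimate_roundtrip(self, tmp_path, icosphere_forward,
                                icosphere_dictionary):
        _, lead = icosphere_forward
        est, _ = apply_solver(
            "flex", _noiseless_dipole(lead, 11), lead, icosphere_dictionary
        )
        prefix = str(tmp_path / "est")
        save_estimate(prefix, est)
        currents, meta = load_estimate(prefix)
        assert np.allclose(currents, est.currents)
        assert meta["candidates"][0]["center_index"] == 11
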