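"""Block design, HRF and the synthetic cohort generator."""

import numpy as np
import pytest

import corticospinal as cs
from corticospinal.cohort import (
    EhiCoupling,
    TruthDistribution,
    clean_m1_series,
    simulate_group_summary,
)
from corticospinal.design import contra_m1, ipsi_m1, ipsi_shc, make_design
from corticospinal.hemodynamics import convolve_hrf, double_gamma_hrf


class TestDesign:
    def test_default_layout(self):
        d = make_design()
        assert d.n_trs == 187
        assert len(d.blocks("rest")) == 9
        assert len(d.task_blocks("RHM")) == 4
        assert len(d.task_blocks("LHM")) == 4
        assert all(n == 11 for _, n in d.blocks("rest"))
        # rest block length matches the protocol timing: 28.6 s / 2.6 s
        assert d.tr_seconds * 11 == pytest.approx(28.6)

    def test_tiny_design_onsets(self):
        d = make_design(tr_seconds=1.0, n_task_blocks=2, n_rest_blocks=3,
                        task_block_trs=2, rest_block_trs=2)
        assert d.onsets == (
            (0, 2, "rest"),
            (2, 2, "RHM"),
            (4, 2, "rest"),
            (6, 2, "LHM"),
            (8, 2, "rest"),
        )

    def test_alternation_starts_with_rhm(self):
        d = make_design()
        task_labels = [c for _, _, c in d.onsets if c != "rest"]
        assert task_labels == ["RHM", "LHM"] * 4

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_task_blocks": 0},
            {"n_rest_blocks": 8},
            {"task_block_trs": 0},
            {"n_task_blocks": 3, "n_rest_blocks": 4},
        ],
    )
    def test_invalid_configurations(self, kwargs):
        with pytest.raises(ValueError):
            make_design(**kwargs)

    def test_odd_blocks_allowed_without_strict_alternation(self):
        d = make_design(n_task_blocks=3, n_rest_blocks=4,
                        strict_alternation=False)
        assert len(d.blocks("RHM")) == 2
        assert len(d.blocks("LHM")) == 1

    def test_boxcar_and_rest_pairing(self):
        d = make_design()
        box = d.boxcar("RHM")
        assert box.sum() == 44  # 4 blocks x 11 TRs
        rests = d.rest_blocks_before("RHM")
        assert len(rests) == 4
        for (rs, rn), (ts, _) in zip(rests, d.task_blocks("RHM")):
            assert rs + rn == ts


class TestHrf:
    def test_unit_sum_and_shape(self):
        h = double_gamma_hrf(2.6)
        assert h.sum() == pytest.approx(1.0)
        assert h[0] == pytest.approx(0.0, abs=1e-6)
        assert np.argmax(h) in (1, 2)  # peak around 5-6 s at TR 2.6

    def test_matches_nilearn_canonical_shape(self):
        from nilearn.glm.first_level import spm_hrf

        tr = 2.6
        ours = double_gamma_hrf(tr)
        # nilearn samples its own grid; interpolate a finely sampled
        # reference onto ours
        fine = spm_hrf(tr, oversampling=260, time_length=33.0)
        t_fine = np.linspace(0, 33.0, fine.size)
        ref = np.interp(np.arange(ours.size) * tr, t_fine, fine)
        c = np.corrcoef(ours, ref)[0, 1]
        assert c > 0.999

    def test_convolution_is_causal(self):
        x = np.zeros(50)
        x[10] = 1.0
        out = convolve_hrf(x, 2.6)
        assert out.size == 50
        assert np.all(out[:10] == 0)


class TestSimulateParticipant:
    def test_noiseless_single_pathway_is_exact_scaling(self, default_design):
        truth = cs.ParticipantTruth(
            participant_id="p",
            w_direct_contra={"RHM": 0.9, "LHM": 0.7},
            w_direct_ipsi={"RHM": 0.0, "LHM": 0.0},
            w_indirect={"RHM": 0.0, "LHM": 0.0},
            a_contra={"RHM": 1.2, "LHM": 1.0},
            a_ipsi={"RHM": 0.0, "LHM": 0.0},
            noise_sd=0.0,
        )
        ts = cs.simulate_participant(truth, default_design, seed=0)
        for hand, w in (("RHM", 0.9), ("LHM", 0.7)):
            shc = ts.series(ipsi_shc(hand))
            m1 = ts.series(contra_m1(hand))
            assert shc == pytest.approx(w * m1, abs=1e-12)

    def test_noiseless_regression_recovers_truth(self, default_design):
        rng = np.random.default_rng(3)
        dist = TruthDistribution(noise_sd=0.0)
        truth = dist.draw(rng, "p")
        ts = cs.simulate_participant(truth, default_design, seed=1)
        m1 = clean_m1_series(truth, default_design)
        for hand in cs.HANDS:
            m1c, m1i = m1[contra_m1(hand)], m1[ipsi_m1(hand)]
            X = np.column_stack([m1c, m1i, m1c * m1i])
            y = ts.series(ipsi_shc(hand))
            # normal-equations oracle
            coef = np.linalg.solve(X.T @ X, X.T @ y)
            expected = [
                truth.w_direct_contra[hand],
                truth.w_direct_ipsi[hand],
                truth.w_indirect[hand],
            ]
            assert coef == pytest.approx(expected, abs=1e-9)

    def test_c5_control_carries_no_task_signal(self, default_design):
        dist = TruthDistribution(noise_sd=0.5)
        rng = np.random.default_rng(4)
        box = default_design.boxcar("RHM")
        within = 0
        n_seeds = 100
        for s in range(n_seeds):
            truth = dist.draw(rng, "p")
            ts = cs.simulate_participant(truth, default_design, seed=100 + s)
            y = ts.series("SHc_R_C5")
            import scipy.stats

            res = scipy.stats.linregress(box, y)
            within += abs(res.slope) < 3 * res.stderr
        assert within / n_seeds > 0.9

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            cs.ParticipantTruth(
                participant_id="p",
                w_direct_contra={"RHM": 1, "LHM": 1},
                w_direct_ipsi={"RHM": 0, "LHM": 0},
                w_indirect={"RHM": 0, "LHM": 0},
                a_contra={"RHM": 1, "LHM": 1},
                a_ipsi={"RHM": 0, "LHM": 0},
                noise_sd=-0.1,
            )

    def test_sign_constraints_enforced(self):
        with pytest.raises(ValueError):
            cs.ParticipantTruth(
                participant_id="p",
                w_direct_contra={"RHM": -0.2, "LHM": 1},
                w_direct_ipsi={"RHM": 0, "LHM": 0},
                w_indirect={"RHM": 0, "LHM": 0},
                a_contra={"RHM": 1, "LHM": 1},
                a_ipsi={"RHM": 0, "LHM": 0},
            )


class TestSimulateCohort:
    def test_determinism_bit_identical(self):
        a = cs.simulate_cohort(n_participants=4, seed=5)
        b = cs.simulate_cohort(n_participants=4, seed=5)
        for pa, pb in zip(a.participants, b.participants):
            assert np.array_equal(pa.values, pb.values)
        assert a.metadata.equals(b.metadata)

    def test_seed_changes_output(self):
        a = cs.simulate_cohort(n_participants=4, seed=5)
        b = cs.simulate_cohort(n_participants=4, seed=6)
        assert not np.array_equal(a.participants[0].values, b.participants[0].values)

    def test_perfect_coupling_gives_correlation_one(self):
        coupling = EhiCoupling(r=1.0, mean=0.0, sd=10.0)
        cohort = cs.simulate_cohort(n_participants=10, coupling=coupling, seed=7)
        w = [t.w_direct_contra["RHM"] for t in cohort.truth]
        r = np.corrcoef(w, cohort.metadata["ehi"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_large_n_hits_target_correlation(self):
        coupling = EhiCoupling(r=0.7, mean=0.0, sd=10.0)
        cohort = cs.simulate_cohort(n_participants=2000, coupling=coupling, seed=8)
        w = [t.w_direct_contra["RHM"] for t in cohort.truth]
        r = np.corrcoef(w, cohort.metadata["ehi"])[0, 1]
        assert r == pytest.approx(0.7, abs=0.05)

    def test_default_ehi_marginal(self):
        cohort = cs.simulate_cohort(n_participants=3000, seed=9)
        ehi = cohort.metadata["ehi"].to_numpy()
        assert np.all(ehi <= 100.0)
        # clipping at +100 pulls the mean slightly below the nominal 84
        assert 78 < ehi.mean() < 85
        assert 10 < ehi.std(ddof=1) < 14

    def test_overtight_coupling_rejected(self):
        with pytest.raises(ValueError):
            EhiCoupling(r=1.2)

    def test_zero_variance_weight_with_coupling_rejected(self):
        dist = TruthDistribution(w_direct_contra=(0.8, 0.0))
        with pytest.raises(ValueError):
            cs.simulate_cohort(n_participants=5, distribution=dist, seed=10)


class TestGroupSummaryGenerator:
    def test_determinism(self):
        a = simulate_group_summary(seed=3)
        b = simulate_group_summary(seed=3)
        assert a.equals(b)

    def test_null_world_has_no_coupling(self):
        df = simulate_group_summary(
            n_participants=5000, coefficients={}, noise_sd=1.0, seed=4
        )
        for factor in ("beta_contra", "slope_ipsi"):
            r = np.corrcoef(df[factor], df["response"])[0, 1]
            assert abs(r) < 0.05

    def test_large_n_coefficient_recovery(self):
        df = simulate_group_summary(n_participants=4000, noise_sd=0.6, seed=5)
        res = cs.fit_group_model(cs.MODEL_FULL, df)
        from corticospinal.cohort import GROUP_MODEL_COEFFICIENTS

        # response z-scoring rescales every coefficient by the same factor
        scale = res.params["interaction_contra"] / GROUP_MODEL_COEFFICIENTS[
            "interaction_contra"
        ]
        for term, coef in GROUP_MODEL_COEFFICIENTS.items():
            assert res.params[term] / scale == pytest.approx(coef, abs=0.06)
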