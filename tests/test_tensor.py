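import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dtipair import (
    DWIVolume,
    compute_scalar_maps,
    eigendecompose,
    fa_of,
    fit_tensor_loglinear,
    make_gradient_table,
    md_of,
    tskew_of,
)
from dtipair.tensor import DiffusionTensorField

E3 = 1e-3


def forward_signal(D, gtab, s0=1000.0):
    """Closed-form single-tensor signal: the oracle for every fit test."""
    quad = np.einsum("vi,ij,vj->v", gtab.bvecs, D, gtab.bvecs)
    return s0 * np.exp(-gtab.bvals * quad)


def random_spd(rng, lo=0.1e-3, hi=2.5e-3):
    evals = np.sort(rng.uniform(lo, hi, 3))[::-1]
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    return q @ np.diag(evals) @ q.T


class TestLogLinearFit:
    def _fit_single(self, D, gtab, s0=1000.0):
        sig = forward_signal(D, gtab, s0).reshape(1, 1, 1, -1)
        dwi = DWIVolume(signal=sig, gtab=gtab)
        field = fit_tensor_loglinear(dwi)
        return field.as_matrices()[0, 0, 0]

    def test_recovers_diagonal_tensor(self, gtab32):
        D = np.diag([1.7 * E3, 0.4 * E3, 0.3 * E3])
        np.testing.assert_allclose(self._fit_single(D, gtab32), D, atol=1e-9)

    def test_isotropic_tensor_has_no_off_diagonals(self, gtab32):
        D = 0.8 * E3 * np.eye(3)
        fit = self._fit_single(D, gtab32)
        off = fit[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() <= 1e-12

    def test_all_b0_scheme_rejected(self):
        from dtipair import GradientTable

        with pytest.raises(ValueError):
            GradientTable(bvals=np.zeros(8), bvecs=np.zeros((8, 3)))

    def test_unit_scaling_leaves_signal_invariant(self, gtab32):
        """Multiplying b by c and dividing D by c predicts the same signal."""
        rng = np.random.default_rng(1)
        D = random_spd(rng)
        c = 2.5
        scaled = make_gradient_table(32, b=1000.0 * c, n_b0=1)
        np.testing.assert_allclose(
            forward_signal(D, gtab32), forward_signal(D / c, scaled), rtol=1e-12
        )

    def test_mask_with_nonpositive_b0_rejected(self, gtab32):
        sig = np.zeros((2, 1, 1, len(gtab32)))
        dwi = DWIVolume(signal=sig, gtab=gtab32)
        with pytest.raises(ValueError, match="non-positive"):
            fit_tensor_loglinear(dwi)

    def test_noise_robustness_fa_bias(self, gtab32):
        """Rician noise at sigma = s0/30: median FA bias stays under 0.05
        on the canonical white-matter tensor (Monte-Carlo, 500 voxels)."""
        from dtipair import rician_noise

        s0 = 1000.0
        evals = np.array([1.7, 0.4, 0.3]) * E3
        D = np.diag(evals)
        clean = forward_signal(D, gtab32, s0)
        rng = np.random.default_rng(2024)
        sig = rician_noise(np.tile(clean, (500, 1, 1, 1)), s0 / 30, rng)
        field = fit_tensor_loglinear(DWIVolume(signal=sig, gtab=gtab32))
        maps = compute_scalar_maps(field)
        fa_true = fa_of(*evals)
        assert abs(np.median(maps["FA"][maps.mask]) - fa_true) <= 0.05


class TestEigendecompose:
    def test_diagonal_case_sorted_descending(self):
        es = eigendecompose([3 * E3, 0, 0, 1 * E3, 0, 2 * E3])
        np.testing.assert_allclose(es.eigenvalues, [3 * E3, 2 * E3, 1 * E3])

    def test_rotation_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            D = random_spd(rng)
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            R = q @ D @ q.T
            comps = [R[0, 0], R[0, 1], R[0, 2], R[1, 1], R[1, 2], R[2, 2]]
            np.testing.assert_allclose(
                eigendecompose(comps).eigenvalues,
                np.sort(np.linalg.eigvalsh(D))[::-1],
                atol=1e-12,
            )

    def test_zero_tensor(self):
        es = eigendecompose(np.zeros(6))
        np.testing.assert_array_equal(es.eigenvalues, 0.0)
        assert not es.has_negative

    def test_orthonormal_eigenvectors(self):
        es = eigendecompose([1.7 * E3, 0.1 * E3, 0, 0.4 * E3, 0, 0.3 * E3])
        gram = es.eigenvectors.T @ es.eigenvectors
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-9)

    def test_negative_eigenvalue_flagged_not_clamped(self):
        es = eigendecompose([1 * E3, 0, 0, -0.2 * E3, 0, 0.5 * E3])
        assert es.has_negative
        assert es.eigenvalues.min() == pytest.approx(-0.2 * E3)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            eigendecompose([np.nan, 0, 0, 1, 0, 1])


class TestScalarFormulas:
    @pytest.mark.parametrize(
        "lams, expected",
        [((1 * E3, 1 * E3, 1 * E3), 1 * E3), ((3 * E3, 0, 0), 1 * E3), ((0, 0, 0), 0)],
    )
    def test_md(self, lams, expected):
        assert md_of(*lams) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "lams, expected, tol",
        [
            ((1 * E3, 1 * E3, 1 * E3), 0.0, 1e-12),
            ((0.9 * E3, 0, 0), 1.0, 1e-12),
            ((1.7 * E3, 0.2 * E3, 0.2 * E3), 0.8703, 1e-4),
            ((0, 0, 0), 0.0, 0),
        ],
    )
    def test_fa(self, lams, expected, tol):
        assert fa_of(*lams) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize(
        "lams, expected",
        [
            ((1 * E3, 1 * E3, 1 * E3), 0.0),
            ((2 * E3, 1 * E3, 0.0), 0.0),  # deviations symmetric about MD
            ((3 * E3, 0, 0), 2e-9),
        ],
    )
    def test_tskew(self, lams, expected):
        assert tskew_of(*lams) == pytest.approx(expected, abs=1e-18)

    @given(
        st.tuples(
            st.floats(0, 3e-3), st.floats(0, 3e-3), st.floats(0, 3e-3)
        ),
        st.permutations([0, 1, 2]),
    )
    def test_metrics_permutation_invariant(self, lams, perm):
        permuted = tuple(lams[i] for i in perm)
        assert md_of(*permuted) == pytest.approx(md_of(*lams), rel=1e-12, abs=1e-18)
        assert fa_of(*permuted) == pytest.approx(fa_of(*lams), rel=1e-9, abs=1e-12)
        assert tskew_of(*permuted) == pytest.approx(tskew_of(*lams), rel=1e-9, abs=1e-24)


class TestScalarMaps:
    def test_isotropic_phantom_fa_zero_md_trace_third(self, gtab32):
        D = 0.7 * E3 * np.eye(3)
        sig = np.tile(forward_signal(D, gtab32), (2, 2, 1, 1))
        field = fit_tensor_loglinear(DWIVolume(signal=sig, gtab=gtab32))
        maps = compute_scalar_maps(field)
        np.testing.assert_allclose(maps["FA"], 0.0, atol=1e-9)
        np.testing.assert_allclose(maps["MD"], 0.7 * E3, atol=1e-12)

    def test_regional_ad_matches_truth_eigenvalue(self, noiseless_maps, noiseless_subject, labels48):
        _, truth = noiseless_subject
        for rid in (1, 20, 48):
            lam1 = np.max(np.linalg.eigvalsh(np.array(truth["tensors"][str(rid)])))
            ad = noiseless_maps["AD"][labels48.labels == rid]
            np.testing.assert_allclose(ad, lam1, atol=1e-9)

    def test_map_invariants_hold(self, noiseless_maps):
        m = noiseless_maps
        inside = m.mask
        assert (m["AD"][inside] >= m["RD1"][inside] - 1e-15).all()
        assert (m["RD1"][inside] >= m["RD2"][inside] - 1e-15).all()
        assert ((m["FA"][inside] >= 0) & (m["FA"][inside] <= 1 + 1e-12)).all()
        np.testing.assert_allclose(
            m["MD"], (m["AD"] + m["RD1"] + m["RD2"]) / 3, atol=1e-12
        )

    def test_empty_mask_warns(self):
        field = DiffusionTensorField(
            components=np.zeros((2, 2, 2, 6)), mask=np.zeros((2, 2, 2), dtype=bool)
        )
        with pytest.warns(UserWarning, match="empty mask"):
            maps = compute_scalar_maps(field)
        assert all(np.all(maps[n] == 0) for n in maps.maps)
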