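"""Tract-profile geometry, FA, cleaning, resampling, weighted averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tractwise.profiles import (
    ProfileMatrix,
    Streamline,
    StreamlineBundle,
    TensorEigenvalues,
    TractLabel,
    bundle_profile,
    clean_streamline_bundle,
    fa_from_eigenvalues,
    gaussian_core_weights,
    read_profile_csv,
    read_streamline_text,
    resample_to_nodes,
    weighted_node_average,
    write_profile_csv,
)

eigval = st.floats(min_value=0.0, max_value=5.0, allow_nan=False)


class TestFA:
    @pytest.mark.parametrize(
        "lam, expected",
        [
            ((1.0, 1.0, 1.0), 0.0),             # isotropic tensor
            ((1.0, 0.0, 0.0), 1.0),             # maximally anisotropic
            ((1.7, 0.3, 0.2), 0.8358681096254011),  # closed-form oracle value
        ],
    )
    def test_known_values(self, lam, expected):
        assert fa_from_eigenvalues(lam) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fa_from_eigenvalues((0.0, 0.0, 0.0))

    def test_eigenvalues_sorted_canonically(self):
        e = TensorEigenvalues(0.2, 1.7, 0.3)
        assert (e.l1, e.l2, e.l3) == (1.7, 0.3, 0.2)

    @settings(derandomize=True, max_examples=200)
    @given(l1=eigval, l2=eigval, l3=eigval, c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, l1, l2, l3, c):
        lam = np.array([l1, l2, l3])
        if np.linalg.norm(lam) == 0:
            return
        fa = fa_from_eigenvalues(lam)
        assert fa_from_eigenvalues(c * lam) == pytest.approx(fa, abs=1e-12)
        assert 0.0 <= fa <= 1.0


def straight_line(offset=(0.0, 0.0, 0.0), n=10, length=1.0, samples=None):
    pts = np.zeros((n, 3))
    pts[:, 0] = np.linspace(0.0, length, n)
    pts += np.asarray(offset)
    return Streamline(pts, samples)


class TestResample:
    def test_equal_spacing_on_a_line(self):
        s = Streamline([[0, 0, 0], [1, 0, 0]])
        r = resample_to_nodes(s, 3)
        np.testing.assert_allclose(r.points[:, 0], [0.0, 0.5, 1.0])

    def test_endpoints_preserved_exactly(self):
        pts = np.cumsum(np.random.default_rng(0).normal(size=(20, 3)), axis=0)
        r = resample_to_nodes(Streamline(pts), 37)
        np.testing.assert_array_equal(r.points[0], pts[0])
        np.testing.assert_array_equal(r.points[-1], pts[-1])

    def test_constant_samples_stay_constant(self):
        s = straight_line(n=7, samples=np.full(7, 0.42))
        r = resample_to_nodes(s, 13)
        np.testing.assert_allclose(r.samples, 0.42)

    def test_linear_samples_interpolate_exactly(self):
        # scalar linear in arc length -> resampled values at quarter points
        s = straight_line(n=11, samples=np.linspace(0.2, 0.6, 11))
        r = resample_to_nodes(s, 5)
        np.testing.assert_allclose(r.samples, [0.2, 0.3, 0.4, 0.5, 0.6], atol=1e-12)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            resample_to_nodes(Streamline([[1, 1, 1], [1, 1, 1]]), 5)


def tight_bundle(n=19, spread=0.01, seed=0, n_pts=10):
    rng = np.random.default_rng(seed)
    return [
        straight_line(offset=(0.0, rng.normal(0.0, spread), rng.normal(0.0, spread)), n=n_pts)
        for _ in range(n)
    ]


class TestCleaning:
    def test_identical_streamlines_all_retained(self):
        b = StreamlineBundle("t", [straight_line() for _ in range(20)])
        out = clean_streamline_bundle(b)
        assert len(out) == 20

    def test_single_gross_outlier_removed(self):
        spread = 0.01
        lines = tight_bundle(19, spread)
        outlier = straight_line(offset=(0.0, 50 * spread, 0.0))
        out = clean_streamline_bundle(StreamlineBundle("t", lines + [outlier]))
        assert len(out) == 19
        assert all(s.points[0, 1] < 0.1 for s in out.streamlines)

    def test_iterative_removal_exposes_second_outlier(self):
        spread = 0.01
        lines = tight_bundle(19, spread)
        far = straight_line(offset=(0.0, 60 * spread, 0.0))
        near = straight_line(offset=(0.0, 12 * spread, 0.0))
        out = clean_streamline_bundle(StreamlineBundle("t", lines + [near, far]))
        assert len(out) == 19

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        lines = tight_bundle(15, 0.3, seed=3) + [straight_line(offset=(0, 5, 0))]
        once = clean_streamline_bundle(StreamlineBundle("t", lines))
        twice = clean_streamline_bundle(once)
        assert [id(s) for s in once.streamlines] == [id(s) for s in twice.streamlines]

    def test_overlong_streamline_removed(self):
        lines = tight_bundle(19, 0.01)
        long = straight_line(length=50.0)
        out = clean_streamline_bundle(StreamlineBundle("t", lines + [long]))
        assert len(out) == 19

    def test_small_bundle_warns_not_errors(self):
        b = StreamlineBundle("t", [straight_line(), straight_line()])
        with pytest.warns(UserWarning, match="reduced"):
            out = clean_streamline_bundle(b)
        assert len(out) == 2


class TestWeightedAverage:
    def test_equal_weights_are_the_mean(self):
        out = weighted_node_average(np.array([[0.4], [0.6]]), np.ones((2, 1)))
        assert out[0] == pytest.approx(0.5)

    def test_degenerate_single_weight(self):
        samples = np.array([[0.1, 0.2], [0.7, 0.9]])
        w = np.array([[1.0, 1.0], [0.0, 0.0]])
        np.testing.assert_allclose(weighted_node_average(samples, w), [0.1, 0.2])

    def test_hand_computed_gaussian_weighting(self):
        # 3 streamlines at y = 0, 0.1, 0.4; core mean y = 1/6 approx 0.1667
        lines = [
            straight_line(offset=(0, 0.0, 0), samples=np.full(10, 0.3)),
            straight_line(offset=(0, 0.1, 0), samples=np.full(10, 0.5)),
            straight_line(offset=(0, 0.4, 0), samples=np.full(10, 0.7)),
        ]
        res = [resample_to_nodes(s, 10) for s in lines]
        w = gaussian_core_weights(res)
        d = np.array([1 / 6, 1 / 15, 0.4 - 1 / 6])
        bw = d.std()
        expect_w = np.exp(-0.5 * (d / bw) ** 2)
        np.testing.assert_allclose(w[:, 0], expect_w, atol=1e-12)
        samples = np.stack([s.samples for s in res])
        got = weighted_node_average(samples, w)
        expected = (expect_w @ np.array([0.3, 0.5, 0.7])) / expect_w.sum()
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_all_zero_weights_named_node(self):
        with pytest.raises(ValueError, match="node.*2"):
            weighted_node_average(np.ones((2, 2)), np.array([[1.0, 0.0], [1.0, 0.0]]))

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_output_bounded_by_inputs(self, seed):
        rng = np.random.default_rng(seed)
        samples = rng.random((4, 6))
        weights = rng.random((4, 6))
        out = weighted_node_average(samples, weights)
        assert np.all(out >= samples.min(axis=0) - 1e-12)
        assert np.all(out <= samples.max(axis=0) + 1e-12)


class TestLabelsAndIO:
    def test_posterior_has_30_nodes(self):
        assert TractLabel("left", "posterior").n_nodes == 30
        assert TractLabel("right", "direct").n_nodes == 100

    def test_profile_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        from tests.conftest import profile_matrix_from_array

        pm = profile_matrix_from_array(rng.random((5, 30)), segment="posterior")
        path = tmp_path / "p.csv"
        write_profile_csv(pm, path)
        back = read_profile_csv(path, TractLabel("left", "posterior"), pm.subject_ids)
        np.testing.assert_allclose(back.data.to_numpy(), pm.data.to_numpy(), atol=1e-9)

    def test_node_count_mismatch_rejected(self, tmp_path):
        from tests.conftest import profile_matrix_from_array

        pm = profile_matrix_from_array(np.full((3, 30), 0.5), segment="posterior")
        path = tmp_path / "p.csv"
        write_profile_csv(pm, path)
        with pytest.raises(ValueError, match="node columns"):
            read_profile_csv(path, TractLabel("left", "direct"))

    def test_streamline_text_reader(self, tmp_path):
        path = tmp_path / "lines.txt"
        path.write_text("0 0 0 0.4\n1 0 0 0.6\n\n0 1 0\n1 1 0\n2 1 0\n")
        lines = read_streamline_text(path)
        assert len(lines) == 2
        np.testing.assert_allclose(lines[0].samples, [0.4, 0.6])
        assert lines[1].samples is None
        assert lines[1].points.shape == (3, 3)


class TestBundleProfile:
    def test_constant_samples_give_constant_profile(self):
        lines = [straight_line(n=12, samples=np.full(12, 0.47)) for _ in range(5)]
        prof = bundle_profile(StreamlineBundle("t", lines), TractLabel("left", "posterior"))
        np.testing.assert_allclose(prof.values, 0.47, atol=1e-12)

    def test_orientation_flips_to_anchor(self):
        samples = np.linspace(0.2, 0.8, 30)
        fwd = straight_line(n=30, samples=samples)
        rev = Streamline(fwd.points[::-1].copy(), samples[::-1].copy())
        prof_f = bundle_profile(
            StreamlineBundle("t", [fwd, fwd]), TractLabel("left", "posterior"), anchor=(0, 0, 0), clean=False
        )
        prof_r = bundle_profile(
            StreamlineBundle("t", [rev, rev]), TractLabel("left", "posterior"), anchor=(0, 0, 0), clean=False
        )
        np.testing.assert_allclose(prof_f.values, prof_r.values, atol=1e-12)
        assert prof_f.values[0] < prof_f.values[-1]
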