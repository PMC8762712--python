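"""Filter-pair geometry, iso-response curvature, entropy, end-stopping."""

import numpy as np
import pytest

from fpnets import (Network, StimulusResponseSummary, build_pyrblocknet,
                    curvature_coefficient, end_stopping_degree,
                    feature_map_entropy, fp_transform, gamma_angle,
                    iso_response_contour, make_square_stimulus, neuron_census,
                    optimal_stimulus, orthogonal_to, pair_response)
from fpnets.fp_block import depthwise_filter, feature_product, instance_stats
from fpnets.neuron_analysis import census_frame, receptive_field


class TestGammaAngle:
    def test_parallel_pair_is_zero(self, rng):
        v = rng.standard_normal(9)
        assert gamma_angle((v, 2.5 * v)) == pytest.approx(0.0, abs=1e-7)

    def test_orthogonal_pair_is_half_pi(self):
        v = np.array([1.0, 0, 0, 0])
        g = np.array([0, 1.0, 0, 0])
        assert gamma_angle((v, g)) == pytest.approx(np.pi / 2)

    def test_known_quarter_pi(self):
        v = np.array([1.0, 0.0, 0.0])
        g = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        assert gamma_angle((v, g)) == pytest.approx(np.pi / 4)

    def test_zero_filter_reported_missing(self):
        assert np.isnan(gamma_angle((np.zeros(9), np.ones(9))))


class TestOrthogonalTo:
    def test_two_dimensional_case_is_forced(self):
        z = orthogonal_to(np.array([1.0, 0.0]), seed=0)
        assert abs(abs(z[1]) - 1.0) < 1e-12 and abs(z[0]) < 1e-12

    @pytest.mark.parametrize("seed", range(9))
    def test_repeated_draws_all_orthogonal_unit(self, seed, rng):
        x = rng.standard_normal(9)
        z = orthogonal_to(x, seed=seed)
        assert abs(z @ (x / np.linalg.norm(x))) < 1e-10
        assert np.linalg.norm(z) == pytest.approx(1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            orthogonal_to(np.zeros(4))


class TestOptimalStimulus:
    def test_equal_pair_returns_normalized_filter(self, rng):
        v = rng.standard_normal(9)
        np.testing.assert_allclose(optimal_stimulus((v, v)), v / np.linalg.norm(v))

    def test_orthogonal_pair_bisector(self):
        x = optimal_stimulus((np.array([1.0, 0.0]), np.array([0.0, 1.0])))
        np.testing.assert_allclose(x, np.array([1.0, 1.0]) / np.sqrt(2))

    def test_beats_all_probed_unit_directions(self):
        v, g = np.array([1.0, 0.0]), np.array([0.6, 0.8])
        x_opt = optimal_stimulus((v, g))
        best = pair_response((v, g), x_opt)
        angles = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        probes = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        assert (pair_response((v, g), probes) <= best + 1e-9).all()


class TestIsoResponseContour:
    def test_gamma_zero_contour_is_straight(self, rng):
        v = rng.standard_normal(9)
        contour = iso_response_contour((v, v), level=1.0)
        ys = contour.points[:, 1]
        assert np.ptp(ys) < 1e-9  # constant y: a line parallel to the t axis

    def test_orthogonal_pair_matches_product_closed_form(self):
        # in the bisector frame: y^2 cos^2(g/2) - t^2 sin^2(g/2) = c
        v, g = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        contour = iso_response_contour((v, g), level=1.0, t_max=0.4, n_t=81)
        t, y = contour.points[:, 0], contour.points[:, 1]
        lhs = y ** 2 * np.cos(np.pi / 4) ** 2 - t ** 2 * np.sin(np.pi / 4) ** 2
        np.testing.assert_allclose(lhs, 1.0, atol=5e-3)

    def test_contour_symmetric_in_t(self):
        v, g = np.array([1.0, 0.0]), np.array([0.5, np.sqrt(0.75)])
        contour = iso_response_contour((v, g), level=0.5, t_max=0.3, n_t=61)
        pts = {round(t, 9): y for t, y in contour.points}
        for t, y in contour.points:
            assert pts[round(-t, 9)] == pytest.approx(y, rel=1e-6)

    def test_unreachable_level_gives_empty_contour(self):
        v = np.array([1.0, 0.0])
        contour = iso_response_contour((v, v), level=1e9, y_max=2.0)
        assert contour.points.size == 0


class TestCurvature:
    def test_too_few_points_reported_missing(self):
        from fpnets.neuron_analysis import ContourSample
        contour = ContourSample(1.0, np.array([[0.1, 1.0], [0.2, 1.1]]))
        assert curvature_coefficient(contour) is None

    def test_closed_form_oracle_and_monotonicity(self):
        c = 0.25
        fitted = []
        for gam in (np.pi / 6, np.pi / 4, np.pi / 3, np.pi / 2):
            pair = (np.array([1.0, 0.0]), np.array([np.cos(gam), np.sin(gam)]))
            contour = iso_response_contour(pair, c, t_max=0.12, n_t=61)
            a = curvature_coefficient(contour, window=0.1)
            a_true = np.sin(gam / 2) ** 2 / (2 * np.sqrt(c) * np.cos(gam / 2))
            assert a == pytest.approx(a_true, rel=0.01)
            fitted.append(a)
        assert all(a1 < a2 for a1, a2 in zip(fitted, fitted[1:]))


class TestFeatureMapEntropy:
    def test_constant_gives_zero_bits(self):
        assert feature_map_entropy(np.full(100, 3.3)) == 0.0

    def test_uniform_over_32_bins_gives_five_bits(self):
        samples = np.repeat((np.arange(32) + 0.5) / 32, 8)
        assert feature_map_entropy(samples, bins=32) == pytest.approx(5.0)

    def test_two_equal_bins_give_one_bit(self):
        samples = np.array([0.1] * 50 + [0.9] * 50)
        assert feature_map_entropy(samples, bins=2) == pytest.approx(1.0)

    def test_bounded_and_scale_invariant(self, rng):
        x = rng.random(1000)
        h = feature_map_entropy(x, bins=32)
        assert 0 <= h <= 5.0
        assert feature_map_entropy(17.3 * x, bins=32) == pytest.approx(h)


class TestEndStoppingDegree:
    def _summary(self, m0, m1, m2, pol="bright"):
        return StimulusResponseSummary(m0, m1, m2, pol)

    def test_ideal_end_stopped(self):
        deg, cls = end_stopping_degree(self._summary(0, 0, 1.0),
                                       self._summary(0, 0, 0.5, "dark"), 1e-4)
        assert deg == pytest.approx(1.0) and cls == "end_stopped_spectrum"

    def test_equal_edge_and_corner_response(self):
        deg, cls = end_stopping_degree(self._summary(0, 0.8, 0.8),
                                       self._summary(0, 0.1, 0.1, "dark"), 1e-4)
        assert deg == pytest.approx(0.0) and cls == "end_stopped_spectrum"

    def test_zero_d_responder_and_non_responder(self):
        _, cls = end_stopping_degree(self._summary(0.9, 0.1, 0.2),
                                     self._summary(0, 0, 0, "dark"), 1e-4)
        assert cls == "zero_d_responder"
        _, cls = end_stopping_degree(self._summary(0, 0, 0),
                                     self._summary(0, 0, 0, "dark"), 1e-4)
        assert cls == "non_responder"

    def test_edge_without_corner_classed_separately(self):
        deg, cls = end_stopping_degree(self._summary(0, 0.5, 0),
                                       self._summary(0, 0, 0, "dark"), 1e-4)
        assert deg is None and cls == "edge_responder"

    def test_degree_never_exceeds_one(self, rng):
        for _ in range(50):
            m = rng.random(6)
            deg, cls = end_stopping_degree(self._summary(*m[:3]),
                                           self._summary(*m[3:], "dark"), 1e-4)
            if deg is not None:
                assert deg <= 1.0

    def test_edge_filter_pair_scores_one_on_square(self):
        """Horizontal-edge x vertical-edge product responds only at corners."""
        v_filt = np.array([[-1, -1, -1], [0, 0, 0], [1, 1, 1]], float)
        g_filt = v_filt.T.copy()
        summaries = {}
        for pol in ("bright", "dark"):
            stim = make_square_stimulus(16, 8, pol, radius=1)
            rv = depthwise_filter(stim.image, v_filt)
            rg = depthwise_filter(stim.image, g_filt)
            t2 = feature_product(rv, rg, instance_stats(rv), instance_stats(rg))
            m = {k: float(t2[msk].mean()) for k, msk in stim.masks.items()}
            summaries[pol] = StimulusResponseSummary(m["0d"], m["1d"], m["2d"], pol)
        thr = 1e-4 * max(s.mean_2d for s in summaries.values())
        deg, cls = end_stopping_degree(summaries["bright"], summaries["dark"], thr)
        assert deg == pytest.approx(1.0) and cls == "end_stopped_spectrum"


class TestReceptiveField:
    def test_first_fp_block_of_cifar_net(self):
        spec = fp_transform(build_pyrblocknet(3), q=1.0)
        radius, stride = receptive_field(spec, 0, 0)
        assert (radius, stride) == (2, 1)  # stem 3x3 + expansion 1x1 + dw 3x3

    def test_stride_accumulates_across_stacks(self):
        spec = fp_transform(build_pyrblocknet(3), q=1.0)
        assert receptive_field(spec, 1, 0)[1] == 2
        assert receptive_field(spec, 2, 0)[1] == 4


@pytest.fixture(scope="module")
def census_random_init(shape_dataset):
    spec = fp_transform(build_pyrblocknet(3), q=1.0)
    net = Network(spec, seed=3)
    return net, neuron_census(net, shape_dataset[0][:64], with_curvature=False)


class TestNeuronCensus:
    def test_census_length_is_total_fp_unit_count(self, census_random_init):
        net, reports = census_random_init
        expected = sum(layer.n_pairs for _, _, layer in net.fp_blocks())
        assert len(reports) == expected == 16 + 32 + 64

    def test_gammas_in_range_and_depths_recorded(self, census_random_init):
        _, reports = census_random_init
        gammas = np.array([r.gamma for r in reports])
        assert ((gammas >= 0) & (gammas <= np.pi)).all()
        # stem(1) + [fp:3, pyr:2, pyr:2] per stack; expansion conv included
        assert sorted({r.depth for r in reports}) == [2, 9, 16]

    def test_census_deterministic(self, census_random_init, shape_dataset):
        net, reports = census_random_init
        again = neuron_census(net, shape_dataset[0][:64], with_curvature=False)
        a, b = census_frame(reports), census_frame(again)
        assert a.equals(b)

    def test_network_without_fp_blocks_yields_empty_census(self, shape_dataset):
        net = Network(build_pyrblocknet(1), seed=0)
        assert neuron_census(net, shape_dataset[0][:8]) == []
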