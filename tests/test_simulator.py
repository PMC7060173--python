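"""Generative model: molecule patterns, labeling, blinking, artifacts."""

import numpy as np
import pytest
from scipy import stats

from clasta import (
    ArtifactSpec,
    BlinkModel,
    ConfigurationError,
    LabelingSpec,
    PatternSpec,
    RegionOfInterest,
    Scenario,
    apply_chromatic_aberration,
    apply_drift,
    apply_localization_error,
    add_unspecific_and_background,
    assign_labels,
    place_molecules,
    simulate_blinking,
    simulate_experiment,
)
from clasta.simulate import scenario_from_dict, scenario_to_dict

from conftest import make_set

ROI_10UM = RegionOfInterest.square(10_000.0)


class TestPlaceMolecules:
    def test_oligomer_counting(self, unit_roi, rng):
        pattern = PatternSpec(kind="oligomer", n_mer=2, molecule_density=10.0)
        pts = place_molecules(pattern, unit_roi, rng)  # 1 um^2 -> 10 molecules
        assert len(pts) == 10
        uniq, counts = np.unique(pts, axis=0, return_counts=True)
        assert len(uniq) == 5 and np.all(counts == 2)

    @pytest.mark.parametrize("n_mer", [1, 2, 3, 4])
    def test_total_count_is_multiple_of_n_mer(self, n_mer, rng):
        pattern = PatternSpec(kind="oligomer", n_mer=n_mer, molecule_density=75.0)
        pts = place_molecules(pattern, ROI_10UM, rng)
        assert len(pts) == n_mer * (7500 // n_mer)

    def test_circular_domains_containment(self, rng):
        pattern = PatternSpec(kind="circular_domains", domain_radius=100.0,
                              domain_density=10.0, fraction_in_domains=1.0)
        pts = place_molecules(pattern, ROI_10UM, rng)
        # every molecule within domain_radius of some molecule-bearing center
        from scipy.spatial import cKDTree
        d, _ = cKDTree(pts).query(pts, k=2)
        assert np.all(d[:, 1] <= 2 * pattern.domain_radius + 1e-9)

    def test_mean_occupancy_of_domains(self, rng):
        # 7500 molecules, fraction 0.6, 1000 domains -> mean 4.5 per domain
        pattern = PatternSpec(kind="circular_domains", domain_radius=100.0,
                              domain_density=10.0, fraction_in_domains=0.6,
                              molecule_density=75.0)
        totals = [len(place_molecules(pattern, ROI_10UM, rng)) for _ in range(20)]
        in_domain = np.mean(totals) - 0.4 * 7500  # outside part is deterministic
        assert in_domain / 1000 == pytest.approx(4.5, rel=0.03)

    def test_random_equals_monomer_distribution(self, rng):
        from scipy.spatial import cKDTree
        a = place_molecules(PatternSpec(kind="random"), ROI_10UM, rng)
        b = place_molecules(PatternSpec(kind="oligomer", n_mer=1), ROI_10UM, rng)
        nn = lambda p: cKDTree(p).query(p, k=2)[0][:, 1]
        assert stats.ks_2samp(nn(a), nn(b)).pvalue > 0.01

    def test_csr_nearest_neighbor_law(self, rng):
        # CSR: cdf(r) = 1 - exp(-lambda * pi * r^2); use an inner margin to
        # avoid edge truncation of neighborhoods
        pts = place_molecules(PatternSpec(kind="random"), ROI_10UM, rng)
        from scipy.spatial import cKDTree
        lam = len(pts) / ROI_10UM.area
        inner = np.all((pts > 300) & (pts < 9700), axis=1)
        d = cKDTree(pts).query(pts[inner], k=2)[0][:, 1]
        res = stats.ks_1samp(d, lambda r: 1 - np.exp(-lam * np.pi * r**2))
        assert res.pvalue > 0.01

    def test_fraction_without_domains_is_error(self, rng):
        pattern = PatternSpec(kind="circular_domains", domain_density=0.0,
                              fraction_in_domains=0.5)
        with pytest.raises(ConfigurationError):
            place_molecules(pattern, ROI_10UM, rng)

    def test_rectangular_domains_fill_their_boxes(self, rng):
        pattern = PatternSpec(kind="rectangular_domains", rect_size=(80.0, 400.0),
                              domain_density=5.0, fraction_in_domains=1.0,
                              molecule_density=75.0)
        pts = place_molecules(pattern, ROI_10UM, rng)
        assert len(pts) == pytest.approx(7500, rel=0.1)  # Poisson occupancy


class TestLabeling:
    def test_balanced_binomial_split(self, rng):
        molecules = rng.uniform(0, 10_000, (10_000, 2))
        red, blue = assign_labels(molecules, LabelingSpec(1.0, 0.5), rng)
        assert len(red) + len(blue) == 10_000
        lo, hi = stats.binom.interval(0.99, 10_000, 0.5)
        assert lo <= len(red) <= hi

    def test_zero_efficiency(self, rng):
        red, blue = assign_labels(rng.uniform(0, 100, (500, 2)),
                                  LabelingSpec(0.0, 0.5), rng)
        assert len(red) == 0 and len(blue) == 0

    def test_reduced_labeling_efficiency(self, rng):
        red, blue = assign_labels(rng.uniform(0, 100, (10_000, 2)),
                                  LabelingSpec(0.4, 0.5), rng)
        lo, hi = stats.binom.interval(0.99, 10_000, 0.4)
        assert lo <= len(red) + len(blue) <= hi


class TestBlinking:
    def test_fixed_counts(self, unit_roi, rng):
        ls = simulate_blinking(rng.uniform(0, 1000, (5, 2)),
                               BlinkModel.fixed(3), unit_roi, rng)
        assert len(ls) == 15

    def test_every_label_detected_at_least_once(self, rng):
        for model in (BlinkModel.lognormal(1.1, 0.9), BlinkModel.geometric(2.0),
                      BlinkModel.from_table([1, 2, 5], [0.2, 0.5, 0.3])):
            counts = model.sample_detections(2000, rng)
            assert counts.min() >= 1

    def test_tenfold_mean_difference_between_channels(self, rng):
        # log-normal channels with a tenfold mean-detection ratio
        lo = BlinkModel.lognormal(1.5, 0.5).sample_detections(20_000, rng)
        hi = BlinkModel.lognormal(1.5 + np.log(10), 0.5).sample_detections(20_000, rng)
        assert hi.mean() / lo.mean() == pytest.approx(10.0, rel=0.15)

    @pytest.mark.parametrize("assignment", ["uniform", "burst"])
    def test_frames_within_movie(self, unit_roi, rng, assignment):
        model = BlinkModel.lognormal(1.1, 0.9, frame_assignment=assignment,
                                     n_frames=500)
        ls = simulate_blinking(rng.uniform(0, 1000, (200, 2)), model, unit_roi, rng)
        assert ls.frame.min() >= 1 and ls.frame.max() <= 500


class TestArtifacts:
    def test_zero_sigma_is_identity(self, unit_roi, rng):
        ls = make_set(rng.uniform(0, 1000, (100, 2)), unit_roi)
        out = apply_localization_error(ls, 0.0, rng)
        np.testing.assert_array_equal(out.xy, ls.xy)

    def test_localization_error_spread_and_isotropy(self, unit_roi, rng):
        n = 10_000
        xy = rng.uniform(400, 600, (n, 2))
        out = apply_localization_error(make_set(xy, unit_roi), 30.0, rng)
        dx, dy = out.x - xy[:, 0], out.y - xy[:, 1]
        assert dx.std() == pytest.approx(30.0, rel=0.05)
        assert dy.std() == pytest.approx(30.0, rel=0.05)
        assert abs(np.corrcoef(dx, dy)[0, 1]) < 0.05

    def test_unspecific_and_background_counts(self, rng):
        red = make_set([(5000, 5000)], ROI_10UM, "red")
        blue = make_set([(5000, 5000)], ROI_10UM, "blue")
        fixed = BlinkModel.fixed(1)
        out_r, out_b = add_unspecific_and_background(
            red, blue, ArtifactSpec(unspecific_label_density=5.0,
                                    background_density_red=1.0,
                                    background_density_blue=2.0,
                                    background_blink=fixed,
                                    localization_error_sigma=0.0),
            ROI_10UM, rng, blink_red=fixed, blink_blue=fixed)
        # labels: Poisson(500) each; background: Poisson(100) red, Poisson(200) blue
        lo_r, hi_r = stats.poisson.interval(0.9999, 600)
        lo_b, hi_b = stats.poisson.interval(0.9999, 700)
        assert lo_r <= len(out_r) - 1 <= hi_r
        assert lo_b <= len(out_b) - 1 <= hi_b
        # zero densities leave channels untouched
        same_r, same_b = add_unspecific_and_background(
            red, blue, ArtifactSpec.ideal(), ROI_10UM, rng)
        assert len(same_r) == 1 and len(same_b) == 1

    def test_drift_is_linear_in_frame(self, unit_roi):
        ls = make_set([(100, 100), (100, 100), (100, 100)], unit_roi,
                      frame=[1, 5000, 10_000])
        out = apply_drift(ls, (500.0, 0.0), 10_000)
        assert out.x[2] == pytest.approx(600.0)
        assert out.x[1] == pytest.approx(350.0)
        assert out.y[2] == pytest.approx(100.0)
        same = apply_drift(ls, (0.0, 0.0), 10_000)
        np.testing.assert_array_equal(same.xy, ls.xy)

    def test_chromatic_aberration_vector_field(self, unit_roi):
        roi = RegionOfInterest.square(5000.0)
        ls = make_set([(3500, 2500), (2500, 2500)], roi)
        out = apply_chromatic_aberration(ls, 0.06, (2500.0, 2500.0))
        assert out.x[0] == pytest.approx(3560.0)
        assert out.y[0] == pytest.approx(2500.0)
        assert out.x[1] == pytest.approx(2500.0)  # center is a fixed point


class TestSimulateExperiment:
    def test_ideal_scenario_composition(self):
        red, blue, truth = simulate_experiment(
            Scenario.ideal(PatternSpec(kind="random")), seed=1)
        assert len(truth) == 7500
        assert len(red) + len(blue) >= 7500  # every label blinks at least once
        assert red.channel_id == "red" and blue.channel_id == "blue"

    def test_realistic_scenario_has_extra_signal(self):
        ideal_red, _, _ = simulate_experiment(
            Scenario.ideal(PatternSpec(kind="random")), seed=1)
        real_red, _, truth = simulate_experiment(
            Scenario.realistic(PatternSpec(kind="random")), seed=1)
        assert len(truth) == 7500
        # 40% labeling loses specific signal but unspecific labels are added
        assert len(real_red) != len(ideal_red)

    def test_same_seed_is_bit_identical(self):
        s = Scenario.realistic(PatternSpec(kind="oligomer", n_mer=3))
        a_red, a_blue, a_truth = simulate_experiment(s, seed=99)
        b_red, b_blue, b_truth = simulate_experiment(s, seed=99)
        np.testing.assert_array_equal(a_red.xy, b_red.xy)
        np.testing.assert_array_equal(a_blue.frame, b_blue.frame)
        np.testing.assert_array_equal(a_truth, b_truth)

    def test_scenario_yaml_round_trip(self):
        s = Scenario.realistic(PatternSpec(kind="circular_domains",
                                           domain_radius=60.0))
        assert scenario_from_dict(scenario_to_dict(s)) == s
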