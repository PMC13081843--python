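import numpy as np
import pandas as pd
import pytest

import placenta3d as p3
from placenta3d.io import CenterlineTree
from placenta3d.metrics import (
    CATEGORIES,
    count_decidual_branches,
    envelopment,
    resample_centerline,
)

from conftest import make_spots


def norm_points(frame, xyz, channel="trophoblast"):
    return p3.normalize_points(make_spots(xyz, channel=channel), frame)


def path_tree(points, tree_id="t"):
    """A single root-to-leaf polyline through the given points."""
    points = np.atleast_2d(points)
    return CenterlineTree(
        pd.DataFrame(
            {
                "node_id": np.arange(len(points)),
                "x": points[:, 0], "y": points[:, 1], "z": points[:, 2],
                "radius": 8.0,
                "parent_id": np.r_[-1, np.arange(len(points) - 1)],
            }
        ),
        tree_id=tree_id,
    )


def radial_point(frame, depth, direction=(0, 0, 1.0)):
    v = np.asarray(direction, float)
    v /= np.linalg.norm(v)
    r_jz = frame.jz_boundary.radius
    r_myo = frame.myo_boundary.radius
    return frame.origin + v * (r_jz + depth * (r_myo - r_jz))


class TestClassification:
    def test_decidual_point_near_artery_is_spiral_adjacent(self, exact_frame):
        t = radial_point(exact_frame, 0.5)
        artery = t + [5.0, 0, 0]
        bd = p3.classify_trophoblasts(norm_points(exact_frame, t), artery, r_adj=20.0)
        assert bd.counts["spiral_artery_adjacent"] == 1

    def test_myometrial_point_far_from_artery_is_stromal(self, exact_frame):
        t = radial_point(exact_frame, 1.2)
        artery = t + [100.0, 0, 0]
        bd = p3.classify_trophoblasts(norm_points(exact_frame, t), artery, r_adj=20.0)
        assert bd.counts["myometrial_stromal"] == 1

    def test_no_artery_points_yields_only_nonadjacent_classes(self, exact_frame):
        pts = np.vstack([radial_point(exact_frame, 0.4), radial_point(exact_frame, 1.1)])
        bd = p3.classify_trophoblasts(norm_points(exact_frame, pts), np.empty((0, 3)), 20.0)
        assert bd.counts["interstitial"] == 1
        assert bd.counts["myometrial_stromal"] == 1
        assert bd.counts["spiral_artery_adjacent"] == 0

    def test_partition_covers_every_in_domain_trophoblast(self, control_norm):
        troph = control_norm.channel("trophoblast")
        artery = control_norm.channel("artery").in_domain()[["x", "y", "z"]].to_numpy()
        bd = p3.classify_trophoblasts(troph, artery, 20.0)
        assert sum(bd.counts.values()) == bd.n_classified == len(troph.in_domain())
        assert sum(bd.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_enlarging_radius_never_decreases_adjacent_count(self, control_norm, control_site):
        troph = control_norm.channel("trophoblast")
        artery = np.vstack([resample_centerline(t, 10.0) for t in control_site.trees])
        prev = -1
        for r in (5.0, 10.0, 20.0, 40.0, 80.0):
            bd = p3.classify_trophoblasts(troph, artery, r)
            adj = bd.counts["spiral_artery_adjacent"] + bd.counts["myometrial_artery_adjacent"]
            assert adj >= prev
            prev = adj

    def test_control_preset_recovers_perivascular_fraction(self, control_site, control_norm):
        # generator oracle: 75% of trophoblasts were placed perivascularly
        troph = control_norm.channel("trophoblast")
        artery = np.vstack(
            [resample_centerline(t, 10.0) for t in control_site.trees]
        )
        bd = p3.classify_trophoblasts(troph, artery, control_site.truth.config.r_adj)
        assert bd.fractions["spiral_artery_adjacent"] == pytest.approx(0.75, abs=0.05)


class TestInvasionSummary:
    def test_max_and_fraction_from_known_depths(self, exact_frame):
        pts = np.vstack([radial_point(exact_frame, d) for d in (0.1, 0.4, 0.9)])
        s = p3.invasion_summary(norm_points(exact_frame, pts))
        assert s.max_depth == pytest.approx(0.9, abs=1e-9)
        assert s.myometrial_fraction == 0.0

    def test_myometrial_invaders_counted(self, exact_frame):
        pts = np.vstack([radial_point(exact_frame, d) for d in (0.5, 1.1)])
        s = p3.invasion_summary(norm_points(exact_frame, pts))
        assert s.max_depth == pytest.approx(1.1, abs=1e-9)
        assert s.myometrial_fraction == pytest.approx(0.5)

    def test_zero_trophoblasts_is_an_explicit_empty_marker(self, exact_frame):
        # a single far-outside point leaves nothing in-domain
        s = p3.invasion_summary(norm_points(exact_frame, radial_point(exact_frame, 3.0)))
        assert s.empty and s.n == 0 and np.isnan(s.max_depth)

    def test_empirical_max_depth_matches_resampling_oracle(self):
        # oracle: direct sampling of the generator's Beta depth law
        cfg = p3.preset("wildtype_E12_5", m_myo=0.0, p_env=0.0,
                        contaminant_fraction=0.0, mesometrial_fraction=0.0)
        rng = np.random.default_rng(99)
        oracle_max = [
            rng.beta(cfg.depth_alpha, cfg.depth_beta, cfg.n_trophoblasts).max() * cfg.d_cap
            for _ in range(200)
        ]
        lo, hi = np.quantile(oracle_max, [0.005, 1.0])
        for seed in (1, 2, 3):
            site = p3.generate_site(cfg, seed=seed)
            frame = p3.fit_half_dome_frame(site.referents)
            norm = p3.normalize_points(site.spots, frame).channel("trophoblast")
            s = p3.invasion_summary(norm)
            assert lo - 0.02 <= s.max_depth <= hi + 0.02


class TestBranchCounts:
    def test_single_descending_path_counts_once(self, exact_frame):
        pts = np.vstack([radial_point(exact_frame, d) for d in (1.3, 1.1, 0.8, 0.2)])
        assert count_decidual_branches([path_tree(pts)], exact_frame) == 1

    def test_myometrial_bifurcation_counts_twice(self, exact_frame):
        a = radial_point(exact_frame, 1.3)
        b = radial_point(exact_frame, 1.1)
        c1 = radial_point(exact_frame, 0.5, (0.1, 0, 1))
        c2 = radial_point(exact_frame, 0.5, (-0.1, 0, 1))
        tree = CenterlineTree(
            pd.DataFrame(
                {
                    "node_id": [0, 1, 2, 3],
                    "x": [a[0], b[0], c1[0], c2[0]],
                    "y": [a[1], b[1], c1[1], c2[1]],
                    "z": [a[2], b[2], c1[2], c2[2]],
                    "radius": 8.0,
                    "parent_id": [-1, 0, 1, 1],
                }
            )
        )
        assert count_decidual_branches([tree], exact_frame) == 2

    def test_path_oscillating_across_boundary_counts_once(self, exact_frame):
        pts = np.vstack([radial_point(exact_frame, d) for d in (1.3, 0.9, 1.05, 0.7, 0.2)])
        assert count_decidual_branches([path_tree(pts)], exact_frame) == 1

    def test_tree_entirely_decidual_contributes_zero(self, exact_frame):
        pts = np.vstack([radial_point(exact_frame, d) for d in (0.8, 0.5, 0.2)])
        assert count_decidual_branches([path_tree(pts)], exact_frame) == 0

    @pytest.mark.parametrize("preset_name,expected", [
        ("wildtype_E6_5", 8), ("wildtype_E8_5", 10), ("wildtype_E12_5", 16),
    ])
    def test_generated_sites_count_equals_configured_trees(self, preset_name, expected):
        cfg = p3.preset(preset_name, landmark_jitter=0.0)
        site = p3.generate_site(cfg, seed=5)
        frame = p3.fit_half_dome_frame(site.referents)
        assert count_decidual_branches(site.trees, frame) == expected


class TestEnvelopment:
    def test_full_decoration_gives_fraction_one(self, exact_frame, control_site):
        tree = control_site.trees[0]
        frame = p3.fit_half_dome_frame(control_site.referents)
        samples = resample_centerline(tree, 10.0)
        d = frame.depth(samples)
        troph = samples[(d >= 0) & (d < 1)] + [3.0, 0.0, 0.0]
        fr, n_env, _ = envelopment([tree], troph, frame, r_env=20.0)
        assert fr[tree.tree_id] == 1.0
        assert n_env == 1

    def test_no_trophoblasts_gives_zero_not_enveloped(self, control_site):
        frame = p3.fit_half_dome_frame(control_site.referents)
        fr, n_env, _ = envelopment(control_site.trees[:2], np.empty((0, 3)), frame)
        assert all(v == 0.0 for v in fr.values())
        assert n_env == 0

    def test_enlarging_radius_never_decreases_fractions(self, control_site, control_norm):
        frame = control_norm.frame
        troph = control_norm.channel("trophoblast").in_domain()[["x", "y", "z"]].to_numpy()
        prev = None
        for r in (5.0, 15.0, 30.0):
            fr, _, _ = envelopment(control_site.trees, troph, frame, r_env=r)
            if prev is not None:
                assert all(fr[k] >= prev[k] - 1e-12 for k in fr)
            prev = fr

    def test_decorated_artery_fraction_recovered_over_seeds(self):
        # generator oracle: 60% of arteries carry the perivascular points
        cfg = p3.preset("wildtype_E12_5", eligible_artery_fraction=0.6,
                        contaminant_fraction=0.0, mesometrial_fraction=0.0)
        recovered = []
        for seed in range(20):
            site = p3.generate_site(cfg, seed=seed)
            frame = p3.fit_half_dome_frame(site.referents)
            norm = p3.normalize_points(site.spots, frame)
            troph = norm.channel("trophoblast").in_domain()[["x", "y", "z"]].to_numpy()
            fr, n_env, _ = envelopment(site.trees, troph, frame,
                                       r_env=cfg.r_env, coverage_threshold=0.5)
            recovered.append(n_env / len(fr))
        assert np.mean(recovered) == pytest.approx(0.6, abs=0.1)


class TestConnectionCounts:
    def test_tree_terminating_on_jz_surface_counted(self, exact_frame):
        pts = np.vstack([radial_point(exact_frame, d) for d in (1.3, 0.6, 0.0)])
        assert p3.count_placenta_connected([path_tree(pts)], exact_frame) == 1

    def test_tree_stopping_midway_not_counted(self, exact_frame):
        pts = np.vstack([radial_point(exact_frame, d) for d in (1.3, 0.8, 0.4)])
        assert p3.count_placenta_connected([path_tree(pts)], exact_frame) == 0

    def test_generated_counts_match_preset_connected_fraction(self):
        for name, expected in (("wildtype_E12_5", 12), ("cxcl12_ko_E12_5", 3)):
            site = p3.generate_site(p3.preset(name, landmark_jitter=0.0), seed=3)
            frame = p3.fit_half_dome_frame(site.referents)
            assert p3.count_placenta_connected(site.trees, frame) == expected


class TestVirtualSections:
    @staticmethod
    def _sections(cfg, seed):
        site = p3.generate_site(cfg, seed=seed)
        frame = p3.fit_half_dome_frame(site.referents)
        norm = p3.normalize_points(site.spots, frame).channel("trophoblast")
        return p3.virtual_sections(norm, frame)

    def test_isotropic_invasion_gives_ratio_near_one(self):
        cfg = p3.preset("wildtype_E12_5", p_env=0.0, contaminant_fraction=0.0,
                        mesometrial_fraction=0.0)
        ratios = [self._sections(cfg, seed).discrepancy_ratio for seed in range(20)]
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)

    def test_off_midline_deep_invaders_inflate_the_ratio(self, exact_frame):
        # construction oracle: depths known by placement; a shallow isotropic
        # background sits in every section while the deep invaders cluster at
        # azimuth u ~ 0.25 (along e2, perpendicular to the midline plane), so
        # every section max is far below the 3D max
        rng = np.random.default_rng(0)
        r_jz, r_myo = 900.0, 1500.0

        def place(d, phi, cos_t):
            sin_t = np.sqrt(1 - cos_t**2)
            r = r_jz + d * (r_myo - r_jz)
            return np.stack(
                [r * sin_t * np.cos(phi), r * sin_t * np.sin(phi), r * cos_t], axis=1
            )

        shallow = place(rng.uniform(0.05, 0.4, 500), rng.uniform(0, 2 * np.pi, 500),
                        rng.uniform(0.05, 0.95, 500))
        deep = place(np.full(100, 0.9), np.pi / 2 + rng.normal(0, 0.05, 100),
                     rng.uniform(0.2, 0.8, 100))
        norm = norm_points(exact_frame, np.vstack([shallow, deep]))
        sc = p3.virtual_sections(norm, exact_frame)
        assert sc.max_depth_3d > 0.85
        assert sc.discrepancy_ratio > 2.0

    def test_ratio_nondecreasing_in_azimuthal_concentration(self):
        # Monte-Carlo monotonicity oracle over three bias settings
        means = []
        for kappa in (0.0, 1.5, 4.0):
            cfg = p3.preset("wildtype_E12_5", p_env=0.0, kappa=kappa,
                            azimuth_center=0.25, depth_alpha=6.0, depth_beta=1.5,
                            contaminant_fraction=0.0, mesometrial_fraction=0.0)
            means.append(np.mean(
                [self._sections(cfg, seed).discrepancy_ratio for seed in range(20)]
            ))
        assert means[0] <= means[1] + 0.02
        assert means[1] <= means[2] + 0.02

    def test_section_max_never_exceeds_3d_max_up_to_convention(self):
        # subset maximum; 0.02 allows the documented chord-vs-ray convention gap
        cfg = p3.preset("wildtype_E12_5", contaminant_fraction=0.0,
                        mesometrial_fraction=0.0)
        for seed in range(5):
            sc = self._sections(cfg, seed)
            finite = sc.section_max_depths[np.isfinite(sc.section_max_depths)]
            assert (finite <= sc.max_depth_3d + 0.02).all()
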