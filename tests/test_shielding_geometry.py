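import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from loxshield import (
    OPEN,
    PlaneFit,
    ShieldingConfig,
    accessibility_score,
    build_probe_points,
    fit_pentadiene_plane,
    min_blocker_distance,
    orient_antarafacial,
    snapshot_accessibility,
)
from loxshield.shielding_geometry import ProbeSite

from conftest import pocket_snapshot


def eigen_plane_oracle(points):
    """Independent plane fit: smallest eigenvector of the centered
    second-moment matrix."""
    pts = np.asarray(points, float)
    centered = pts - pts.mean(axis=0)
    eigvals, eigvecs = np.linalg.eigh(centered.T @ centered)
    normal = eigvecs[:, 0]
    residual = math.sqrt(max(eigvals[0], 0.0) / len(pts))
    return normal, residual


def random_rigid(rng):
    rotation = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    translation = rng.normal(0, 10, 3)
    return rotation.as_matrix(), translation


class TestPlaneFit:
    def test_coplanar_points_give_exact_plane(self, rng):
        xy = rng.normal(0, 2, (5, 2))
        points = np.column_stack([xy, np.zeros(5)])
        fit = fit_pentadiene_plane(points)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-12)
        assert abs(fit.normal @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_rigid_invariance_of_residual(self, rng):
        points = rng.normal(0, 2, (5, 3))
        fit = fit_pentadiene_plane(points)
        rotation, translation = random_rigid(rng)
        moved = points @ rotation.T + translation
        fit_moved = fit_pentadiene_plane(moved)
        assert fit_moved.rms_residual == pytest.approx(fit.rms_residual, abs=1e-9)
        assert abs(fit_moved.normal @ (rotation @ fit.normal)) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_matches_eigen_oracle_on_random_sets(self, rng):
        for _ in range(100):
            points = rng.normal(0, 1.5, (5, 3))
            fit = fit_pentadiene_plane(points)
            oracle_normal, oracle_residual = eigen_plane_oracle(points)
            assert abs(abs(fit.normal @ oracle_normal) - 1.0) < 1e-8
            assert fit.rms_residual == pytest.approx(oracle_residual, abs=1e-8)

    def test_optimal_among_random_candidate_planes(self, rng):
        points = rng.normal(0, 1.5, (5, 3))
        fit = fit_pentadiene_plane(points)
        centered = points - points.mean(axis=0)
        candidates = rng.normal(size=(1000, 3))
        candidates /= np.linalg.norm(candidates, axis=1, keepdims=True)
        rms = np.sqrt(np.mean((centered @ candidates.T) ** 2, axis=0))
        assert fit.rms_residual <= rms.min() + 1e-12

    def test_collinear_points_rejected(self):
        points = np.outer(np.arange(5), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            fit_pentadiene_plane(points)


class TestAntarafacialOrientation:
    def plane(self):
        return PlaneFit(
            centroid=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]), rms_residual=0.0
        )

    def test_normal_kept_when_iron_opposite(self):
        normal = orient_antarafacial(self.plane(), [0, 0, -5])
        assert np.allclose(normal, [0, 0, 1])

    def test_normal_flipped_when_iron_on_normal_side(self):
        normal = orient_antarafacial(self.plane(), [0, 0, 5])
        assert np.allclose(normal, [0, 0, -1])

    def test_iron_in_plane_is_degenerate(self):
        with pytest.raises(ValueError, match="antarafacial"):
            orient_antarafacial(self.plane(), [0, 0, 0.01])


class TestProbePoints:
    def test_planar_substrate_probes_directly_above_carbons(self, config):
        snap = pocket_snapshot(iron_z=-3.0)
        sites = build_probe_points(snap, config)
        assert [s.carbon_label for s in sites] == ["C9", "C11", "C13"]
        for site in sites:
            assert np.allclose(
                site.probe_position, site.carbon_position + [0, 0, 3.0], atol=1e-9
            )

    def test_zero_probe_distance_limit(self):
        config = ShieldingConfig(d_probe=0.0)
        snap = pocket_snapshot()
        for site in build_probe_points(snap, config):
            assert np.allclose(site.probe_position, site.carbon_position)

    def test_probe_carbon_distance_invariant_on_jittered_scene(self, small_scene, config):
        _, ensemble, _ = small_scene
        for snap in ensemble:
            for site in build_probe_points(snap, config):
                d = np.linalg.norm(site.probe_position - site.carbon_position)
                assert d == pytest.approx(config.d_probe, abs=1e-6)

    def test_equivariance_under_rigid_motion(self, config, rng):
        snap = pocket_snapshot(blockers=[("BK11", (2.8, 0.15, 5.0))])
        sites = build_probe_points(snap, config)
        rotation, translation = random_rigid(rng)
        for atom in snap.atoms:
            atom.position = rotation @ atom.position + translation
        moved_sites = build_probe_points(snap, config)
        for site, moved in zip(sites, moved_sites):
            assert np.allclose(
                moved.probe_position,
                rotation @ site.probe_position + translation,
                atol=1e-9,
            )


class TestMinBlockerDistance:
    def test_single_blocker_at_known_distance(self, config):
        snap = pocket_snapshot(blockers=[("BK11", (2.8, 0.3, 4.0))])
        sites = build_probe_points(snap, config)
        c11 = sites[1]
        expected = np.linalg.norm(np.array([2.8, 0.3, 4.0]) - c11.probe_position)
        assert min_blocker_distance(c11, snap, config) == pytest.approx(expected)

    def test_no_blocker_within_r_open_is_open(self, config):
        snap = pocket_snapshot(blockers=[("BKF", (2.8, 0.0, 20.0))])
        for site in build_probe_points(snap, config):
            assert min_blocker_distance(site, snap, config) == OPEN

    def test_empty_blocker_set_is_open(self, config):
        snap = pocket_snapshot()
        site = build_probe_points(snap, config)[0]
        assert min_blocker_distance(site, snap, config) == OPEN

    def test_substrate_and_iron_never_block(self, config):
        snap = pocket_snapshot(iron_z=-0.5)  # iron close, still excluded
        site = ProbeSite("C11", np.array([2.8, 0.3, 0.0]), np.array([2.8, 0.3, 0.5]))
        # probe 0.5 Å from a substrate carbon: still OPEN
        assert min_blocker_distance(site, snap, config) == OPEN

    def test_matches_brute_force_on_random_clouds(self, config, rng):
        """1000 random blocker clouds: k-d tree minimum equals an exhaustive scan."""
        for _ in range(1000):
            n = int(rng.integers(1, 12))
            cloud = rng.normal(0, 2.5, (n, 3)) + [2.8, 0.0, 3.0]
            snap = pocket_snapshot(
                blockers=[(f"B{i}", cloud[i]) for i in range(n)]
            )
            site = build_probe_points(snap, config)[1]
            brute = np.linalg.norm(cloud - site.probe_position, axis=1).min()
            expected = OPEN if brute > config.r_open else brute
            assert min_blocker_distance(site, snap, config) == pytest.approx(expected)


class TestAccessibilityScore:
    @pytest.mark.parametrize(
        "distance,expected",
        [
            (2.5, 1.0),   # beyond r_open: fully accessible
            (2.2, 1.0),   # boundary convention: closed at r_open
            (1.8, 0.0),   # boundary convention: closed at r_block
            (1.5, 0.0),   # inside r_block: fully shielded
            (OPEN, 1.0),
        ],
    )
    def test_plateaus_and_boundaries(self, config, distance, expected):
        assert accessibility_score(distance, config) == expected

    def test_midpoint_matches_hand_evaluated_ramp(self, config):
        # u = 0.5, k = 2: g = (e^1 - 1)/(e^2 - 1) = 1/(e + 1)
        expected = 1.0 / (math.e + 1.0)
        assert accessibility_score(2.0, config) == pytest.approx(expected, abs=1e-12)
        assert 0.0 < accessibility_score(2.0, config) < 1.0

    def test_negative_distance_rejected(self, config):
        with pytest.raises(ValueError):
            accessibility_score(-0.1, config)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        d1=st.floats(0.0, 4.0),
        d2=st.floats(0.0, 4.0),
        k=st.floats(0.1, 10.0),
    )
    def test_monotone_and_bounded_for_any_steepness(self, d1, d2, k):
        config = ShieldingConfig(ramp_steepness=k)
        lo, hi = sorted((d1, d2))
        s_lo = accessibility_score(lo, config)
        s_hi = accessibility_score(hi, config)
        assert 0.0 <= s_lo <= s_hi <= 1.0

    def test_continuity_at_thresholds(self, config):
        eps = 1e-9
        assert accessibility_score(config.r_block + eps, config) < 1e-6
        assert accessibility_score(config.r_open - eps, config) > 1 - 1e-6


class TestBlockerPolicies:
    def test_policies_filter_waters_and_hydrogens(self):
        rows_extra = [
            ("OW", (2.8, 0.3, 4.0)),  # will be re-labelled below
        ]
        snap = pocket_snapshot(blockers=rows_extra)
        # turn the blocker into a water and add a protein hydrogen nearby
        water = snap.atoms[-1]
        water.residue_name = "HOH"
        water.element = "O"
        from loxshield.structure_io import AtomRecord

        snap.atoms.append(
            AtomRecord(99, "H1", "H", "ALA", 50, "A", np.array([2.8, 0.3, 4.1]))
        )
        snap._reindex()

        site_of = lambda cfg: build_probe_points(snap, cfg)[1]
        all_cfg = ShieldingConfig(blocker_policy="all-non-substrate")
        assert min_blocker_distance(site_of(all_cfg), snap, all_cfg) < OPEN
        protein_cfg = ShieldingConfig(blocker_policy="protein-only")
        d = min_blocker_distance(site_of(protein_cfg), snap, protein_cfg)
        assert d < OPEN  # the hydrogen counts by default
        no_h = ShieldingConfig(blocker_policy="protein-only", include_hydrogens=False)
        assert min_blocker_distance(site_of(no_h), snap, no_h) == OPEN
        pw = ShieldingConfig(blocker_policy="protein+water", include_hydrogens=False)
        assert min_blocker_distance(site_of(pw), snap, pw) < OPEN


def test_snapshot_accessibility_profiles_open_and_blocked(config):
    snap = pocket_snapshot(blockers=[("BK11", (2.8, 0.3, 4.0))])  # 1 Å above probe
    profile = snapshot_accessibility(snap, config)
    c9, c11, c13 = profile.scores
    assert c9 == 1.0 and c13 == 1.0
    assert c11 == 0.0  # blocker 1.0 Å from the C11 probe


def test_config_yaml_round_trip(tmp_path):
    config = ShieldingConfig(ramp_steepness=3.5, blocker_policy="protein+water")
    path = tmp_path / "config.yaml"
    config.to_yaml(path)
    assert ShieldingConfig.from_yaml(path) == config


def test_config_validation():
    with pytest.raises(ValueError):
        ShieldingConfig(r_open=1.5, r_block=1.8)
    with pytest.raises(ValueError):
        ShieldingConfig(ramp_steepness=0)
    with pytest.raises(ValueError):
        ShieldingConfig(c11_penalty=1.0)
    with pytest.raises(ValueError):
        ShieldingConfig(blocker_policy="everything")
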