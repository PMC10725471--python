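"""Superposition, RMSD/RMSF, distances and the two-triangle site area."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from baxdm import ensemble_metrics as em
from baxdm import synthetic_data as syn
from baxdm.ensemble_metrics import AreaSpec, ConformationEnsemble
from baxdm.structure_io import AtomSelection

from conftest import horn_superpose


def rotation_z(deg):
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


# --------------------------------------------------------------------------
# kabsch_superpose


def test_identity_superposition():
    P = np.random.default_rng(0).uniform(0, 10, (6, 3))
    res = em.kabsch_superpose(P, P)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)


def test_rigid_motion_recovered_exactly():
    P = np.random.default_rng(1).uniform(0, 10, (5, 3))
    Q = P @ rotation_z(90).T + np.array([1.0, 2.0, 3.0])
    res = em.kabsch_superpose(P, Q)
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("seed", range(20))
def test_rmsd_agrees_with_quaternion_oracle(seed):
    rng = np.random.default_rng(seed)
    P = rng.uniform(-10, 10, (5, 3))
    Q = rng.uniform(-10, 10, (5, 3))
    res = em.kabsch_superpose(P, Q)
    _, _, oracle_rmsd = horn_superpose(P, Q)
    assert res.rmsd == pytest.approx(oracle_rmsd, abs=1e-8)


def test_reflection_is_corrected_to_proper_rotation():
    rng = np.random.default_rng(3)
    P = rng.uniform(-5, 5, (6, 3))
    Q = P.copy()
    Q[:, 0] *= -1  # mirrored set
    res = em.kabsch_superpose(P, Q)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)


def test_too_few_points_raise():
    with pytest.raises(ValueError, match="3 points"):
        em.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def test_collinear_points_flagged_with_translation_fallback():
    P = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    Q = P + np.array([5.0, 5.0, 5.0])
    res = em.kabsch_superpose(P, Q)
    assert res.degenerate
    np.testing.assert_allclose(res.rotation, np.eye(3))
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)


# --------------------------------------------------------------------------
# rmsd_series / rmsf


def _ensemble_from_frames(frames, names=None, resnums=None):
    frames = np.asarray(frames, float)
    n_atoms = frames.shape[1]
    names = names or ["CA"] * n_atoms
    resnums = resnums or list(range(1, n_atoms + 1))
    return ConformationEnsemble(frames, names, resnums)


def test_rmsd_series_zero_for_identical_frames():
    base = np.random.default_rng(0).uniform(0, 10, (5, 3))
    ens = _ensemble_from_frames([base] * 4)
    np.testing.assert_allclose(em.rmsd_series(ens), 0.0, atol=1e-12)


def test_rmsd_series_matches_per_frame_recomputation():
    rng = np.random.default_rng(5)
    base = rng.uniform(0, 10, (8, 3))
    frames = base[None] + rng.normal(0, 0.2, (6, 8, 3))
    frames[0] = base
    ens = _ensemble_from_frames(frames)
    series = em.rmsd_series(ens, reference_frame=0)
    for f in range(6):
        assert series[f] == pytest.approx(
            em.kabsch_superpose(base, frames[f]).rmsd, abs=1e-12
        )


def test_single_frame_rmsd_is_zero():
    base = np.random.default_rng(0).uniform(0, 10, (4, 3))
    ens = _ensemble_from_frames(base[None])
    np.testing.assert_allclose(em.rmsd_series(ens), [0.0], atol=1e-12)


def test_rmsf_all_identical_frames_is_zero():
    base = np.random.default_rng(0).uniform(0, 10, (6, 3))
    ens = _ensemble_from_frames([base] * 5)
    assert all(v == pytest.approx(0.0, abs=1e-12) for v in em.rmsf_per_residue(ens).values())


def test_rmsf_needs_two_frames():
    base = np.zeros((4, 3))
    ens = _ensemble_from_frames(base[None])
    with pytest.raises(ValueError, match="2 frames"):
        em.rmsf_per_residue(ens)


def test_two_frame_displacement_gives_half_distance():
    # one atom near the centroid displaced by d between two frames ->
    # RMSF = d/2; a wide cloud of anchors keeps the rigid fit pinned
    rng = np.random.default_rng(0)
    anchors = rng.uniform(-40, 40, (80, 3))
    anchors -= anchors.mean(axis=0)
    base = np.vstack([[0.0, 0.0, 0.0], anchors])
    moved = base.copy()
    moved[0] += [0.0, 0.0, 1.0]
    ens = _ensemble_from_frames([base, moved])
    rmsf = em.rmsf_per_residue(ens)
    assert rmsf[1] == pytest.approx(0.5, rel=0.05)


def test_planted_fluctuation_recovered_as_sigma_sqrt3():
    # median over seeds: sqrt(3) * 0.2 ~ 0.346 A within 5%
    ratios = []
    for seed in range(10):
        ens, truth = syn.gen_ensemble(
            n_frames=2000, sigma_per_residue={85: 0.2}, sigma_default=0.0, seed=seed
        )
        ratios.append(em.rmsf_per_residue(ens)[85] / truth["rmsf"][85])
    assert abs(np.median(ratios) - 1.0) < 0.05


def test_delta_rmsf_identities():
    apo = {1: 0.5, 2: 1.0}
    assert em.delta_rmsf(apo, apo) == {1: 0.0, 2: 0.0}
    bound = {k: 1.5 * v for k, v in apo.items()}
    out = em.delta_rmsf(bound, apo)
    assert out[1] == pytest.approx(0.5) and out[2] == pytest.approx(0.5)


def test_delta_rmsf_zero_apo_names_residue():
    with pytest.raises(ZeroDivisionError, match="residue 2"):
        em.delta_rmsf({1: 1.0, 2: 1.0}, {1: 1.0, 2: 0.0})


def test_delta_rmsf_mismatched_residues_raise():
    with pytest.raises(ValueError, match="different residue sets"):
        em.delta_rmsf({1: 1.0}, {2: 1.0})


# --------------------------------------------------------------------------
# distance_series


def test_constant_pair_distance():
    f = np.array([[0.0, 0, 0], [3.0, 0, 0]])
    ens = _ensemble_from_frames([f, f, f], names=["NZ", "CD"], resnums=[21, 19])
    d = em.distance_series(ens, (AtomSelection(21, "NZ"), AtomSelection(19, "CD")))
    np.testing.assert_allclose(d, 3.0)


def test_centroid_selection_measures_to_midpoint():
    # carboxylate-like 2-atom group: distance to its midpoint
    f = np.array([[0.0, 0, 0], [0, 1, 0], [0, -1, 0], [4, 0, 0]])
    ens = _ensemble_from_frames(
        [f], names=["NZ", "OD1", "OD2", "CA"], resnums=[21, 48, 48, 7]
    )
    d = em.distance_series(
        ens, (AtomSelection(21, "NZ"), AtomSelection(48, ("OD1", "OD2")))
    )
    np.testing.assert_allclose(d, [0.0])
    d2 = em.distance_series(
        ens, (AtomSelection(7, "CA"), AtomSelection(48, ("OD1", "OD2")))
    )
    np.testing.assert_allclose(d2, [4.0])


def test_distance_series_matches_direct_norms():
    rng = np.random.default_rng(8)
    frames = rng.uniform(0, 10, (7, 2, 3))
    ens = _ensemble_from_frames(frames, names=["CA", "CA"], resnums=[1, 2])
    d = em.distance_series(ens, (AtomSelection(1, "CA"), AtomSelection(2, "CA")))
    np.testing.assert_allclose(
        d, np.linalg.norm(frames[:, 0] - frames[:, 1], axis=1), atol=1e-12
    )


def test_unresolvable_pair_raises():
    ens = _ensemble_from_frames(np.zeros((1, 2, 3)), names=["CA", "CA"], resnums=[1, 2])
    with pytest.raises(KeyError):
        em.distance_series(ens, (AtomSelection(1, "CA"), AtomSelection(99, "CA")))


# --------------------------------------------------------------------------
# heron_area / canonical_site_area


def test_right_triangle_area():
    assert em.heron_area([0, 0, 0], [3, 0, 0], [0, 4, 0]) == pytest.approx(6.0)


def test_collinear_triangle_is_zero():
    assert em.heron_area([0, 0, 0], [1, 1, 1], [2, 2, 2]) == pytest.approx(0.0, abs=1e-9)


@given(st.integers(0, 2**31 - 1))
def test_heron_equals_cross_product(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(-50, 50, (3, 3))
    cross = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
    assert em.heron_area(*p) == pytest.approx(cross, rel=1e-9, abs=1e-12)


def _square_ensemble(side=10.0, n_frames=3):
    # vertices of a square in the plane; two right triangles of side^2/2
    pts = np.array(
        [[0.0, 0, 0], [side, 0, 0], [side, side, 0], [0, side, 0]]
    )
    frames = np.repeat(pts[None], n_frames, axis=0)
    return ConformationEnsemble(
        frames, ["CA"] * 4, [189, 91, 85, 79]
    )


def test_square_decomposes_to_full_area():
    ens = _square_ensemble(side=10.0)
    res = em.canonical_site_area(ens)
    np.testing.assert_allclose(res.area_series, 100.0)
    assert res.mean == pytest.approx(100.0)


def test_identical_ensembles_zero_percent_change():
    ens = _square_ensemble()
    res = em.canonical_site_area(ens, reference=ens)
    assert res.percent_change == pytest.approx(0.0, abs=1e-12)


def test_percent_change_worked_example():
    a = _square_ensemble(side=np.sqrt(96.0))  # mean area 96
    b = _square_ensemble(side=np.sqrt(104.5))  # mean area 104.5
    res = em.canonical_site_area(b, reference=a)
    assert res.percent_change == pytest.approx(100 * 8.5 / 96, rel=1e-9)
    assert round(res.percent_change) == 9


def test_area_symmetric_in_decomposition_and_additive():
    ens = _square_ensemble()
    alt = AreaSpec(triangles=((2, 1, 0), (2, 3, 0)))  # same diagonal, reordered
    res = em.canonical_site_area(ens, spec=alt)
    assert res.mean == pytest.approx(100.0)


def test_metrics_invariant_under_global_rigid_transform():
    rng = np.random.default_rng(12)
    ens, _ = syn.gen_ensemble(n_frames=20, sigma_default=0.1, seed=4)
    R = rotation_z(37.0)
    t = np.array([5.0, -3.0, 11.0])
    moved = ConformationEnsemble(
        ens.coords @ R.T + t, ens.atom_names, ens.residue_numbers
    )
    np.testing.assert_allclose(
        em.rmsd_series(ens), em.rmsd_series(moved), atol=1e-6
    )
    r1 = em.rmsf_per_residue(ens)
    r2 = em.rmsf_per_residue(moved)
    np.testing.assert_allclose(list(r1.values()), list(r2.values()), atol=1e-6)
    pair = (AtomSelection(21, "NZ"), AtomSelection(48, ("OD1", "OD2")))
    np.testing.assert_allclose(
        em.distance_series(ens, pair), em.distance_series(moved, pair), atol=1e-6
    )
    a1 = em.canonical_site_area(ens)
    a2 = em.canonical_site_area(moved)
    np.testing.assert_allclose(a1.area_series, a2.area_series, atol=1e-6)


def test_replicate_mean_is_mean_of_ensemble_means():
    e1 = _square_ensemble(side=10.0)
    e2 = _square_ensemble(side=np.sqrt(60.5))  # area 60.5
    assert em.replicate_mean_area([e1, e2]) == pytest.approx((100 + 60.5) / 2)
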