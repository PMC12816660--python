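"""Lesion-matrix construction, dTLVC, SVR back-projection and inference."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from convergemap.images import VoxelImage
from convergemap.svrlsm import (LesionCohort, SvrLsmConfig, apply_dtlvc,
                                atlas_overlap, build_lesion_matrix, cfwer_threshold,
                                fit_svrlsm_beta, permutation_pmap,
                                reproducibility_index, residualize_behaviour)


def _cohort_from_stack(stack, scores=None):
    n = stack.shape[0]
    subjects = [f"s{i}" for i in range(n)]
    masks = [VoxelImage(stack[i].astype(np.uint8)) for i in range(n)]
    behaviour = pd.DataFrame({"delta_asymmetry": scores if scores is not None
                              else np.zeros(n)}, index=subjects)
    return LesionCohort(subjects, masks, behaviour)


def test_inclusion_threshold_is_ceil_of_fraction(rng):
    """n=82 at 10% -> a voxel needs >= 9 lesioned subjects to enter."""
    stack = np.zeros((82, 3, 3, 3), dtype=np.uint8)
    stack[:8, 0, 0, 0] = 1   # 8 subjects: below ceil(8.2) = 9
    stack[:9, 1, 1, 1] = 1   # 9 subjects: included
    cohort = _cohort_from_stack(stack)
    matrix, mask, idx = build_lesion_matrix(cohort, SvrLsmConfig())
    assert mask.data[0, 0, 0] == 0
    assert mask.data[1, 1, 1] == 1
    assert matrix.shape == (82, 1)


def test_inclusion_zero_fraction_keeps_any_lesioned_voxel():
    stack = np.zeros((5, 2, 2, 2), dtype=np.uint8)
    stack[0, 0, 0, 0] = 1
    stack[:, 1, 1, 1] = 1
    cohort = _cohort_from_stack(stack)
    matrix, mask, _ = build_lesion_matrix(cohort, SvrLsmConfig(min_lesion_fraction=0.0))
    assert mask.data.sum() == 2


def test_single_shared_voxel_yields_one_column():
    stack = np.zeros((6, 2, 2, 2), dtype=np.uint8)
    stack[:, 0, 1, 0] = 1
    matrix, mask, _ = build_lesion_matrix(_cohort_from_stack(stack), SvrLsmConfig())
    assert matrix.shape == (6, 1)
    assert mask.data.sum() == 1


def test_empty_inclusion_raises_with_diagnostic():
    stack = np.zeros((30, 2, 2, 2), dtype=np.uint8)
    stack[0, 0, 0, 0] = 1
    with pytest.raises(ValueError, match="min_lesion_fraction"):
        build_lesion_matrix(_cohort_from_stack(stack), SvrLsmConfig())


def test_inclusion_mask_monotone_in_fraction(rng):
    stack = (rng.random((40, 4, 4, 4)) < 0.3).astype(np.uint8)
    stack[:, 0, 0, 0] = 1  # keep at least one voxel included at any fraction
    cohort = _cohort_from_stack(stack)
    prev = None
    for frac in (0.05, 0.1, 0.2, 0.4, 0.8):
        _, mask, _ = build_lesion_matrix(cohort, SvrLsmConfig(min_lesion_fraction=frac))
        cur = mask.data.astype(bool)
        if prev is not None:
            assert np.all(cur <= prev), "raising the fraction added voxels"
        prev = cur


@pytest.mark.parametrize("volume,expected", [(4, 0.5), (100, 0.1), (1, 1.0)])
def test_dtlvc_scales_by_inverse_sqrt_volume(volume, expected):
    row = np.zeros(volume + 3)
    row[:volume] = 1.0
    scaled = apply_dtlvc(row[None, :])
    assert scaled[0, 0] == pytest.approx(expected, abs=1e-12)
    # zero pattern preserved
    assert np.array_equal(scaled != 0, row[None, :] != 0)


def test_dtlvc_uses_whole_mask_volume_and_enforces_sqrt_law():
    matrix = np.array([[1.0, 0.0], [1.0, 1.0]])
    scaled = apply_dtlvc(matrix, total_volumes=np.array([1.0, 4.0]))
    assert scaled[0, 0] == 1.0
    assert scaled[1, 0] == 0.5  # volume over whole mask, not included columns
    with pytest.raises(ValueError):
        apply_dtlvc(np.array([[0.0, 0.0]]))


def test_residualize_drops_constant_covariate_to_centering(rng):
    n = 50
    score = rng.normal(size=n)
    table = pd.DataFrame({"score": score, "const": np.ones(n)})
    with pytest.warns(UserWarning, match="zero variance"):
        resid = residualize_behaviour(table, "score", ["const"])
    assert np.allclose(resid, score - score.mean(), atol=1e-10)


def test_residualize_removes_exact_linear_dependence(rng):
    n = 40
    age = rng.uniform(20, 70, n)
    table = pd.DataFrame({"score": 2.0 * age + 1.0, "age": age})
    resid = residualize_behaviour(table, "score", ["age"])
    assert np.max(np.abs(resid)) < 1e-9


def test_residualize_keeps_signal_removes_covariate(rng):
    n = 200
    age = rng.uniform(20, 70, n)
    planted = rng.normal(size=n)
    table = pd.DataFrame({"score": planted + 2.0 * age, "age": age})
    resid = residualize_behaviour(table, "score", ["age"])
    assert abs(sps.spearmanr(resid, age).statistic) < 0.05
    assert sps.pearsonr(resid, planted).statistic > 0.9


def test_rank_deficient_design_raises(rng):
    n = 20
    a = rng.normal(size=n)
    table = pd.DataFrame({"score": rng.normal(size=n), "a": a, "b": 2 * a})
    with pytest.raises(ValueError, match="rank-deficient"):
        residualize_behaviour(table, "score", ["a", "b"])


# --- SVR beta back-projection ----------------------------------------------

HP = {"C": 30.0, "sigma": 2.0, "epsilon": 0.05}


def test_planted_single_voxel_effect_peaks_at_planted_voxel(rng):
    n, p = 60, 40
    X = (rng.random((n, p)) < 0.3).astype(float)
    y = 2.0 * X[:, 7]  # noiseless effect at voxel 7
    beta = fit_svrlsm_beta(X, y, HP)
    assert int(np.argmax(np.abs(beta))) == 7


def test_beta_deterministic_for_fixed_hyperparameters(rng):
    X = (rng.random((30, 20)) < 0.3).astype(float)
    y = rng.normal(size=30)
    assert np.array_equal(fit_svrlsm_beta(X, y, HP), fit_svrlsm_beta(X, y, HP))


def test_duplicated_subjects_scale_beta_consistently(rng):
    X = (rng.random((25, 15)) < 0.4).astype(float)
    y = rng.normal(size=25)
    beta = fit_svrlsm_beta(X, y, HP)
    beta2 = fit_svrlsm_beta(np.vstack([X, X]), np.concatenate([y, y]), HP)
    # doubling the cohort doubles the dual mass: direction is preserved
    c = np.corrcoef(beta, beta2)[0, 1]
    assert c > 0.99


def test_constant_score_rejected(rng):
    X = (rng.random((10, 5)) < 0.5).astype(float)
    with pytest.raises(ValueError, match="constant"):
        fit_svrlsm_beta(X, np.ones(10), HP)


# --- permutation inference --------------------------------------------------

def test_pmap_formula_bounds_and_determinism(rng):
    X = (rng.random((30, 25)) < 0.3).astype(float)
    y = rng.normal(size=30)
    p1, b1, pb1 = permutation_pmap(X, y, HP, 99, seed_or_rng=42)
    p2, b2, pb2 = permutation_pmap(X, y, HP, 99, seed_or_rng=42)
    assert np.array_equal(p1, p2) and np.array_equal(pb1, pb2)
    assert p1.min() >= 1 / 100 and p1.max() <= 1.0


def test_pmap_uniform_under_null(rng):
    """Voxelwise permutation p-values are uniform for a signal-free cohort."""
    X = (rng.random((40, 30)) < 0.3).astype(float)
    y = rng.normal(size=40)
    p, _, _ = permutation_pmap(X, y, HP, 200, seed_or_rng=7)
    ks = sps.kstest(p, "uniform")
    assert ks.pvalue > 0.01


def test_too_few_permutations_rejected(rng):
    X = (rng.random((10, 5)) < 0.5).astype(float)
    y = rng.normal(size=10)
    with pytest.raises(ValueError):
        permutation_pmap(X, y, HP, 10, seed_or_rng=0)
    with pytest.warns(UserWarning):
        permutation_pmap(X, y, HP, 50, seed_or_rng=0)


def _mask_and_idx(shape, p):
    mask = np.zeros(shape, dtype=np.uint8)
    flat = np.arange(p)
    mask.ravel()[flat] = 1
    return VoxelImage(mask), flat


def test_cfwer_significant_set_monotone_in_alpha(rng):
    """Raising alpha moves the critical pair outward and never shrinks the mask;
    at alpha near 1 the critical p reaches the largest recorded order statistic."""
    X = (rng.random((30, 20)) < 0.3).astype(float)
    y = rng.normal(size=30)
    p, b, pb = permutation_pmap(X, y, HP, 100, seed_or_rng=3)
    mask, idx = _mask_and_idx((3, 3, 3), 20)
    prev = None
    prev_crit = -1.0
    for alpha in (0.05, 0.2, 0.5, 0.999):
        crit, sig, _ = cfwer_threshold(p, b, pb, mask, idx, alpha=alpha, v=1,
                                       voxel_p=1.0)
        cur = sig.data.astype(bool)
        assert crit >= prev_crit
        if prev is not None:
            assert np.all(prev <= cur)
        prev, prev_crit = cur, crit


def test_cfwer_v_exceeding_voxels_rejected(rng):
    X = (rng.random((20, 10)) < 0.4).astype(float)
    y = rng.normal(size=20)
    p, b, pb = permutation_pmap(X, y, HP, 50, seed_or_rng=3)
    mask, idx = _mask_and_idx((3, 3, 2), 10)
    with pytest.raises(ValueError, match="included voxels"):
        cfwer_threshold(p, b, pb, mask, idx, v=10)


def test_reproducibility_duplicated_halves_near_one(rng):
    X = (rng.random((20, 30)) < 0.3).astype(float)
    y = rng.normal(size=20)
    X2 = np.vstack([X, X])
    y2 = np.concatenate([y, y])
    # every half-split draws from two identical copies: maps nearly coincide
    rs = []
    for seed in range(5):
        perm = np.random.default_rng(seed)
        # deterministic split: first copy vs second copy
        beta_a = fit_svrlsm_beta(X2[:20], y2[:20], HP)
        beta_b = fit_svrlsm_beta(X2[20:], y2[20:], HP)
        rs.append(np.corrcoef(beta_a, beta_b)[0, 1])
    assert np.mean(rs) > 0.99


def test_reproducibility_null_near_zero(rng):
    X = (rng.random((60, 40)) < 0.3).astype(float)
    y = rng.normal(size=60)
    r = reproducibility_index(X, y, HP, n_splits=10, seed_or_rng=5)
    assert abs(r) < 0.2


def test_reproducibility_planted_exceeds_null(lesion_cohort):
    from convergemap.svrlsm import apply_dtlvc, build_lesion_matrix
    cohort, truth = lesion_cohort
    cfg = SvrLsmConfig(seed=7)
    m, _, _ = build_lesion_matrix(cohort, cfg)
    X = apply_dtlvc(m, cohort.stacked().reshape(len(cohort.subjects), -1).sum(1))
    y = cohort.behaviour["delta_asymmetry"].to_numpy()
    hp = {"C": 10.0, "sigma": 10.0, "epsilon": 0.1}
    r_signal = reproducibility_index(X, y, hp, n_splits=6, seed_or_rng=3)
    r_null = reproducibility_index(X, np.random.default_rng(0).permutation(y),
                                   hp, n_splits=6, seed_or_rng=3)
    assert r_signal > 0.4
    assert r_signal > r_null + 0.2


# --- atlas overlap ----------------------------------------------------------

def test_atlas_overlap_percentages():
    labels = np.zeros((6, 6, 6), dtype=int)
    labels[:3] = 1          # parcel 1: 108 voxels
    labels[3:] = 2          # parcel 2: 108 voxels
    cluster = np.zeros((6, 6, 6), dtype=np.uint8)
    cluster[0] = 1          # 36 voxels inside parcel 1
    parcels, nets = atlas_overlap(
        VoxelImage(cluster), VoxelImage(labels),
        networks=pd.DataFrame({"label": [1, 2], "parcel_name": ["a", "b"],
                               "network_name": ["N1", "N1"]}))
    p1 = parcels.set_index("label")
    assert p1.loc[1, "overlap_percent"] == pytest.approx(100 * 36 / 108)
    assert p1.loc[2, "overlap_percent"] == 0.0
    assert nets.loc[0, "overlap_percent"] == pytest.approx(100 * 36 / 216)


def test_atlas_overlap_identity_and_disjoint():
    labels = np.zeros((4, 4, 4), dtype=int)
    labels[:2] = 3
    full = VoxelImage((labels == 3).astype(np.uint8))
    parcels, _ = atlas_overlap(full, VoxelImage(labels))
    assert parcels.loc[0, "overlap_percent"] == 100.0
    empty = VoxelImage(np.zeros((4, 4, 4), dtype=np.uint8))
    parcels, _ = atlas_overlap(empty, VoxelImage(labels))
    assert parcels.loc[0, "overlap_percent"] == 0.0


def test_atlas_overlap_grid_mismatch_raises():
    a = VoxelImage(np.zeros((3, 3, 3), dtype=np.uint8))
    b = VoxelImage(np.zeros((4, 4, 4), dtype=int))
    with pytest.raises(ValueError):
        atlas_overlap(a, b)
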