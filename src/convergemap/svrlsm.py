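"""Multivariate SVR lesion-symptom mapping with permutation/CFWER inference.

The analysis regresses a behavioural change score on the binary voxelwise
resection status of a patient cohort using an epsilon-SVR with an RBF
(Gaussian) kernel. The fitted model is back-projected to a voxelwise
beta-map (beta = X^T alpha, the dual-coefficient convention), lesion size is
de-confounded by direct total lesion volume control (dTLVC: each subject's
lesion vector scaled by 1/sqrt(lesion volume)), and nuisance covariates are
regressed out of the behavioural score beforehand.

Inference is by permutation: the score vector is permuted, the pipeline
refitted, and voxelwise one-tailed p-values computed against the permutation
ensemble (direction: lesion associated with worsening). Familywise control
uses the continuum/cluster FWER procedure (CFWER): each permutation map is
itself converted to a p-map against the ensemble, the v-th smallest p per
map is recorded, and the alpha-quantile of that distribution gives the
critical p. Because ranked p-values are lattice-valued, ties between maps
are broken by the standardized beta magnitude, which keeps the procedure
exact (FWER = floor(alpha*(K+1))/(K+1)) under exchangeability.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .images import VoxelImage

log = logging.getLogger(__name__)

__all__ = [
    "SvrLsmConfig",
    "LesionCohort",
    "SvrLsmResult",
    "build_lesion_matrix",
    "apply_dtlvc",
    "residualize_behaviour",
    "fit_svrlsm_beta",
    "optimize_hyperparameters",
    "permutation_pmap",
    "cfwer_threshold",
    "reproducibility_index",
    "atlas_overlap",
    "run_svrlsm",
]

#: 26-neighbourhood connectivity for cluster labelling.
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class SvrLsmConfig:
    """Tunable parameters of the lesion-symptom mapping pipeline.

    Defaults follow common practice for RBF SVR-LSM of resection cohorts:
    voxels resected in at least 10% of the group are analysed, C in [1, 80],
    sigma in [0.1, 30], 5000 permutations thresholded at voxelwise p < 0.005
    with CFWER at alpha = 0.05, v = 1. The epsilon search interval defaults
    to [0.05, 2.5] * IQR(score)/10, derived from the score scale at run time.
    """

    min_lesion_fraction: float = 0.10
    C_range: tuple[float, float] = (1.0, 80.0)
    sigma_range: tuple[float, float] = (0.1, 30.0)
    epsilon_range: Optional[tuple[float, float]] = None
    n_permutations: int = 5000
    voxel_p: float = 0.005
    cfwer_alpha: float = 0.05
    cfwer_v: int = 1
    n_folds: int = 5
    n_opt_iterations: int = 200
    n_repro_splits: int = 10
    two_tailed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.voxel_p < 1):
            raise ValueError("voxel_p must be in (0, 1)")
        if self.cfwer_v < 1:
            raise ValueError("cfwer_v must be >= 1")
        for name in ("C_range", "sigma_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a nonempty positive interval")
        if not (0 <= self.min_lesion_fraction <= 1):
            raise ValueError("min_lesion_fraction must be in [0, 1]")

    def seed_streams(self) -> dict[str, np.random.Generator]:
        """Named substreams derived from the single config seed.

        Order is fixed (optimisation, permutation, reproducibility, synth) so
        that adding consumers never perturbs existing streams.
        """
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("optimize", "permute", "reproducibility", "misc")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class LesionCohort:
    """Per-subject binary resection masks on a shared grid plus behaviour rows."""

    subjects: list[str]
    masks: list[VoxelImage]
    behaviour: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.subjects) != len(self.masks):
            raise ValueError("one mask per subject required")
        ref = self.masks[0]
        for m in self.masks[1:]:
            if not ref.same_grid(m):
                raise ValueError("all masks must share grid shape and affine")
        for m in self.masks:
            if not m.is_binary():
                raise ValueError("lesion masks must be binary")
        missing = set(self.subjects) - set(self.behaviour.index)
        if missing:
            raise ValueError(f"behaviour rows missing for subjects: {sorted(missing)}")

    @property
    def grid(self) -> VoxelImage:
        return self.masks[0]

    def stacked(self) -> np.ndarray:
        """(n_subjects, nx, ny, nz) uint8 stack of masks."""
        return np.stack([m.data.astype(np.uint8) for m in self.masks])


@dataclass
class SvrLsmResult:
    beta_map: VoxelImage
    p_map: VoxelImage
    significant_cluster_mask: VoxelImage
    included_voxel_mask: VoxelImage
    hyperparameters: dict
    critical_p: float
    prediction_accuracy: float
    prediction_accuracy_sd: float
    reproducibility: float
    cluster_table: pd.DataFrame
    n_permutations: int


def build_lesion_matrix(cohort: LesionCohort, config: SvrLsmConfig) -> tuple[np.ndarray, VoxelImage, np.ndarray]:
    """Subjects-by-voxels binary matrix restricted to sufficiently lesioned voxels.

    A voxel enters the analysis iff it is lesioned in at least
    ceil(min_lesion_fraction * n) subjects ("at least 10%" of the group).
    Columns follow C-order (ravel) linear voxel indexing of the grid.

    Returns (matrix, inclusion mask image, flat voxel indices of the columns).
    """
    stack = cohort.stacked()
    n = stack.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    counts = stack.sum(axis=0)
    threshold = max(1, math.ceil(config.min_lesion_fraction * n))
    included = counts >= threshold
    if not included.any():
        raise ValueError(
            f"no voxel is lesioned in >= {threshold} of {n} subjects "
            f"(max coverage {int(counts.max())}); lower min_lesion_fraction or check masks"
        )
    flat_idx = np.flatnonzero(included.ravel(order="C"))
    matrix = stack.reshape(n, -1)[:, flat_idx].astype(float)
    mask_img = VoxelImage(included.astype(np.uint8), cohort.grid.affine.copy(), cohort.grid.space_tag)
    return matrix, mask_img, flat_idx


def apply_dtlvc(matrix: np.ndarray, total_volumes: Optional[np.ndarray] = None) -> np.ndarray:
    """Direct total lesion volume control: scale each row by 1/sqrt(lesion volume).

    ``total_volumes`` is the per-subject lesion volume in voxels over the whole
    mask (not only included columns); when omitted it is taken from the row
    sums of ``matrix`` itself.
    """
    matrix = np.asarray(matrix, dtype=float)
    if total_volumes is None:
        total_volumes = matrix.sum(axis=1)
    total_volumes = np.asarray(total_volumes, dtype=float)
    if np.any(total_volumes <= 0):
        bad = np.flatnonzero(total_volumes <= 0)
        raise ValueError(f"subjects with zero lesion volume: rows {bad.tolist()}")
    return matrix / np.sqrt(total_volumes)[:, None]


def residualize_behaviour(table: pd.DataFrame, score: str,
                          covariates: Sequence[str]) -> np.ndarray:
    """OLS residuals of the behavioural score on an intercept plus covariates.

    Zero-variance covariates are dropped with a warning (they are collinear
    with the intercept); any remaining rank deficiency raises.
    """
    y = table[score].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"missing values in score column {score!r}")
    kept: list[str] = []
    for c in covariates:
        col = table[c].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValueError(f"missing values in covariate {c!r}")
        if np.std(col) == 0:
            warnings.warn(f"covariate {c!r} has zero variance; dropped", stacklevel=2)
            continue
        kept.append(c)
    X = np.column_stack([np.ones(len(y))] + [table[c].to_numpy(dtype=float) for c in kept])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient covariate design: {kept}")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def _rbf_gamma(sigma: float) -> float:
    # sklearn's RBF uses exp(-gamma * ||x-x'||^2); sigma parameterization: gamma = 1/(2 sigma^2)
    return 1.0 / (2.0 * sigma * sigma)


def fit_svrlsm_beta(matrix: np.ndarray, score: np.ndarray,
                    hyperparams: dict, kernel: Optional[np.ndarray] = None) -> np.ndarray:
    """Fit the epsilon-SVR on all subjects and back-project to voxelwise beta.

    beta = X^T alpha with alpha the sign-carrying dual coefficients of the
    fitted machine; a precomputed RBF Gram matrix may be supplied to amortise
    kernel evaluation across permutations (the kernel depends on the lesion
    matrix only).
    """
    score = np.asarray(score, dtype=float)
    if np.std(score) == 0:
        raise ValueError("behavioural score is constant; SVR-LSM undefined")
    C, sigma, epsilon = hyperparams["C"], hyperparams["sigma"], hyperparams["epsilon"]
    if kernel is None:
        kernel = rbf_kernel(matrix, matrix, gamma=_rbf_gamma(sigma))
    model = SVR(kernel="precomputed", C=C, epsilon=epsilon).fit(kernel, score)
    alpha = np.zeros(matrix.shape[0])
    alpha[model.support_] = model.dual_coef_[0]
    return matrix.T @ alpha


def _default_epsilon_range(score: np.ndarray) -> tuple[float, float]:
    iqr = float(np.subtract(*np.percentile(score, [75, 25])))
    base = max(iqr, 1e-6) / 10.0
    return (0.05 * base, 2.5 * base)


def optimize_hyperparameters(matrix: np.ndarray, score: np.ndarray, config: SvrLsmConfig,
                             rng: Optional[np.random.Generator] = None
                             ) -> tuple[dict, float, float]:
    """Seeded random search over (C, sigma, epsilon) with k-fold cross-validation.

    Candidates are drawn log-uniformly over the C and sigma ranges and
    uniformly over the epsilon interval; the candidate minimising the pooled
    out-of-fold squared error wins. Prediction accuracy is the mean (+/- sd
    across folds) Pearson correlation between out-of-fold predictions and
    scores for the winning candidate; near-constant predictions are flagged
    by returning an accuracy of nan.
    """
    rng = rng or config.seed_streams()["optimize"]
    score = np.asarray(score, dtype=float)
    n = len(score)
    eps_range = config.epsilon_range or _default_epsilon_range(score)
    folds = list(KFold(config.n_folds, shuffle=True,
                       random_state=int(rng.integers(2**31 - 1))).split(matrix))
    best = None
    for _ in range(config.n_opt_iterations):
        C = float(np.exp(rng.uniform(*np.log(config.C_range))))
        sigma = float(np.exp(rng.uniform(*np.log(config.sigma_range))))
        epsilon = float(rng.uniform(*eps_range))
        gamma = _rbf_gamma(sigma)
        sse = 0.0
        fold_r = []
        for train, test in folds:
            K_tr = rbf_kernel(matrix[train], matrix[train], gamma=gamma)
            model = SVR(kernel="precomputed", C=C, epsilon=epsilon).fit(K_tr, score[train])
            K_te = rbf_kernel(matrix[test], matrix[train], gamma=gamma)
            pred = model.predict(K_te)
            sse += float(((pred - score[test]) ** 2).sum())
            if np.std(pred) > 1e-12 and np.std(score[test]) > 0:
                fold_r.append(float(np.corrcoef(pred, score[test])[0, 1]))
        cand = {"C": C, "sigma": sigma, "epsilon": epsilon}
        if best is None or sse < best[0]:
            best = (sse, cand, fold_r)
    _, hyper, fold_r = best
    if len(fold_r) < config.n_folds:
        log.warning("constant out-of-fold predictions in %d/%d folds; accuracy partial",
                    config.n_folds - len(fold_r), config.n_folds)
    if not fold_r:
        return hyper, math.nan, math.nan
    return hyper, float(np.mean(fold_r)), float(np.std(fold_r, ddof=1)) if len(fold_r) > 1 else 0.0


def permutation_pmap(matrix: np.ndarray, score: np.ndarray, hyperparams: dict,
                     n_permutations: int, seed_or_rng, two_tailed: bool = False
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxelwise permutation p-values for the observed beta-map.

    The score vector is permuted ``n_permutations`` times and the SVR refitted
    each time (the Gram matrix is fixed, so only the dual problem is re-solved).
    One-tailed p = (1 + #{perm beta >= observed beta}) / (n + 1) in the
    direction associating lesion status with worsening; with ``two_tailed``
    the comparison is on |beta|.

    Returns (p_map values, observed beta, permutation beta stack (K, voxels)).
    """
    if n_permutations < 20:
        raise ValueError("fewer than 20 permutations is uninterpretable")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations: p-values are coarse", stacklevel=2)
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    score = np.asarray(score, dtype=float)
    kernel = rbf_kernel(matrix, matrix, gamma=_rbf_gamma(hyperparams["sigma"]))
    beta_obs = fit_svrlsm_beta(matrix, score, hyperparams, kernel=kernel)
    perm_betas = np.empty((n_permutations, matrix.shape[1]))
    for k in range(n_permutations):
        perm_betas[k] = fit_svrlsm_beta(matrix, rng.permutation(score), hyperparams, kernel=kernel)
    stat_obs, stat_perm = (np.abs(beta_obs), np.abs(perm_betas)) if two_tailed \
        else (beta_obs, perm_betas)
    p = (1 + (stat_perm >= stat_obs[None, :]).sum(axis=0)) / (n_permutations + 1)
    return p, beta_obs, perm_betas


def cfwer_threshold(p_map_values: np.ndarray, beta_obs: np.ndarray, perm_betas: np.ndarray,
                    included_mask: VoxelImage, flat_idx: np.ndarray,
                    alpha: float = 0.05, v: int = 1, voxel_p: float = 0.005,
                    two_tailed: bool = False) -> tuple[float, VoxelImage, pd.DataFrame]:
    """Continuum FWER correction from the v-th order statistic of permutation p-maps.

    Observed and permutation maps are pooled and ranked voxelwise to p-values;
    for each map the v-th smallest p (ties between voxels broken by larger
    standardized beta) defines its extremeness, paired with the standardized
    beta at that voxel. The critical pair is the floor(alpha*(K+1))-th most
    extreme permutation pair; an observed voxel is significant iff its
    (p, z) pair is strictly more extreme than the critical pair and its
    p-value also passes the voxelwise threshold. Significant voxels are
    labelled into 26-connected clusters.
    """
    K, n_vox = perm_betas.shape
    if v >= n_vox:
        raise ValueError(f"v={v} must be smaller than the {n_vox} included voxels")
    stat = np.vstack([beta_obs[None, :], perm_betas])
    if two_tailed:
        stat = np.abs(stat)
    # voxelwise standardization over the pooled ensemble (continuous tie-breaker)
    mu = stat.mean(axis=0)
    sd = stat.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (stat - mu) / sd
    # p of each map at each voxel: fraction of pooled maps at least as extreme
    p_all = sps.rankdata(-stat, axis=0, method="max") / (K + 1)

    def _vth(m: int) -> tuple[float, float]:
        order = np.lexsort((-z[m], p_all[m]))
        j = order[v - 1]
        return float(p_all[m, j]), float(z[m, j])

    pairs = np.array([_vth(m) for m in range(1, K + 1)])  # permutation maps only
    w_obs = _vth(0)
    # most extreme first: small p, then large z
    order = np.lexsort((-pairs[:, 1], pairs[:, 0]))
    m_star = int(math.floor(alpha * (K + 1)))
    shape = included_mask.shape
    sig = np.zeros(shape, dtype=np.uint8)
    if m_star == 0:
        critical_p = 0.0
    else:
        w_crit, t_crit = pairs[order[m_star - 1]]
        critical_p = float(w_crit)
        more_extreme = (p_map_values < w_crit) | ((p_map_values == w_crit) & (z[0] > t_crit))
        passing = more_extreme & (p_map_values <= voxel_p)
        sig_flat = np.zeros(int(np.prod(shape)), dtype=np.uint8)
        sig_flat[flat_idx[passing]] = 1
        sig = sig_flat.reshape(shape)
    labels, n_clusters = ndimage.label(sig, structure=CONNECTIVITY_26)
    rows = []
    beta_vol = np.zeros(int(np.prod(shape)))
    beta_vol[flat_idx] = beta_obs
    beta_vol = beta_vol.reshape(shape)
    for c in range(1, n_clusters + 1):
        voxels = np.argwhere(labels == c)
        vals = beta_vol[labels == c]
        peak = voxels[np.argmax(np.abs(vals))]
        peak_mm = included_mask.voxel_to_world(peak)[0]
        rows.append({"cluster": c, "size_voxels": len(voxels),
                     "peak_x_mm": peak_mm[0], "peak_y_mm": peak_mm[1], "peak_z_mm": peak_mm[2],
                     "peak_beta": float(vals[np.argmax(np.abs(vals))])})
    table = pd.DataFrame(rows, columns=["cluster", "size_voxels", "peak_x_mm",
                                        "peak_y_mm", "peak_z_mm", "peak_beta"])
    sig_img = VoxelImage(sig, included_mask.affine.copy(), included_mask.space_tag)
    return critical_p, sig_img, table


def reproducibility_index(matrix: np.ndarray, score: np.ndarray, hyperparams: dict,
                          n_splits: int = 10, seed_or_rng=0) -> float:
    """Mean Pearson correlation of beta-maps over repeated random half-splits.

    A split whose half has a constant score is resampled (logged); after 50
    consecutive failures the data are effectively constant and an error is
    raised upstream by the beta fit.
    """
    if matrix.shape[0] < 20:
        raise ValueError("need n >= 20 subjects for half-split reproducibility")
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    score = np.asarray(score, dtype=float)
    n = len(score)
    half = n // 2
    correlations = []
    attempts = 0
    while len(correlations) < n_splits:
        attempts += 1
        if attempts > n_splits + 50:
            raise ValueError("could not draw half-splits with non-constant scores")
        perm = rng.permutation(n)
        a, b = perm[:half], perm[half:]
        if np.std(score[a]) == 0 or np.std(score[b]) == 0:
            log.info("half-split with constant score resampled")
            continue
        beta_a = fit_svrlsm_beta(matrix[a], score[a], hyperparams)
        beta_b = fit_svrlsm_beta(matrix[b], score[b], hyperparams)
        if np.std(beta_a) == 0 or np.std(beta_b) == 0:
            correlations.append(0.0)
        else:
            correlations.append(float(np.corrcoef(beta_a, beta_b)[0, 1]))
    return float(np.mean(correlations))


def atlas_overlap(cluster_mask: VoxelImage, parcellation: VoxelImage,
                  networks: Optional[pd.DataFrame] = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage of each parcel (and network) volume covered by the cluster.

    ``networks``: optional table with columns (label, parcel_name, network_name).
    Returns (per-parcel table, per-network table); the network table is empty
    when no network lookup is given.
    """
    if not cluster_mask.same_grid(parcellation):
        raise ValueError("cluster mask and parcellation are on different grids")
    cluster = cluster_mask.data > 0
    labels = parcellation.data.astype(int)
    parcel_rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        parcel = labels == lab
        size = int(parcel.sum())
        inter = int(np.logical_and(parcel, cluster).sum())
        parcel_rows.append({"label": int(lab), "parcel_voxels": size,
                            "overlap_voxels": inter,
                            "overlap_percent": 100.0 * inter / size})
    parcels = pd.DataFrame(parcel_rows, columns=["label", "parcel_voxels",
                                                 "overlap_voxels", "overlap_percent"])
    nets = pd.DataFrame(columns=["network_name", "network_voxels", "overlap_voxels",
                                 "overlap_percent"])
    if networks is not None and len(parcels):
        merged = parcels.merge(networks, on="label", how="left")
        grp = merged.groupby("network_name", dropna=True)
        nets = pd.DataFrame({
            "network_voxels": grp["parcel_voxels"].sum(),
            "overlap_voxels": grp["overlap_voxels"].sum(),
        }).reset_index()
        nets["overlap_percent"] = 100.0 * nets["overlap_voxels"] / nets["network_voxels"]
    return parcels, nets


def run_svrlsm(cohort: LesionCohort, config: SvrLsmConfig, score: str = "delta_asymmetry",
               covariates: Sequence[str] = ("age", "education", "grade"),
               hyperparams: Optional[dict] = None) -> SvrLsmResult:
    """End-to-end lesion-symptom mapping on one cohort.

    Builds the inclusion-filtered lesion matrix, applies dTLVC, residualizes
    the score on the covariates, optimises (or accepts) hyperparameters,
    computes the permutation p-map and the CFWER-corrected significant
    cluster mask, and evaluates prediction accuracy and half-split
    reproducibility.
    """
    streams = config.seed_streams()
    matrix, included, flat_idx = build_lesion_matrix(cohort, config)
    volumes = cohort.stacked().reshape(len(cohort.subjects), -1).sum(axis=1)
    X = apply_dtlvc(matrix, volumes)
    cov = [c for c in covariates if c in cohort.behaviour.columns]
    y = residualize_behaviour(cohort.behaviour.loc[cohort.subjects], score, cov)
    if hyperparams is None:
        hyperparams, acc, acc_sd = optimize_hyperparameters(X, y, config, streams["optimize"])
    else:
        _, acc, acc_sd = _accuracy_only(X, y, hyperparams, config, streams["optimize"])
    p_vals, beta, perm_betas = permutation_pmap(
        X, y, hyperparams, config.n_permutations, streams["permute"], config.two_tailed)
    critical_p, sig_img, clusters = cfwer_threshold(
        p_vals, beta, perm_betas, included, flat_idx,
        config.cfwer_alpha, config.cfwer_v, config.voxel_p, config.two_tailed)
    repro = reproducibility_index(X, y, hyperparams, config.n_repro_splits,
                                  streams["reproducibility"])
    shape = included.shape
    beta_vol = np.zeros(int(np.prod(shape)), dtype=np.float32)
    beta_vol[flat_idx] = beta
    p_vol = np.ones(int(np.prod(shape)), dtype=np.float32)
    p_vol[flat_idx] = p_vals
    return SvrLsmResult(
        beta_map=included.with_data(beta_vol.reshape(shape)),
        p_map=included.with_data(p_vol.reshape(shape)),
        significant_cluster_mask=sig_img,
        included_voxel_mask=included,
        hyperparameters=hyperparams,
        critical_p=critical_p,
        prediction_accuracy=acc,
        prediction_accuracy_sd=acc_sd,
        reproducibility=repro,
        cluster_table=clusters,
        n_permutations=config.n_permutations,
    )


def _accuracy_only(X: np.ndarray, y: np.ndarray, hyperparams: dict,
                   config: SvrLsmConfig, rng: np.random.Generator) -> tuple[dict, float, float]:
    """Cross-validated accuracy for fixed hyperparameters (no search)."""
    gamma = _rbf_gamma(hyperparams["sigma"])
    fold_r = []
    for train, test in KFold(config.n_folds, shuffle=True,
                             random_state=int(rng.integers(2**31 - 1))).split(X):
        K_tr = rbf_kernel(X[train], X[train], gamma=gamma)
        model = SVR(kernel="precomputed", C=hyperparams["C"],
                    epsilon=hyperparams["epsilon"]).fit(K_tr, y[train])
        pred = model.predict(rbf_kernel(X[test], X[train], gamma=gamma))
        if np.std(pred) > 1e-12 and np.std(y[test]) > 0:
            fold_r.append(float(np.corrcoef(pred, y[test])[0, 1]))
    if not fold_r:
        return hyperparams, math.nan, math.nan
    sd = float(np.std(fold_r, ddof=1)) if len(fold_r) > 1 else 0.0
    return hyperparams, float(np.mean(fold_r)), sd
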