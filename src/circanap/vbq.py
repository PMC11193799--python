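"""Voxel-based quantification with permutation cluster-level inference.

Subject maps are smoothed with tissue-weighted Gaussian kernels,
restricted to cohort-level tissue masks, and regressed voxel-wise on
circadian REM amplitude with demographic and sleep covariates.
Cluster-level family-wise error is controlled by Freedman-Lane
permutation of the maximal suprathreshold cluster extent: nuisance
covariates are regressed out, their residuals permuted across subjects,
and the full model re-fitted on each permuted dataset to build the null
distribution of the largest cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .phenotype import phenotype_cohort
from .simulate import CohortBundle, MAP_PARAMS

logger = logging.getLogger(__name__)

__all__ = [
    "DESIGN_COLUMNS",
    "TissueMasks",
    "StatMap",
    "ClusterInfo",
    "ClusterResult",
    "build_design",
    "tissue_weighted_smooth",
    "build_masks",
    "voxelwise_regression",
    "cluster_inference",
    "run_vbq",
]

#: Design-matrix columns; ``rem_amp`` is the variable of interest.
DESIGN_COLUMNS = (
    "intercept", "rem_amp", "age", "sex", "education", "se_amp",
    "mean_rem", "mean_se", "rem_slope", "se_slope",
    "baseline_rem", "baseline_se",
)
_FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))
_CONNECTIVITY = np.ones((3, 3, 3), dtype=int)  # 26-neighbour


@dataclass(frozen=True)
class TissueMasks:
    """Disjoint cohort-level grey/white matter analysis masks."""

    gm_mask: np.ndarray
    wm_mask: np.ndarray

    def __post_init__(self) -> None:
        if (self.gm_mask & self.wm_mask).any():
            raise ValueError("tissue masks must be disjoint")

    def __getitem__(self, tissue: str) -> np.ndarray:
        return {"gm": self.gm_mask, "wm": self.wm_mask}[tissue]


@dataclass(frozen=True)
class StatMap:
    """Voxel-wise t statistics (NaN outside the analysed mask)."""

    t: np.ndarray
    df: int
    mask: np.ndarray
    map_label: str = ""
    tissue: str = ""


@dataclass(frozen=True)
class ClusterInfo:
    extent: int
    peak_t: float
    peak_ijk: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    p_fwe: float


@dataclass(frozen=True)
class ClusterResult:
    clusters: tuple[ClusterInfo, ...]
    label_map: np.ndarray
    voxel_p: float
    t_crit: float
    alpha: float
    n_perm: int
    seed: int
    tail: int
    df: int

    @property
    def significant(self) -> tuple[ClusterInfo, ...]:
        return tuple(c for c in self.clusters if c.p_fwe < self.alpha)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(extent=c.extent, peak_t=c.peak_t,
                  peak_i=c.peak_ijk[0], peak_j=c.peak_ijk[1],
                  peak_k=c.peak_ijk[2], p_fwe=c.p_fwe)
             for c in self.clusters]
        )


def build_design(pheno: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix in the canonical column order plus its contrast.

    Returns ``(X, contrast)`` where the contrast vector selects the
    circadian REM amplitude column.  Raises on rank deficiency, naming
    the collinear columns.
    """
    data = pheno.copy()
    data["intercept"] = 1.0
    missing = [c for c in DESIGN_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"phenotype table lacks design columns: {missing}")
    X = data.loc[:, list(DESIGN_COLUMNS)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite values")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [DESIGN_COLUMNS[i] for i in range(X.shape[1])
               if abs(R[i, i]) < 1e-8 * abs(np.diag(R)).max()]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    contrast = np.zeros(X.shape[1])
    contrast[DESIGN_COLUMNS.index("rem_amp")] = 1.0
    return X, contrast


def tissue_weighted_smooth(
    volume: np.ndarray,
    tissue_prob: np.ndarray,
    fwhm_mm: float = 6.0,
    voxel_size: float = 1.0,
    support_threshold: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Tissue-weighted Gaussian smoothing, s = G*(w x) / G*(w).

    Normalizing by the smoothed tissue probability limits partial-volume
    mixing across tissue boundaries.  Voxels whose smoothed weight falls
    below ``support_threshold`` are masked out (returned as NaN).
    Returns ``(smoothed, support_mask)``.
    """
    if volume.shape != tissue_prob.shape:
        raise ValueError("map and tissue probability grids differ")
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / voxel_size
    num = ndimage.gaussian_filter(tissue_prob * volume, sigma_vox)
    den = ndimage.gaussian_filter(tissue_prob.astype(float), sigma_vox)
    support = den > support_threshold
    out = np.full(volume.shape, np.nan)
    out[support] = num[support] / den[support]
    return out, support


def build_masks(gm_probs, wm_probs, threshold: float = 0.20) -> TissueMasks:
    """Cohort tissue masks: average probabilities, argmax class, floor.

    Voxels whose mean grey and white probabilities both fail to exceed
    ``threshold`` are removed (non-brain); ties go to grey matter.
    """
    gm = np.mean(np.asarray(gm_probs, dtype=float), axis=0)
    wm = np.mean(np.asarray(wm_probs, dtype=float), axis=0)
    if gm.shape != wm.shape:
        raise ValueError("tissue probability grids differ")
    gm_mask = (gm >= wm) & (gm > threshold)
    wm_mask = (wm > gm) & (wm > threshold)
    return TissueMasks(gm_mask, wm_mask)


def _fit_engine(X: np.ndarray, contrast: np.ndarray):
    """Precompute the projection pieces reused by every (permuted) fit."""
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    pinv = XtX_inv @ X.T
    c_row = contrast @ pinv                     # 1 x n: c' beta = c_row @ Y
    c_var = float(contrast @ XtX_inv @ contrast)
    Q, _ = np.linalg.qr(X)                      # n x p orthonormal basis
    return c_row, c_var, Q, n - p


def _t_from_Y(Y: np.ndarray, c_row, c_var, Q, df) -> np.ndarray:
    eff = c_row @ Y
    QtY = Q.T @ Y
    rss = np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", QtY, QtY)
    rss = np.maximum(rss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = eff / np.sqrt(rss / df * c_var)
    # zero-residual voxels: perfect fit, t is +/-inf (0 for a null effect)
    exact = np.where(eff > 0, np.inf, np.where(eff < 0, -np.inf, 0.0))
    return np.where(rss > 0, t, exact)


def voxelwise_regression(
    Y: np.ndarray,
    X: np.ndarray,
    contrast: np.ndarray,
    mask: np.ndarray,
    map_label: str = "",
    tissue: str = "",
) -> StatMap:
    """Mass-univariate OLS t-map for one contrast.

    ``Y`` is an ``(n_subjects, *volume)`` stack.  Voxels with NaN values
    or zero variance across subjects are dropped from the mask (logged).
    """
    n = Y.shape[0]
    if X.shape[0] != n:
        raise ValueError("design rows must match number of subject maps")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design is rank deficient")
    mask = mask.copy()
    flat = Y.reshape(n, -1)
    mflat = mask.ravel()
    bad = mflat & (~np.isfinite(flat).all(axis=0) | (np.ptp(flat, axis=0) == 0))
    if bad.any():
        logger.info("dropping %d degenerate/NaN voxels from mask", int(bad.sum()))
        mflat = mflat & ~bad
        mask = mflat.reshape(mask.shape)
    c_row, c_var, Q, df = _fit_engine(X, contrast)
    t_in = _t_from_Y(flat[:, mflat], c_row, c_var, Q, df)
    t_vol = np.full(mask.shape, np.nan)
    t_vol[mask] = t_in
    return StatMap(t_vol, df, mask, map_label, tissue)


def _max_extent(t_flat: np.ndarray, mask_shape, in_mask_idx, t_crit: float) -> int:
    if not (t_flat > t_crit).any():
        return 0
    vol = np.zeros(mask_shape, dtype=bool)
    vol.ravel()[in_mask_idx] = t_flat > t_crit
    labels, n = ndimage.label(vol, structure=_CONNECTIVITY)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_inference(
    Y: np.ndarray,
    X: np.ndarray,
    contrast: np.ndarray,
    mask: np.ndarray,
    voxel_p: float = 1e-4,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    tail: int = +1,
    voxel_size: float = 1.0,
    map_label: str = "",
    tissue: str = "",
) -> tuple[StatMap, ClusterResult]:
    """Cluster-level FWE by Freedman-Lane permutation of max extent.

    Suprathreshold clusters (26-connected, one-sided voxel threshold at
    ``voxel_p``) of the observed t-map are assigned
    ``p_fwe = (1 + #{perm max extent >= observed}) / (n_perm + 1)``.
    ``tail=-1`` tests the inverse (negative) contrast.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse FWE estimate",
                      stacklevel=2)
    stat = voxelwise_regression(Y, X, contrast, mask, map_label, tissue)
    mask = stat.mask
    n = Y.shape[0]
    flat = Y.reshape(n, -1)[:, mask.ravel()]
    in_mask_idx = np.flatnonzero(mask.ravel())
    t_crit = float(stats.t.isf(voxel_p, stat.df))
    t_obs = tail * stat.t[mask]

    # observed clusters
    supra = np.zeros(mask.shape, dtype=bool)
    supra.ravel()[in_mask_idx] = t_obs > t_crit
    label_map, n_clusters = ndimage.label(supra, structure=_CONNECTIVITY)
    extents = np.bincount(label_map.ravel())[1:] if n_clusters else np.array([], int)

    # Freedman-Lane null of the maximal extent
    ci = int(np.argmax(np.abs(contrast)))
    Z = np.delete(X, ci, axis=1)
    pinv_z = np.linalg.pinv(Z)
    fitted_z = Z @ (pinv_z @ flat)
    resid_z = flat - fitted_z
    c_row, c_var, Q, df = _fit_engine(X, contrast)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Y_b = fitted_z + resid_z[perm]
        t_b = tail * _t_from_Y(Y_b, c_row, c_var, Q, df)
        null_max[b] = _max_extent(t_b, mask.shape, in_mask_idx, t_crit)

    infos = []
    for lab in range(1, n_clusters + 1):
        ext = int(extents[lab - 1])
        cl_idx = np.argwhere(label_map == lab)
        tvals = stat.t[label_map == lab] * tail
        k = int(np.argmax(tvals))
        peak = tuple(int(v) for v in cl_idx[k])
        p_fwe = float((1 + int((null_max >= ext).sum())) / (n_perm + 1))
        infos.append(ClusterInfo(
            ext, float(tail * tvals[k]), peak,
            tuple(float(v * voxel_size) for v in peak), p_fwe,
        ))
    infos.sort(key=lambda c: -c.extent)
    result = ClusterResult(tuple(infos), label_map, voxel_p, t_crit, alpha,
                           n_perm, seed, tail, stat.df)
    return stat, result


def run_vbq(
    bundle: CohortBundle,
    pheno: pd.DataFrame | None = None,
    maps: tuple[str, ...] = ("MTsat", "R1", "R2star"),
    tissues: tuple[str, ...] = ("gm", "wm"),
    tails: tuple[int, ...] = (+1, -1),
    fwhm_mm: float = 6.0,
    voxel_p: float = 1e-4,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    vbm: bool = False,
    vbm_fwhm_mm: float = 8.0,
) -> dict:
    """Whole-cohort VBQ: every map x tissue x contrast sign.

    Phenotypes are computed from the bundle when not supplied; subjects
    missing from the phenotype table are dropped from the imaging
    analysis.  The optional VBM variant runs the same engine on the
    modulated grey-matter volume maps smoothed at ``vbm_fwhm_mm``.
    Returns ``{"results": {(map, tissue, tail): (StatMap, ClusterResult)},
    "pheno": ..., "masks": ..., "n_subjects": ...}``.
    """
    if pheno is None:
        pheno = phenotype_cohort(bundle)
    ids = [s.subject_id for s in bundle.subjects if s.subject_id in pheno.index]
    dropped = bundle.n_subjects - len(ids)
    if dropped:
        logger.info("run_vbq: %d subjects without phenotypes dropped", dropped)
    recs = {s.subject_id: s for s in bundle.subjects}
    X, contrast = build_design(pheno.loc[ids])

    voxel_size = recs[ids[0]].maps.voxel_size
    masks = build_masks(
        [recs[i].maps.gm_prob for i in ids],
        [recs[i].maps.wm_prob for i in ids],
    )
    results: dict[tuple, tuple[StatMap, ClusterResult]] = {}
    rng = np.random.default_rng(seed)
    for tissue in tissues:
        tissue_mask = masks[tissue]
        for map_label in maps:
            stack = []
            support_all = np.ones_like(tissue_mask)
            for i in ids:
                rec = recs[i]
                w = rec.maps.gm_prob if tissue == "gm" else rec.maps.wm_prob
                sm, support = tissue_weighted_smooth(
                    rec.maps.maps[map_label], w, fwhm_mm, voxel_size
                )
                stack.append(sm)
                support_all &= support
            Y = np.stack(stack)
            mask = tissue_mask & support_all
            for tail in tails:
                sub_seed = int(rng.integers(0, 2**31 - 1))
                results[(map_label, tissue, tail)] = cluster_inference(
                    Y, X, contrast, mask, voxel_p, alpha, n_perm, sub_seed,
                    tail, voxel_size, map_label, tissue,
                )
    if vbm:
        stack = []
        for i in ids:
            vol = recs[i].maps.gm_prob.astype(float)
            sm = ndimage.gaussian_filter(
                vol, vbm_fwhm_mm * _FWHM_TO_SIGMA / voxel_size
            )
            stack.append(sm)
        Y = np.stack(stack)
        for tail in tails:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            results[("GMvol", "gm", tail)] = cluster_inference(
                Y, X, contrast, masks["gm"], voxel_p, alpha, n_perm,
                sub_seed, tail, voxel_size, "GMvol", "gm",
            )
    return dict(results=results, pheno=pheno, masks=masks,
                n_subjects=len(ids))
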