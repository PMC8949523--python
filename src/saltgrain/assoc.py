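"""Single-marker association scanning.

Two per-SNP models over a filtered biallelic panel:

* GLM — ordinary least squares of the trait on allele dosage, an intercept
  and optional structure covariates (principal components); the marker test
  is the partial t/F test and the reported R^2 is the marker's incremental
  share of the total sum of squares.
* MLM — the mixed model y = X b + s a + u + e with Var(u) = sigma_g^2 K and
  Var(e) = sigma_e^2 I. Variance components are estimated by REML through
  the spectral decomposition of the kinship matrix (a one-dimensional
  optimization over the ratio delta = sigma_e^2 / sigma_g^2 in the
  eigenbasis). By default the null-model components are reused for every
  marker (the P3D shortcut); exact per-marker REML is available behind a
  flag. Markers are tested by generalized least squares after whitening
  with V = K + delta I.

Missing genotypes are dropped per SNP for testing and mean-imputed only for
kinship and principal components. Positions are 1-based. p-values are
two-sided and floored at 1e-300.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular
from sklearn.isotonic import IsotonicRegression

from .config import ScanConfig
from .panel import GenotypePanel

P_FLOOR = 1e-300

RESULT_COLUMNS = ["chrom", "pos", "snp_id", "trait", "model", "beta", "p_value", "neg_log10_p", "r2_pve", "n_used"]


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_snps(panel: GenotypePanel, cfg: ScanConfig | None = None) -> tuple[GenotypePanel, dict]:
    """Retain SNPs with missingness < ``missing_max`` (strict) and
    MAF >= ``maf_min`` (inclusive), both computed on non-missing calls.

    Returns the filtered panel and a report of counts removed per criterion
    (a SNP failing both is counted under missingness).
    """
    cfg = cfg or ScanConfig()
    miss = panel.missing_fraction()
    maf = panel.maf()
    fail_miss = miss >= cfg.missing_max
    fail_maf = ~fail_miss & (np.isnan(maf) | (maf < cfg.maf_min))
    keep = ~fail_miss & ~fail_maf
    if not keep.any():
        raise ValueError("no SNPs survive filtering")
    report = {
        "n_input": panel.n_snps,
        "removed_missing": int(fail_miss.sum()),
        "removed_maf": int(fail_maf.sum()),
        "n_retained": int(keep.sum()),
    }
    return panel.take_snps(np.where(keep)[0]), report


# ---------------------------------------------------------------------------
# Kinship and structure covariates
# ---------------------------------------------------------------------------

def kinship(panel: GenotypePanel) -> np.ndarray:
    """Centered-cross-product (VanRaden) kinship from mean-imputed dosages:
    K = Z Z' / (2 sum p(1-p)), Z the dosage matrix centered at 2p."""
    d = panel.dosage(mean_impute=True)
    p = d.mean(axis=0) / 2.0
    z = d - 2.0 * p
    denom = 2.0 * np.sum(p * (1 - p))
    if denom <= 0:
        raise ValueError("panel has no genotypic variance; kinship undefined")
    K = (z @ z.T) / denom
    return (K + K.T) / 2.0


def structure_pcs(panel: GenotypePanel, n_pcs: int = 3) -> np.ndarray:
    """Orthonormal principal-component scores of the standardized genotype
    matrix, ordered by explained variance; shape (n_accessions, n_pcs)."""
    if n_pcs == 0:
        return np.empty((panel.n_accessions, 0))
    d = panel.dosage(mean_impute=True)
    sd = d.std(axis=0)
    informative = sd > 0
    if not informative.any():
        raise ValueError("panel has no genotypic variance; PCs undefined")
    z = (d[:, informative] - d[:, informative].mean(axis=0)) / sd[informative]
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    k = min(n_pcs, u.shape[1])
    return u[:, :k]


# ---------------------------------------------------------------------------
# GLM scan
# ---------------------------------------------------------------------------

def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != n:
        covariates = covariates.T
    return np.column_stack([np.ones(n), covariates])


def glm_scan(
    panel: GenotypePanel,
    trait: pd.Series | np.ndarray,
    covariates: np.ndarray | None = None,
    trait_name: str = "trait",
) -> pd.DataFrame:
    """Per-SNP OLS of trait on dosage + intercept + covariates.

    Accessions missing either the trait or the SNP call are dropped for that
    SNP. Monomorphic SNPs after dropping yield NaN rows (flagged, never 0).
    """
    y_all = np.asarray(pd.Series(trait).reindex(panel.accessions) if isinstance(trait, pd.Series) else trait, dtype=float)
    X0_all = _design(panel.n_accessions, covariates)
    dos = panel.dosage()
    rows = []
    for j in range(panel.n_snps):
        g = dos[:, j]
        mask = np.isfinite(y_all) & np.isfinite(g)
        n = int(mask.sum())
        stats_row = _ols_marker(y_all[mask], X0_all[mask], g[mask]) if n >= X0_all.shape[1] + 2 else None
        rows.append(_result_row(panel, j, trait_name, "GLM", stats_row, n))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _ols_marker(y: np.ndarray, X0: np.ndarray, g: np.ndarray):
    """(beta, p, r2_pve) for the marker partial test; None if monomorphic."""
    if np.ptp(g) == 0:
        return None
    X = np.column_stack([X0, g])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        return None  # marker collinear with covariates
    resid = y - X @ coef
    sse_full = float(resid @ resid)
    coef0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    r0 = y - X0 @ coef0
    sse_red = float(r0 @ r0)
    sst = float(np.sum((y - y.mean()) ** 2))
    n, p = X.shape
    df = n - p
    beta = float(coef[-1])
    if sse_full <= 1e-28 * max(sst, 1.0):  # numerically perfect fit
        return beta, P_FLOOR, 100.0 * (sse_red - sse_full) / sst if sst > 0 else np.nan
    sigma2 = sse_full / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    t = beta / se
    p_val = max(2.0 * stats.t.sf(abs(t), df), P_FLOOR)
    r2 = 100.0 * (sse_red - sse_full) / sst if sst > 0 else np.nan
    return beta, p_val, r2


def _result_row(panel: GenotypePanel, j: int, trait_name: str, model: str, stats_row, n: int) -> dict:
    beta, p_val, r2 = stats_row if stats_row is not None else (np.nan, np.nan, np.nan)
    return {
        "chrom": panel.chrom[j],
        "pos": int(panel.pos[j]),
        "snp_id": panel.snp_id[j],
        "trait": trait_name,
        "model": model,
        "beta": beta,
        "p_value": p_val,
        "neg_log10_p": -np.log10(p_val) if np.isfinite(p_val) else np.nan,
        "r2_pve": r2,
        "n_used": n,
    }


# ---------------------------------------------------------------------------
# REML machinery for the mixed model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RemlFit:
    """Null-model REML fit: delta = sigma_e^2/sigma_g^2, profiled sigma_g^2,
    restricted log-likelihood, and the accession mask used."""

    delta: float
    sigma_g2: float
    sigma_e2: float
    loglik: float
    mask: np.ndarray
    converged: bool = True


def reml_loglik(delta: float, eigvals: np.ndarray, y_rot: np.ndarray, X_rot: np.ndarray) -> float:
    """Restricted log-likelihood at variance ratio ``delta`` in the
    eigenbasis of K (Patterson-Thompson form, sigma_g^2 profiled out)."""
    w = 1.0 / (eigvals + delta)
    XtWX = X_rot.T @ (w[:, None] * X_rot)
    XtWy = X_rot.T @ (w * y_rot)
    beta = np.linalg.solve(XtWX, XtWy)
    r = y_rot - X_rot @ beta
    rss = float(np.sum(w * r * r))
    n, p = X_rot.shape
    sigma2 = rss / (n - p)
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    _, logdet_XtX = np.linalg.slogdet(X_rot.T @ X_rot)
    return -0.5 * (
        (n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
        + np.sum(np.log(eigvals + delta))
        + logdet_XtWX
        - logdet_XtX
    )


def fit_null_reml(
    y: np.ndarray, X: np.ndarray, K: np.ndarray, log_delta_range: tuple[float, float] = (-5.0, 5.0)
) -> RemlFit:
    """One-dimensional REML over delta on the eigenbasis of K (EMMA-style):
    coarse grid scan followed by bounded scalar refinement."""
    mask = np.isfinite(y)
    y, X, K = y[mask], X[mask], K[np.ix_(mask, mask)]
    eigvals, U = np.linalg.eigh(K)
    if eigvals.min() < -1e-8:
        warnings.warn("kinship not PSD; clipping negative eigenvalues at 0", stacklevel=2)
    eigvals = np.clip(eigvals, 0.0, None)
    y_rot, X_rot = U.T @ y, U.T @ X

    grid = np.linspace(*log_delta_range, 41)
    lls = np.array([reml_loglik(10.0**g, eigvals, y_rot, X_rot) for g in grid])
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -reml_loglik(10.0**g, eigvals, y_rot, X_rot), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    converged = bool(res.success)
    delta = float(10.0 ** res.x)
    ll = float(-res.fun)
    w = 1.0 / (eigvals + delta)
    XtWX = X_rot.T @ (w[:, None] * X_rot)
    beta = np.linalg.solve(XtWX, X_rot.T @ (w * y_rot))
    r = y_rot - X_rot @ beta
    sigma_g2 = float(np.sum(w * r * r) / (len(y) - X.shape[1]))
    return RemlFit(delta=delta, sigma_g2=sigma_g2, sigma_e2=sigma_g2 * delta, loglik=ll, mask=mask, converged=converged)


def mlm_scan(
    panel: GenotypePanel,
    trait: pd.Series | np.ndarray,
    covariates: np.ndarray | None,
    K: np.ndarray,
    trait_name: str = "trait",
    exact: bool = False,
) -> pd.DataFrame:
    """Per-SNP mixed-model association with kinship random effect.

    Default is the P3D shortcut: delta is estimated once under the null and
    reused, each marker tested by GLS after Cholesky whitening of
    V = K + delta I restricted to the accessions observed for that marker.
    With ``exact=True`` delta is re-estimated by REML per marker.
    """
    y_all = np.asarray(pd.Series(trait).reindex(panel.accessions) if isinstance(trait, pd.Series) else trait, dtype=float)
    if K.shape != (panel.n_accessions, panel.n_accessions):
        raise ValueError("kinship dimension does not match panel")
    X0_all = _design(panel.n_accessions, covariates)
    null = fit_null_reml(y_all, X0_all, K)
    dos = panel.dosage()
    V_full = K + null.delta * np.eye(panel.n_accessions)
    rows = []
    for j in range(panel.n_snps):
        g = dos[:, j]
        mask = np.isfinite(y_all) & np.isfinite(g)
        n = int(mask.sum())
        if n < X0_all.shape[1] + 2 or np.ptp(g[mask]) == 0:
            rows.append(_result_row(panel, j, trait_name, "MLM", None, n))
            continue
        if exact:
            fit_j = fit_null_reml(np.where(mask, y_all, np.nan), X0_all, K)
            V = K + fit_j.delta * np.eye(panel.n_accessions)
            stats_row = _gls_marker(y_all, X0_all, g, mask, V)
        else:
            stats_row = _gls_marker(y_all, X0_all, g, mask, V_full)
        rows.append(_result_row(panel, j, trait_name, "MLM", stats_row, n))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _gls_marker(y_all, X0_all, g_all, mask, V_full):
    """Whitened marker test: Cholesky of V on the observed subset, then the
    same partial test as OLS on the whitened data."""
    idx = np.where(mask)[0]
    V = V_full[np.ix_(idx, idx)]
    try:
        Lc = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        V = V + 1e-8 * np.eye(len(idx))
        Lc = np.linalg.cholesky(V)
    rhs = np.column_stack([y_all[idx], X0_all[idx], g_all[idx]])
    wh = solve_triangular(Lc, rhs, lower=True)
    y_w = wh[:, 0]
    X0_w = wh[:, 1 : 1 + X0_all.shape[1]]
    g_w = wh[:, -1]
    res = _ols_marker_whitened(y_w, X0_w, g_w)
    return res


def _ols_marker_whitened(y, X0, g):
    """Partial test of g given X0 on whitened data; the baseline for R^2 is
    the whitened-intercept residual (reduces to the OLS total SS when V is
    proportional to the identity)."""
    X = np.column_stack([X0, g])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        return None
    resid = y - X @ coef
    sse_full = float(resid @ resid)
    coef0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    r0 = y - X0 @ coef0
    sse_red = float(r0 @ r0)
    ones = X0[:, :1]  # whitened intercept column
    a, *_ = np.linalg.lstsq(ones, y, rcond=None)
    r_null = y - ones @ a
    sst = float(r_null @ r_null)
    n, p = X.shape
    df = n - p
    beta = float(coef[-1])
    if sse_full <= 1e-28 * max(sst, 1.0):
        return beta, P_FLOOR, 100.0 * (sse_red - sse_full) / sst if sst > 0 else np.nan
    sigma2 = sse_full / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    t = beta / se
    p_val = max(2.0 * stats.t.sf(abs(t), df), P_FLOOR)
    r2 = 100.0 * (sse_red - sse_full) / sst if sst > 0 else np.nan
    return beta, p_val, r2


# ---------------------------------------------------------------------------
# Thresholds and hit handling
# ---------------------------------------------------------------------------

def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise threshold on the -log10(p) scale: -log10(alpha/n_tests)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return float(-np.log10(alpha / n_tests))


def significant_hits(results: pd.DataFrame, glm_threshold: float, mlm_threshold: float) -> pd.DataFrame:
    """Rows whose -log10(p) meets the model-specific threshold (>=)."""
    thr = results["model"].map({"GLM": glm_threshold, "MLM": mlm_threshold})
    return results[results["neg_log10_p"] >= thr].copy()


def dedupe_snps(hits: pd.DataFrame) -> pd.DataFrame:
    """Unique SNPs across traits/environments/models, keyed on (chrom, pos);
    the row with the maximum -log10(p) represents each SNP."""
    if hits.empty:
        return hits.copy()
    idx = hits.groupby(["chrom", "pos"], sort=False)["neg_log10_p"].idxmax()
    return hits.loc[idx].sort_values(["chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def pairwise_r2(panel: GenotypePanel, chrom: str | None = None, start: int | None = None, end: int | None = None) -> pd.DataFrame:
    """Composite (dosage-correlation) r^2 matrix, pairwise-complete over
    non-missing calls; monomorphic SNPs yield NaN rows/columns."""
    sub = panel
    if chrom is not None:
        sub = panel.region(chrom, start or 1, end or int(panel.pos.max()))
    if sub.n_snps < 2:
        raise ValueError("need >=2 SNPs for pairwise r^2")
    d = pd.DataFrame(sub.dosage(), columns=sub.snp_id)
    r = d.corr(method="pearson", min_periods=4)
    return r**2


def ld_decay_distance(
    panel: GenotypePanel,
    r2_target: float = 0.1,
    max_dist: int = 500_000,
    n_bins: int = 40,
) -> tuple[float, pd.DataFrame]:
    """Distance at which mean r^2 decays to ``r2_target``.

    Pools same-chromosome SNP pairs up to ``max_dist``, bins their distances,
    fits a non-increasing (isotonic) curve to the binned means weighted by
    pair counts, and returns the smallest bin center whose fitted mean is
    <= the target, together with the per-bin table. NaN when the curve never
    reaches the target.
    """
    dists, r2s = [], []
    for chrom in panel.chromosomes:
        sub = panel.region(chrom, 1, int(panel.pos.max()))
        if sub.n_snps < 2:
            continue
        r2 = pairwise_r2(sub).to_numpy()
        pos = sub.pos
        dd = np.abs(pos[:, None] - pos[None, :])
        iu = np.triu_indices(len(pos), k=1)
        d_flat, r_flat = dd[iu], r2[iu]
        ok = (d_flat <= max_dist) & np.isfinite(r_flat)
        dists.append(d_flat[ok])
        r2s.append(r_flat[ok])
    if not dists:
        raise ValueError("no SNP pairs available for LD decay")
    d_all = np.concatenate(dists)
    r_all = np.concatenate(r2s)
    edges = np.linspace(0, max_dist, n_bins + 1)
    which = np.clip(np.digitize(d_all, edges) - 1, 0, n_bins - 1)
    table = pd.DataFrame({"bin": which, "dist": d_all, "r2": r_all}).groupby("bin").agg(
        center=("dist", "mean"), mean_r2=("r2", "mean"), n_pairs=("r2", "size")
    )
    iso = IsotonicRegression(increasing=False)
    table["fitted_r2"] = iso.fit_transform(table["center"], table["mean_r2"], sample_weight=table["n_pairs"])
    below = table[table["fitted_r2"] <= r2_target]
    decay = float(below["center"].iloc[0]) if len(below) else float("nan")
    return decay, table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Multi-trait driver
# ---------------------------------------------------------------------------

def scan_traits(
    panel: GenotypePanel,
    traits: pd.DataFrame,
    cfg: ScanConfig | None = None,
    trait_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Run the configured models over each per-environment relative trait.

    ``traits`` is the wide table from :func:`saltgrain.phenotyping.relative_traits`;
    by default the nine per-environment columns (RGR1..RRL3) are scanned.
    """
    cfg = cfg or ScanConfig()
    if trait_columns is None:
        trait_columns = [c for c in traits.columns if not c.endswith("-AVG")]
    pcs = structure_pcs(panel, cfg.n_pcs) if cfg.n_pcs > 0 else None
    K = kinship(panel) if "MLM" in cfg.models else None
    out = []
    for col in trait_columns:
        y = traits[col]
        if "GLM" in cfg.models:
            out.append(glm_scan(panel, y, pcs, trait_name=col))
        if "MLM" in cfg.models:
            out.append(mlm_scan(panel, y, pcs, K, trait_name=col))
    return pd.concat(out, ignore_index=True)
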