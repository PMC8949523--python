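"""Association-scan correctness: filters, kinship/structure, GLM vs a
brute-force regression oracle, the mixed model's analytic limits and its
REML optimum, thresholds, hit handling and LD utilities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import saltgrain as sg
from saltgrain import assoc
from saltgrain.panel import MISSING


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _panel_from_calls(calls, chrom=None, pos=None):
    calls = np.asarray(calls, dtype=np.int8)
    n_acc, n_snp = calls.shape
    return sg.GenotypePanel(
        calls=calls,
        chrom=np.array(chrom if chrom is not None else ["Chr1"] * n_snp, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, n_snp + 1) * 1000),
        accessions=[f"S{i}" for i in range(n_acc)],
    )


def test_filter_maf_boundary_inclusive():
    n = 100  # MAF = alt alleles / 200
    col_049 = np.zeros(n, dtype=np.int8)
    col_049[:9] = 1
    col_049[9] = 0  # 9/200 = 0.045 < 0.05 -> removed
    col_05 = np.zeros(n, dtype=np.int8)
    col_05[:10] = 1  # 10/200 = 0.05 -> retained (>= inclusive)
    panel = _panel_from_calls(np.column_stack([col_049, col_05]))
    kept, report = assoc.filter_snps(panel)
    assert report["removed_maf"] == 1 and kept.n_snps == 1
    assert kept.pos[0] == 2000


def test_filter_missing_boundary_strict():
    n = 10
    col_20 = np.ones(n, dtype=np.int8)
    col_20[:2] = MISSING  # 20% missing -> removed ("< 0.2" strict)
    col_20[2:6] = 0
    col_10 = np.ones(n, dtype=np.int8)
    col_10[0] = MISSING  # 10% -> retained
    col_10[1:5] = 0
    panel = _panel_from_calls(np.column_stack([col_20, col_10]))
    kept, report = assoc.filter_snps(panel)
    assert report["removed_missing"] == 1 and kept.n_snps == 1


def test_filter_toy_panel_planted_violations(rng):
    """10 SNPs, 3 planted violations -> 7 survive."""
    n = 50
    good = rng.integers(0, 2, size=(n, 7)).astype(np.int8) + rng.integers(0, 2, size=(n, 7)).astype(np.int8)
    good[:, :] = np.where(good.sum(axis=0) / (2 * n) < 0.05, 1, good)  # ensure common
    rare = np.zeros((n, 2), dtype=np.int8)
    rare[0, :] = 1  # MAF 0.01
    gappy = np.ones((n, 1), dtype=np.int8)
    gappy[: n // 2, 0] = MISSING  # 50% missing
    panel = _panel_from_calls(np.column_stack([good, rare, gappy]))
    kept, report = assoc.filter_snps(panel)
    assert kept.n_snps == 7
    assert report["removed_maf"] == 2 and report["removed_missing"] == 1


def test_filter_empty_result_errors():
    panel = _panel_from_calls(np.zeros((10, 2), dtype=np.int8))
    with pytest.raises(ValueError):
        assoc.filter_snps(panel)


# ---------------------------------------------------------------------------
# kinship and structure
# ---------------------------------------------------------------------------

def test_kinship_duplicate_accession(tiny_panel):
    calls = tiny_panel.calls.copy()
    calls[1] = calls[0]  # make accession 1 a clone of accession 0
    panel = _panel_from_calls(calls, chrom=tiny_panel.chrom, pos=tiny_panel.pos)
    K = assoc.kinship(panel)
    assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-12)
    assert np.allclose(K, K.T)
    assert np.linalg.eigvalsh(K).min() > -1e-8  # PSD


def test_structure_pcs_orthonormal(tiny_panel):
    pcs = assoc.structure_pcs(tiny_panel, 3)
    assert pcs.shape == (30, 3)
    assert np.allclose(pcs.T @ pcs, np.eye(3), atol=1e-10)


def test_structure_pcs_separate_strong_subpops():
    from sklearn.metrics import silhouette_score

    cfg = sg.SimConfig(seed=21, n_accessions=120, n_chrom=3, snps_per_chrom=150,
                       chrom_length_bp=5_000_000, fst=0.35, missing_rate=0.0)
    panel = sg.syndata.simulate_genotypes(cfg)
    pcs = assoc.structure_pcs(panel, 2)
    assert silhouette_score(pcs, panel.subpop) > 0.5


def test_structure_pcs_no_separation_without_fst():
    """With fst=0 the leading PC carries no subpopulation signal: one-way
    ANOVA of PC1 on labels is non-significant at alpha=0.01 in most seeds."""
    n_sig = 0
    for seed in range(10):
        cfg = sg.SimConfig(seed=seed + 100, n_accessions=90, n_chrom=2, snps_per_chrom=80,
                           chrom_length_bp=40_000_000, fst=0.0, missing_rate=0.0)
        panel = sg.syndata.simulate_genotypes(cfg)
        pcs = assoc.structure_pcs(panel, 1)
        groups = [pcs[panel.subpop == sp, 0] for sp in ("Oil", "OF", "Fiber")]
        n_sig += stats.f_oneway(*groups).pvalue < 0.01
    assert n_sig <= 1


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------

def _bruteforce_ols(y, X0, g):
    """Textbook partial-F regression oracle via normal equations."""
    X = np.column_stack([X0, g])
    bf = np.linalg.solve(X.T @ X, X.T @ y)
    rf = y - X @ bf
    sse_f = rf @ rf
    b0 = np.linalg.solve(X0.T @ X0, X0.T @ y)
    sse_r = (y - X0 @ b0) @ (y - X0 @ b0)
    df = len(y) - X.shape[1]
    F = (sse_r - sse_f) / (sse_f / df)
    p = stats.f.sf(F, 1, df)
    sst = np.sum((y - y.mean()) ** 2)
    return bf[-1], p, 100.0 * (sse_r - sse_f) / sst


def test_glm_matches_bruteforce_oracle(tiny_panel, rng):
    y = pd.Series(rng.normal(size=30), index=tiny_panel.accessions)
    pcs = assoc.structure_pcs(tiny_panel, 2)
    res = assoc.glm_scan(tiny_panel, y, pcs, "toy")
    X0 = np.column_stack([np.ones(30), pcs])
    dos = tiny_panel.dosage()
    for j in range(tiny_panel.n_snps):
        g = dos[:, j]
        if np.ptp(g) == 0:
            continue
        beta, p, r2 = _bruteforce_ols(y.to_numpy(), X0, g)
        assert res["beta"].iloc[j] == pytest.approx(beta, abs=1e-8)
        assert res["p_value"].iloc[j] == pytest.approx(p, abs=1e-8)
        assert res["r2_pve"].iloc[j] == pytest.approx(r2, abs=1e-8)


def test_glm_perfect_fit_guard(tiny_panel):
    j = 0
    y = pd.Series(tiny_panel.dosage()[:, j], index=tiny_panel.accessions)
    res = assoc.glm_scan(tiny_panel, y, None, "toy")
    assert res["p_value"].iloc[j] == assoc.P_FLOOR
    assert res["r2_pve"].iloc[j] == pytest.approx(100.0)


def test_glm_monomorphic_flagged_missing():
    calls = np.ones((20, 1), dtype=np.int8)
    panel = _panel_from_calls(calls)
    res = assoc.glm_scan(panel, np.random.default_rng(0).normal(size=20), None)
    assert np.isnan(res["p_value"].iloc[0]) and np.isnan(res["beta"].iloc[0])


def test_glm_drops_missing_per_snp(tiny_panel, rng):
    calls = tiny_panel.calls.copy()
    calls[:5, 0] = MISSING
    panel = _panel_from_calls(calls, chrom=tiny_panel.chrom, pos=tiny_panel.pos)
    y = rng.normal(size=30)
    res = assoc.glm_scan(panel, y, None)
    assert res["n_used"].iloc[0] == 25
    assert res["n_used"].iloc[1] == 30


# ---------------------------------------------------------------------------
# MLM
# ---------------------------------------------------------------------------

def test_mlm_identity_kinship_equals_glm(rng):
    cfg = sg.SimConfig(seed=31, n_accessions=50, n_chrom=2, snps_per_chrom=30,
                       chrom_length_bp=2_000_000, missing_rate=0.05)
    panel = sg.syndata.simulate_genotypes(cfg)
    y = pd.Series(rng.normal(size=50), index=panel.accessions)
    pcs = assoc.structure_pcs(panel, 2)
    glm = assoc.glm_scan(panel, y, pcs, "t")
    mlm = assoc.mlm_scan(panel, y, pcs, np.eye(50), "t")
    ok = glm["p_value"].notna()
    assert np.allclose(mlm.loc[ok, "p_value"], glm.loc[ok, "p_value"], atol=1e-6)
    assert np.allclose(mlm.loc[ok, "beta"], glm.loc[ok, "beta"], atol=1e-6)
    assert np.allclose(mlm.loc[ok, "r2_pve"], glm.loc[ok, "r2_pve"], atol=1e-6)


def _dense_reml_loglik(delta, y, X, K):
    """Textbook restricted likelihood with explicit dense inverses."""
    n, p = X.shape
    H = K + delta * np.eye(n)
    Hi = np.linalg.inv(H)
    XtHiX = X.T @ Hi @ X
    beta = np.linalg.solve(XtHiX, X.T @ Hi @ y)
    r = y - X @ beta
    rss = r @ Hi @ r
    sigma2 = rss / (n - p)
    _, ld_H = np.linalg.slogdet(H)
    _, ld_XtHiX = np.linalg.slogdet(XtHiX)
    _, ld_XtX = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1) + ld_H + ld_XtHiX - ld_XtX)


def test_reml_optimum_matches_dense_grid(rng):
    cfg = sg.SimConfig(seed=41, n_accessions=20, n_chrom=2, snps_per_chrom=40,
                       chrom_length_bp=2_000_000, missing_rate=0.0)
    panel = sg.syndata.simulate_genotypes(cfg)
    K = assoc.kinship(panel)
    u = rng.multivariate_normal(np.zeros(20), K + 1e-6 * np.eye(20))
    y = 1.0 + u + rng.normal(scale=0.7, size=20)
    X = np.ones((20, 1))
    fit = assoc.fit_null_reml(y, X, K)
    grid = np.logspace(-5, 5, 2001)
    lls = [_dense_reml_loglik(d, y, X, K) for d in grid]
    assert fit.loglik >= max(lls) - 1e-10
    assert fit.loglik == pytest.approx(max(lls), abs=1e-4)


def test_mlm_without_polygenic_signal_matches_glm(rng):
    """When the trait has no kinship-structured component the variance ratio
    goes to the noise end and the mixed model reproduces OLS closely."""
    cfg = sg.SimConfig(seed=51, n_accessions=100, n_chrom=2, snps_per_chrom=50,
                       chrom_length_bp=2_000_000, missing_rate=0.0, fst=0.02)
    panel = sg.syndata.simulate_genotypes(cfg)
    K = assoc.kinship(panel)
    y = pd.Series(rng.normal(size=100), index=panel.accessions)
    glm = assoc.glm_scan(panel, y, None, "t")
    mlm = assoc.mlm_scan(panel, y, None, K, "t")
    ok = glm["p_value"].notna()
    corr = np.corrcoef(glm.loc[ok, "neg_log10_p"], mlm.loc[ok, "neg_log10_p"])[0, 1]
    assert corr > 0.99


def test_mlm_exact_close_to_p3d(tiny_panel, rng):
    y = pd.Series(rng.normal(size=30), index=tiny_panel.accessions)
    K = assoc.kinship(tiny_panel)
    p3d = assoc.mlm_scan(tiny_panel, y, None, K)
    exact = assoc.mlm_scan(tiny_panel, y, None, K, exact=True)
    ok = p3d["p_value"].notna()
    assert np.corrcoef(p3d.loc[ok, "neg_log10_p"], exact.loc[ok, "neg_log10_p"])[0, 1] > 0.99


# ---------------------------------------------------------------------------
# thresholds and hits
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n_tests, alpha, expected, ndigits",
    [(674074, 0.05, 7.13, 2), (1, 0.05, 1.301, 3), (100, 0.05, 3.301, 3)],
)
def test_bonferroni_threshold(n_tests, alpha, expected, ndigits):
    assert round(assoc.bonferroni_threshold(n_tests, alpha), ndigits) == expected


def _hits_frame():
    rows = []
    for trait in ("RGR1", "RGR2", "RSL1"):
        rows.append({"chrom": "Chr1", "pos": 100, "snp_id": "s1", "trait": trait,
                     "model": "GLM", "beta": 0.1, "p_value": 1e-9, "neg_log10_p": 9.0,
                     "r2_pve": 10.0, "n_used": 200})
    rows.append({"chrom": "Chr1", "pos": 200, "snp_id": "s2", "trait": "RGR1",
                 "model": "MLM", "beta": 0.1, "p_value": 1e-3, "neg_log10_p": 3.0,
                 "r2_pve": 2.0, "n_used": 200})
    return pd.DataFrame(rows)


def test_significant_hits_and_dedupe():
    res = _hits_frame()
    assert len(assoc.significant_hits(res.iloc[0:0], 5.0, 5.0)) == 0
    hits = assoc.significant_hits(res, 5.0, 5.0)
    assert len(hits) == 3  # same SNP significant for 3 traits -> 3 rows
    assert len(assoc.dedupe_snps(hits)) == 1


def test_thresholding_monotone():
    res = _hits_frame()
    low = assoc.significant_hits(res, 2.0, 2.0)
    high = assoc.significant_hits(res, 5.0, 5.0)
    assert set(map(tuple, high[["chrom", "pos", "trait", "model"]].values)) <= set(
        map(tuple, low[["chrom", "pos", "trait", "model"]].values)
    )


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def test_pairwise_r2_limits(tiny_panel):
    r2 = assoc.pairwise_r2(tiny_panel)
    assert np.allclose(np.diag(r2), 1.0)
    calls = np.column_stack([tiny_panel.calls[:, 0], tiny_panel.calls[:, 0], np.ones(30, dtype=np.int8)])
    panel = _panel_from_calls(calls)
    r2 = assoc.pairwise_r2(panel)
    assert r2.iloc[0, 1] == pytest.approx(1.0)  # identical dosage vectors
    assert np.isnan(r2.iloc[0, 2])  # monomorphic partner undefined


def test_ld_decay_roundtrip_recovers_calibrated_distance():
    """Generator round-trip: decay distance within +/-25% of the 54 kb the
    panel was calibrated to."""
    cfg = sg.SimConfig(seed=61, n_chrom=3, snps_per_chrom=400, chrom_length_bp=4_000_000,
                       missing_rate=0.02)
    panel = sg.syndata.simulate_genotypes(cfg)
    decay, _ = assoc.ld_decay_distance(panel, max_dist=300_000, n_bins=30)
    assert 0.75 * 54_000 <= decay <= 1.25 * 54_000
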