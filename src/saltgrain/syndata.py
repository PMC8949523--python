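"""Synthetic diversity-panel generator.

Produces structured genotype panels, multi-environment germination
phenotypes, gene models, differential-expression lists and annotation maps
with the statistical structure the downstream analysis assumes, so the whole
pipeline is testable without any external download.

Genotypes follow a Balding-Nichols model: each SNP has an ancestral
frequency, and each subpopulation draws its own frequency from a Beta
distribution whose spread is controlled by ``fst``. Within-chromosome
linkage disequilibrium is induced by a latent Gaussian AR(1) process along
each haplotype whose correlation length is calibrated so that the mean
genotype r^2 at ``ld_decay_bp`` is ~0.1 (the decay readout the analysis
uses for its QTL window).

Phenotypes are built on the *relative-trait* scale (salt / control ratio):
an accession's relative trait in one environment is the sum of a planted-QTL
genetic value, a latent tolerance deviate shared across environments, an
environment deviate shared across traits, and independent noise, with the
component variances solved from the target heritability, cross-environment
correlation and within-environment cross-trait correlation. Raw control
measurements (shoot/root length, germinated counts out of ``n_seeds_germ``)
are then drawn and the salt-treatment values derived from them through the
relative trait, germination counts binomially.
"""

from __future__ import annotations

import functools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigurationError, PlantedQTL, SimConfig, TRAIT_FAMILIES
from .panel import MISSING, GenotypePanel

# trait means on the relative scale under 100-250 mM NaCl stress
_TRAIT_MEANS = {"RGR": 0.65, "RSL": 0.55, "RRL": 0.50}
_BASELINE_VAR = 0.0225  # relative-trait variance when no genetics is planted (sd 0.15)
_QTL_FAV_FREQ = (0.60, 0.25)  # favorable-allele freq in (favored, other) subpops


# ---------------------------------------------------------------------------
# LD calibration: latent AR(1) correlation length for a target r^2 decay
# ---------------------------------------------------------------------------

def _binary_r2_from_latent(rho: float, p1: float, p2: float) -> float:
    """Squared correlation of two threshold-Gaussian Bernoulli variables."""
    t1, t2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    p11 = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf([t1, t2])
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    return float(((p11 - p1 * p2) / denom) ** 2)


@functools.lru_cache(maxsize=8)
def latent_scale_for_ld(ld_decay_bp: int, target_r2: float = 0.1) -> float:
    """Correlation length L of the latent AR(1) such that allele r^2 at
    distance ``ld_decay_bp`` averages ``target_r2`` over the ancestral
    frequency prior. Latent correlation at distance d is exp(-d/L)."""
    cal_rng = np.random.default_rng(987654321)  # internal, independent of user seeds
    freqs = cal_rng.uniform(0.1, 0.9, size=(40, 2))
    rho_grid = np.linspace(0.1, 0.95, 18)
    mean_r2 = np.array(
        [np.mean([_binary_r2_from_latent(r, p1, p2) for p1, p2 in freqs]) for r in rho_grid]
    )
    if target_r2 <= mean_r2[0]:
        rho_star = rho_grid[0]
    elif target_r2 >= mean_r2[-1]:
        rho_star = rho_grid[-1]
    else:
        rho_star = float(np.interp(target_r2, mean_r2, rho_grid))
    return -ld_decay_bp / np.log(rho_star)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _subpop_assignments(cfg: SimConfig) -> np.ndarray:
    counts = np.floor(np.asarray(cfg.subpop_props) * cfg.n_accessions).astype(int)
    counts[0] += cfg.n_accessions - counts.sum()  # remainder to the first subpop
    return np.repeat(np.arange(len(counts)), counts)


def _distinct_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    pos: set[int] = set()
    while len(pos) < n:
        pos.update(rng.integers(1, length + 1, size=2 * (n - len(pos))).tolist())
    return np.sort(rng.permutation(np.fromiter(pos, dtype=np.int64))[:n])


def simulate_genotypes(cfg: SimConfig) -> GenotypePanel:
    """Draw a structured biallelic panel under the configured conditions.

    Calls are coded 0/1/2 dosages of the minor (at generation time) allele
    with -1 for missing; positions are strictly increasing and 1-based per
    chromosome; SNPs whose realized MAF (on non-missing calls) falls below
    ``cfg.maf_min`` are dropped, except planted-QTL sites which are kept.
    """
    rng = np.random.default_rng(cfg.seed)
    subpop_idx = _subpop_assignments(cfg)
    n_acc, n_sub = cfg.n_accessions, len(cfg.subpop_props)
    L_scale = latent_scale_for_ld(cfg.ld_decay_bp)

    qtl_by_chrom: dict[str, list[PlantedQTL]] = {}
    for q in cfg.planted_qtls:
        qtl_by_chrom.setdefault(q.chrom, []).append(q)

    chroms, poss, calls_cols, qtl_flags = [], [], [], []
    for chrom in cfg.chrom_names:
        positions = _distinct_positions(rng, cfg.snps_per_chrom, cfg.chrom_length_bp)
        is_qtl = np.zeros(len(positions), dtype=bool)
        for q in qtl_by_chrom.get(chrom, []):
            j = int(np.argmin(np.abs(positions - q.pos)))
            positions[j] = q.pos  # force an assayed SNP at the planted site
            is_qtl[j] = True
        order = np.argsort(positions)
        positions, is_qtl = positions[order], is_qtl[order]

        p_anc = rng.uniform(0.1, 0.9, size=len(positions))
        if cfg.fst > 0:
            a = p_anc * (1 - cfg.fst) / cfg.fst
            b = (1 - p_anc) * (1 - cfg.fst) / cfg.fst
            p_sub = rng.beta(a[None, :], b[None, :], size=(n_sub, len(positions)))
            p_sub = np.clip(p_sub, 1e-4, 1 - 1e-4)
        else:
            p_sub = np.tile(p_anc, (n_sub, 1))
        for q in qtl_by_chrom.get(chrom, []):
            j = int(np.searchsorted(positions, q.pos))
            if q.favored_subpop is not None:
                fav = cfg.subpop_names.index(q.favored_subpop)
                p_sub[:, j] = _QTL_FAV_FREQ[1]
                p_sub[fav, j] = _QTL_FAV_FREQ[0]
            else:
                p_sub[:, j] = 0.4

        # latent AR(1) along each of the 2n haplotypes
        n_hap = 2 * n_acc
        hap_sub = np.repeat(subpop_idx, 2)
        z = np.empty((n_hap, len(positions)))
        z[:, 0] = rng.standard_normal(n_hap)
        deltas = np.diff(positions)
        coeffs = np.exp(-deltas / L_scale)
        for j in range(1, len(positions)):
            a_j = coeffs[j - 1]
            z[:, j] = a_j * z[:, j - 1] + np.sqrt(1 - a_j**2) * rng.standard_normal(n_hap)
        thresh = stats.norm.ppf(p_sub)[hap_sub, :]  # (n_hap, n_snp)
        alleles = (z < thresh).astype(np.int8)
        geno = alleles[0::2, :] + alleles[1::2, :]

        chroms.append(np.full(len(positions), chrom, dtype=object))
        poss.append(positions)
        calls_cols.append(geno)
        qtl_flags.append(is_qtl)

    calls = np.concatenate(calls_cols, axis=1)
    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(poss)
    is_qtl = np.concatenate(qtl_flags)

    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(mask, MISSING, calls)

    # recode to minor-allele dosage (planted sites keep the favorable allele coded)
    obs = calls != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(obs, calls, 0).sum(axis=0) / (2.0 * obs.sum(axis=0))
    flip = (freq > 0.5) & ~is_qtl
    calls[:, flip] = np.where(calls[:, flip] == MISSING, MISSING, 2 - calls[:, flip])
    freq = np.where(flip, 1 - freq, freq)

    maf = np.minimum(freq, 1 - freq)
    keep = (maf >= cfg.maf_min) | is_qtl
    panel = GenotypePanel(
        calls=calls[:, keep],
        chrom=chrom_arr[keep],
        pos=pos_arr[keep],
        accessions=[f"ACC{i:04d}" for i in range(1, n_acc + 1)],
        subpop=np.asarray(cfg.subpop_names, dtype=object)[subpop_idx],
    )
    ref = np.where(flip[keep], "G", "A").astype(object)
    alt = np.where(flip[keep], "A", "G").astype(object)
    panel.ref, panel.alt = ref, alt
    return panel


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _variance_components(cov_g: np.ndarray, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-trait weights (V, a, b, d) solving the correlation targets.

    For trait t with planted genetic variance var_g_t the total variance is
    V_t = var_g_t / h2 (a baseline variance when no genetics is planted), the
    across-environment tolerance weight a_t satisfies
    (var_g_t + a_t^2)/V_t ~ env_corr, and the within-environment shared
    weights b_t are solved pairwise so that
    cov_g_tt' + a_t a_t' + b_t b_t' ~ trait_corr sqrt(V_t V_t').
    The independent-noise variance d_t^2 absorbs the remainder, less the
    anticipated binomial counting noise of the germination ratio (out of
    ``n_seeds_germ`` seeds) so realized correlations stay near target.
    """
    n_t = len(TRAIT_FAMILIES)
    var_g = np.diag(cov_g).copy()
    V_nom = np.where(var_g > 0, var_g / max(cfg.h2, 1e-12), _BASELINE_VAR)
    h2_eff = np.where(var_g > 0, cfg.h2, 0.0)

    # counting noise of salt/control germinated ratios (delta-method scale)
    p_bar = 28.0 / 30.0  # mean control germination probability
    m = _TRAIT_MEANS["RGR"]
    v_count = m * (1 - p_bar * m) / (cfg.n_seeds_germ * p_bar) + m**2 * (1 - p_bar) / (cfg.n_seeds_germ * p_bar)
    v_extra = np.array([v_count if t == "RGR" else 0.0 for t in TRAIT_FAMILIES])

    # free independent noise; counting noise spends part of the (1-trait_corr)
    # budget, and the total variance T grows beyond nominal when it overflows
    d2 = np.maximum((1.0 - cfg.trait_corr) * V_nom - v_extra, 0.01 * V_nom)
    T = V_nom + np.maximum(v_extra - (1.0 - cfg.trait_corr) * V_nom, 0.0)
    a = np.zeros(n_t)
    b = np.zeros(n_t)
    for _ in range(4):  # fixed-point on the total variance
        a = np.sqrt(np.maximum(cfg.env_corr * T - var_g, 0.0))
        deficits = {}
        for s in range(n_t):
            for t in range(s + 1, n_t):
                deficits[(s, t)] = cfg.trait_corr * np.sqrt(T[s] * T[t]) - cov_g[s, t] - a[s] * a[t]
        if n_t == 3 and all(d > 0 for d in deficits.values()):
            d01, d02, d12 = deficits[(0, 1)], deficits[(0, 2)], deficits[(1, 2)]
            b = np.sqrt([d01 * d02 / d12, d01 * d12 / d02, d02 * d12 / d01])
        else:
            b = np.sqrt(np.maximum(cfg.trait_corr - np.maximum(cfg.env_corr, h2_eff), 0.0) * T)
        T = var_g + a**2 + b**2 + d2 + v_extra
    return T, a, b, np.sqrt(d2)


def simulate_phenotypes(panel: GenotypePanel, cfg: SimConfig) -> pd.DataFrame:
    """Long-format raw trait table (accession, env, condition, trait, value).

    Traits are ``germ_count`` (out of ``cfg.n_seeds_germ``), ``shoot_len``
    and ``root_len`` (mm), under conditions ``control`` and ``salt``.
    Salt-treatment lengths are control x relative trait clipped at 0; salt
    germination counts are binomial with success probability control
    probability x relative germination, clipped to [0, 1].
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 424242]))
    n = panel.n_accessions
    envs = [f"E{k}" for k in range(1, cfg.n_envs + 1)]

    # genetic values per trait family from planted QTLs (centered dosages)
    genetic = {t: np.zeros(n) for t in TRAIT_FAMILIES}
    if cfg.h2 > 0:
        for q in cfg.planted_qtls:
            try:
                j = panel.locate(q.chrom, q.pos)
            except KeyError as exc:
                raise ConfigurationError(f"planted QTL {q.chrom}:{q.pos} is not present in the panel") from exc
            d = panel.dosage(mean_impute=True)[:, j]
            contrib = q.effect_size * (d - d.mean())
            for t in q.affected_traits:
                genetic[t] += contrib

    tau = rng.standard_normal(n)  # latent tolerance, shared across traits and envs
    c_env = rng.standard_normal((n, cfg.n_envs))  # per accession x env, shared across traits

    G = np.column_stack([genetic[t] for t in TRAIT_FAMILIES])
    cov_g = np.cov(G.T) if np.any(G) else np.zeros((len(TRAIT_FAMILIES), len(TRAIT_FAMILIES)))
    _, a_w, b_w, d_w = _variance_components(np.atleast_2d(cov_g), cfg)

    rel = {}  # (trait, env index) -> relative trait vector
    for ti, t in enumerate(TRAIT_FAMILIES):
        for e in range(cfg.n_envs):
            eps = rng.standard_normal(n)
            r = _TRAIT_MEANS[t] + genetic[t] + a_w[ti] * tau + b_w[ti] * c_env[:, e] + d_w[ti] * eps
            rel[(t, e)] = np.clip(r, 0.0, None)

    rows = []
    for e, env in enumerate(envs):
        sl_ctrl = rng.lognormal(mean=np.log(33.0), sigma=0.15, size=n)
        rl_ctrl = rng.lognormal(mean=np.log(38.0), sigma=0.18, size=n)
        p_ctrl = rng.beta(28, 2, size=n)
        germ_ctrl = rng.binomial(cfg.n_seeds_germ, p_ctrl)
        p_salt = np.clip(p_ctrl * rel[("RGR", e)], 0.0, 1.0)
        germ_salt = rng.binomial(cfg.n_seeds_germ, p_salt)
        sl_salt = sl_ctrl * rel[("RSL", e)]
        rl_salt = rl_ctrl * rel[("RRL", e)]
        for i, acc in enumerate(panel.accessions):
            rows.extend(
                [
                    (acc, env, "control", "germ_count", float(germ_ctrl[i])),
                    (acc, env, "salt", "germ_count", float(germ_salt[i])),
                    (acc, env, "control", "shoot_len", float(sl_ctrl[i])),
                    (acc, env, "salt", "shoot_len", float(sl_salt[i])),
                    (acc, env, "control", "root_len", float(rl_ctrl[i])),
                    (acc, env, "salt", "root_len", float(rl_salt[i])),
                ]
            )
    return pd.DataFrame(rows, columns=["accession", "env", "condition", "trait", "value"])


# ---------------------------------------------------------------------------
# Gene models, DEG lists, annotations
# ---------------------------------------------------------------------------

def simulate_gene_models(
    cfg: SimConfig, genes_per_chrom: int = 10, mean_len: int = 3000, seed: int | None = None
) -> pd.DataFrame:
    """Non-overlapping gene intervals with stable IDs (``chrom, start, end,
    strand, gene_id``), one slot-placed gene per chromosome segment."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    gid = 1
    for chrom in cfg.chrom_names:
        slot = cfg.chrom_length_bp // genes_per_chrom
        for k in range(genes_per_chrom):
            length = max(200, int(rng.exponential(mean_len)))
            length = min(length, slot - 2)
            start = slot * k + 1 + int(rng.integers(0, max(1, slot - length - 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"Lus1{gid:07d}", chrom, start, start + length - 1, strand))
            gid += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def simulate_deg_lists(
    genes: pd.DataFrame,
    fraction_up: float = 0.05,
    fraction_down: float = 0.05,
    seed: int = 0,
    n_lists: int = 2,
) -> list[pd.DataFrame]:
    """Independent differential-expression call sets over the gene universe.

    Each list is a two-column table (gene_id, direction in {up, down}) drawn
    without replacement; lists emulate independent salt-stress transcriptome
    reports used as candidate-gene evidence.
    """
    rng = np.random.default_rng(seed)
    out = []
    ids = genes["gene_id"].to_numpy()
    for _ in range(n_lists):
        n_up = int(round(fraction_up * len(ids)))
        n_down = int(round(fraction_down * len(ids)))
        pick = rng.choice(ids, size=min(n_up + n_down, len(ids)), replace=False)
        direction = ["up"] * n_up + ["down"] * n_down
        out.append(pd.DataFrame({"gene_id": pick[: len(direction)], "direction": direction[: len(pick)]}))
    return out


_SALT_PHRASES = [
    "Glutathione S-transferase (GST)",
    "NAC domain transcription factor",
    "WRKY transcription factor",
    "bZIP transcription factor",
    "ERF/AP2 ethylene-responsive factor",
    "MYB transcription factor",
    "ABA-responsive protein",
    "SnRK2 serine/threonine kinase",
    "ABC transporter family protein",
    "RING finger E3 ubiquitin ligase",
]
_NEUTRAL_PHRASES = [
    "ribosomal protein L13",
    "photosystem II reaction center",
    "cellulose synthase-like protein",
    "pentatricopeptide repeat protein",
    "unknown function",
    "tubulin beta chain",
]


def simulate_annotations(genes: pd.DataFrame, salt_fraction: float = 0.2, seed: int = 0) -> pd.DataFrame:
    """Homolog-annotation map (gene_id, homolog_id, function); a configurable
    fraction of genes receives a stress-related functional phrase."""
    rng = np.random.default_rng(seed)
    funcs, homologs = [], []
    for k in range(len(genes)):
        if rng.random() < salt_fraction:
            funcs.append(_SALT_PHRASES[int(rng.integers(len(_SALT_PHRASES)))])
        else:
            funcs.append(_NEUTRAL_PHRASES[int(rng.integers(len(_NEUTRAL_PHRASES)))])
        homologs.append(f"AT{int(rng.integers(1, 6))}G{int(rng.integers(1, 80000)):05d}")
    return pd.DataFrame({"gene_id": genes["gene_id"], "homolog_id": homologs, "function": funcs})


# ---------------------------------------------------------------------------
# Fixture writers
# ---------------------------------------------------------------------------

def write_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                f"{g.chrom}\tsaltgrain\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_traits_csv(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, index=False)
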