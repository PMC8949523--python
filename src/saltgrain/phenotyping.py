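"""Germination-stage phenotyping: relative traits, membership-function
scoring and salt-tolerance grading.

The composite tolerance score D of an accession is a coefficient-of-
variation-weighted sum of min-max-normalized trait indices:

    mu(X_i) = (X_i - X_i_min) / (X_i_max - X_i_min)          (membership)
    W_i     = CV_i / sum_j CV_j,   CV_i = sd(mu_i)/mean(mu_i) (weights)
    D       = sum_i mu(X_i) * W_i                             (score)

where X_i is the i-th relative trait index (treatment/control ratio),
min/max are taken over the panel, and CV uses the sample standard
deviation (n-1). Accessions with any missing index are excluded from D;
an index constant across the panel carries no information and is dropped
with a warning before weighting.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "germination_rate",
    "relative_value",
    "relative_traits",
    "membership_mu",
    "cv_weights",
    "d_value",
    "d_scores",
    "assign_grades",
    "grade_percentages",
    "trait_summary",
    "trait_correlations",
    "GRADE_NAMES_5",
    "D_INDICES",
]

#: indices entering the composite score: panel averages of the relative traits
D_INDICES = ("RGR-AVG", "RSL-AVG", "RRL-AVG")

#: five ordered tolerance grades, most tolerant first
GRADE_NAMES_5 = ("high-tolerance", "tolerant", "moderate", "sensitive", "high-sensitivity")


def germination_rate(n_germinated, n_seeds: int = 50):
    """Percentage of seeds germinated: 100 * n_germinated / n_seeds."""
    n_germinated = np.asarray(n_germinated, dtype=float)
    if n_seeds <= 0:
        raise ValueError("n_seeds must be positive")
    if np.any(n_germinated < 0) or np.any(n_germinated > n_seeds):
        raise ValueError("germinated count must lie in [0, n_seeds]")
    out = 100.0 * n_germinated / n_seeds
    return float(out) if out.ndim == 0 else out


def relative_value(treatment, control):
    """Salt-stress value divided by control value; NaN when control is 0.

    Values above 1 are allowed (mild stimulation under stress occurs)."""
    treatment = np.asarray(treatment, dtype=float)
    control = np.asarray(control, dtype=float)
    if np.any(treatment < 0) or np.any(control < 0):
        raise ValueError("measurements must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(control > 0, treatment / np.where(control > 0, control, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


_TRAIT_TO_INDEX = {"germ_count": "RGR", "shoot_len": "RSL", "root_len": "RRL"}


def relative_traits(raw: pd.DataFrame) -> pd.DataFrame:
    """Wide per-accession table of relative traits from a long raw table.

    ``raw`` has columns (accession, env, condition, trait, value) with
    conditions control/salt and traits germ_count/shoot_len/root_len.
    Output columns are RGR/RSL/RRL per environment suffix (RGR1, ...) plus
    RGR-AVG/RSL-AVG/RRL-AVG averaged over non-missing environments.
    A relative value is missing (NaN), never 0, when its control is 0.
    """
    wide = raw.pivot_table(index=["accession", "env", "trait"], columns="condition", values="value", aggfunc="first")
    for cond in ("control", "salt"):
        if cond not in wide.columns:
            raise ValueError(f"raw trait table lacks condition '{cond}'")
    rel = pd.Series(relative_value(wide["salt"].to_numpy(), wide["control"].to_numpy()), index=wide.index)
    rel = rel.reset_index(name="value")
    rel["index"] = rel["trait"].map(_TRAIT_TO_INDEX) + rel["env"].str.extract(r"(\d+)$", expand=False)
    out = rel.pivot(index="accession", columns="index", values="value")
    envs = sorted(raw["env"].unique())
    for fam in ("RGR", "RSL", "RRL"):
        cols = [c for c in out.columns if c.startswith(fam)]
        out[f"{fam}-AVG"] = out[cols].mean(axis=1)  # non-missing envs only
    return out.rename_axis(columns=None)


def membership_mu(x, x_min: float, x_max: float):
    """Min-max membership value (x - x_min)/(x_max - x_min) in [0, 1].

    Returns NaN for every value when the index is degenerate
    (x_max == x_min); callers drop such indices."""
    x = np.asarray(x, dtype=float)
    if np.any(x < x_min - 1e-12) or np.any(x > x_max + 1e-12):
        raise ValueError("x outside [x_min, x_max]")
    if x_max == x_min:
        out = np.full_like(x, np.nan)
        return float(out) if out.ndim == 0 else out
    out = (x - x_min) / (x_max - x_min)
    return float(out) if out.ndim == 0 else out


def cv_weights(mu_matrix) -> np.ndarray:
    """Per-index weights proportional to the coefficient of variation of the
    membership values (sample sd / mean); weights sum to 1."""
    mu = np.asarray(mu_matrix, dtype=float)
    if mu.ndim != 2 or mu.shape[0] < 2 or mu.shape[1] < 1:
        raise ValueError("mu_matrix must be (>=2 accessions) x (>=1 indices)")
    means = mu.mean(axis=0)
    if np.any(means == 0):
        raise ValueError("an index has zero mean membership; CV undefined")
    cv = mu.std(axis=0, ddof=1) / means
    total = cv.sum()
    if total == 0:
        raise ValueError("all indices constant; no variation to weight")
    return cv / total


def d_value(mu_row, weights):
    """Weighted sum of membership values; rows and weights must align and
    weights must sum to 1."""
    mu = np.asarray(mu_row, dtype=float)
    w = np.asarray(weights, dtype=float)
    if mu.shape[-1] != w.shape[0]:
        raise ValueError("mu_row and weights length mismatch")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return mu @ w


def d_scores(traits: pd.DataFrame, indices: tuple[str, ...] = D_INDICES) -> pd.DataFrame:
    """Per-accession membership values, weights and composite D score.

    Accessions missing any index are excluded (logged); degenerate indices
    (no panel spread) are dropped and weights renormalized over the rest.
    Returns a frame indexed by accession with mu_<index> columns, the D
    column, and the weights in ``.attrs["weights"]``.
    """
    sub = traits[list(indices)]
    complete = sub.dropna()
    if len(complete) < len(sub):
        warnings.warn(
            f"excluded {len(sub) - len(complete)} accession(s) with missing indices from D scoring",
            stacklevel=2,
        )
    kept = []
    mu_cols = {}
    for idx in indices:
        x = complete[idx].to_numpy()
        if x.max() == x.min():
            warnings.warn(f"index {idx} is constant across the panel; dropped from D", stacklevel=2)
            continue
        mu_cols[f"mu_{idx}"] = membership_mu(x, x.min(), x.max())
        kept.append(idx)
    if not kept:
        raise ValueError("no informative indices remain for D scoring")
    mu = np.column_stack([mu_cols[f"mu_{i}"] for i in kept])
    w = cv_weights(mu)
    out = pd.DataFrame(mu_cols, index=complete.index)
    out["D"] = d_value(mu, w)
    out.attrs["weights"] = dict(zip(kept, w))
    return out


def assign_grades(d_values: pd.Series | np.ndarray, k: int = 5) -> pd.Series:
    """Partition accessions into ``k`` ordered tolerance grades by 1-D Ward
    agglomerative clustering on D, grade 1 = highest mean D. For k=5 the
    returned series carries grade names in ``.attrs['grade_names']``."""
    d = pd.Series(d_values).dropna()
    if k < 2 or k > len(d):
        raise ValueError(f"k must be in [2, {len(d)}]")
    vals = d.to_numpy(dtype=float)
    if np.all(vals == vals[0]):
        raise ValueError("all D values identical; no grade partition exists")
    Z = linkage(vals.reshape(-1, 1), method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    order = pd.Series(vals).groupby(raw).mean().sort_values(ascending=False)
    remap = {c: g + 1 for g, c in enumerate(order.index)}
    grades = pd.Series([remap[c] for c in raw], index=d.index, name="grade")
    if k == len(GRADE_NAMES_5):
        grades.attrs["grade_names"] = dict(zip(range(1, k + 1), GRADE_NAMES_5))
    return grades


def grade_percentages(counts) -> np.ndarray:
    """Percentage of the panel in each grade from per-grade counts."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0) or counts.sum() == 0:
        raise ValueError("counts must be non-negative and not all zero")
    return 100.0 * counts / counts.sum()


def trait_summary(traits: pd.DataFrame) -> pd.DataFrame:
    """Min, max, mean and CV (sample sd / mean) per relative-trait column."""
    num = traits.select_dtypes(float)
    summ = pd.DataFrame(
        {
            "min": num.min(),
            "max": num.max(),
            "mean": num.mean(),
            "sd": num.std(ddof=1),
        }
    )
    summ["cv"] = summ["sd"] / summ["mean"]
    return summ


def trait_correlations(traits: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between relative-trait columns;
    cells with fewer than ``min_pairs`` complete pairs are NaN."""
    num = traits.select_dtypes(float)
    if len(num) < 3:
        raise ValueError("need >=3 accessions for correlations")
    corr = num.corr(method="pearson", min_periods=min_pairs)
    return corr
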