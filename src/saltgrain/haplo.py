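"""Lead-SNP haplotype comparison and subpopulation allele frequencies.

In a highly selfing crop most accessions are homozygous at any SNP, so the
two homozygous genotype classes (e.g. GG vs AA) define the haplotype
groups; heterozygous calls are excluded by default (configurable to keep
them as a third group). Group trait distributions are compared with
Welch's unequal-variance t-test (two-sided, Satterthwaite degrees of
freedom).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .panel import MISSING, GenotypePanel


@dataclasses.dataclass
class HaplotypeComparison:
    chrom: str
    pos: int
    groups: dict[str, pd.Series]  # genotype label -> trait values by accession
    group_stats: pd.DataFrame  # mean, sd, n per group
    t_statistic: float | None
    df: float | None
    p_value: float | None
    performed: bool
    note: str = ""


def split_by_allele(
    panel: GenotypePanel,
    chrom: str,
    pos: int,
    trait: pd.Series,
    het_policy: str = "exclude",
) -> dict[str, pd.Series]:
    """Partition accessions by genotype class at a SNP.

    Returns a mapping of genotype label (e.g. ``"GG"``, ``"AA"``, and
    ``"AG"`` when ``het_policy="keep"``) to the trait values of the
    accessions in that class; missing genotypes are always excluded.
    """
    j = panel.locate(chrom, pos)
    calls = panel.calls[:, j]
    ref, alt = str(panel.ref[j]), str(panel.alt[j])
    labels = {0: ref + ref, 1: ref + alt, 2: alt + alt}
    trait = trait.reindex(panel.accessions)
    groups: dict[str, pd.Series] = {}
    for code, label in labels.items():
        if code == 1 and het_policy == "exclude":
            continue
        mask = calls == code
        vals = trait[np.asarray(mask)].dropna()
        if len(vals):
            groups[label] = vals
    return groups


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t: statistic, Satterthwaite df, two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for name, g in (("first", a), ("second", b)):
        if len(g) < 2:
            raise ValueError(f"{name} group has fewer than 2 observations")
        if np.var(g, ddof=1) == 0:
            raise ValueError(f"{name} group has zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_haplotypes(
    panel: GenotypePanel,
    chrom: str,
    pos: int,
    trait: pd.Series,
    het_policy: str = "exclude",
) -> HaplotypeComparison:
    """Two-group haplotype comparison at a lead SNP.

    When fewer than two genotype classes carry data (monomorphic SNP) the
    comparison is flagged not performed instead of erroring.
    """
    groups = split_by_allele(panel, chrom, pos, trait, het_policy=het_policy)
    gstats = pd.DataFrame(
        {
            label: {"mean": v.mean(), "sd": v.std(ddof=1), "n": len(v)}
            for label, v in groups.items()
        }
    ).T
    hom = {k: v for k, v in groups.items() if k[0] == k[1]}
    if len(hom) < 2:
        return HaplotypeComparison(chrom, pos, groups, gstats, None, None, None, False, note="fewer than two homozygous classes with data")
    (la, va), (lb, vb) = sorted(hom.items())[:2]
    t, df, p = welch_t(va, vb)
    return HaplotypeComparison(chrom, pos, groups, gstats, t, df, p, True, note=f"{la} vs {lb}")


def allele_freq_by_subpop(
    panel: GenotypePanel, chrom: str, pos: int, subpop: np.ndarray | None = None
) -> pd.DataFrame:
    """Allele counts and frequencies per subpopulation at one SNP.

    Frequencies are over non-missing calls and sum to 1 per subpopulation.
    """
    j = panel.locate(chrom, pos)
    labels = subpop if subpop is not None else panel.subpop
    if labels is None:
        raise ValueError("no subpopulation labels available")
    labels = np.asarray(labels, dtype=object)
    if len(labels) != panel.n_accessions:
        raise ValueError("subpopulation labels length mismatch")
    calls = panel.calls[:, j]
    ref, alt = str(panel.ref[j]), str(panel.alt[j])
    rows = []
    for sp in pd.unique(labels):
        mask = (labels == sp) & (calls != MISSING)
        c = calls[mask].astype(int)
        n_alleles = 2 * mask.sum()
        alt_count = int(c.sum())
        if n_alleles == 0:
            rows.append({"subpop": sp, "allele": ref, "count": 0, "freq": np.nan})
            rows.append({"subpop": sp, "allele": alt, "count": 0, "freq": np.nan})
            continue
        rows.append({"subpop": sp, "allele": ref, "count": n_alleles - alt_count, "freq": (n_alleles - alt_count) / n_alleles})
        rows.append({"subpop": sp, "allele": alt, "count": alt_count, "freq": alt_count / n_alleles})
    return pd.DataFrame(rows)


def haplotype_long_table(comparison: HaplotypeComparison, trait_name: str = "trait") -> pd.DataFrame:
    """Boxplot-ready long format: accession, genotype group, trait value."""
    rows = []
    for label, vals in comparison.groups.items():
        for acc, v in vals.items():
            rows.append({"accession": acc, "group": label, "trait": trait_name, "value": v})
    return pd.DataFrame(rows)
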