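"""Genotype panel container with VCF and TSV input/output.

The panel holds biallelic calls as an accessions x SNPs int8 matrix of
coded-allele dosages (0/1/2) with -1 for missing, plus per-SNP chromosome
and 1-based position metadata and optional per-accession subpopulation
labels. VCF reading/writing goes through :mod:`pysam`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

MISSING = np.int8(-1)


@dataclasses.dataclass
class GenotypePanel:
    calls: np.ndarray  # (n_accessions, n_snps) int8, -1 = missing
    chrom: np.ndarray  # (n_snps,) str
    pos: np.ndarray  # (n_snps,) int64, 1-based
    accessions: list[str]
    snp_id: np.ndarray | None = None
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    subpop: np.ndarray | None = None  # (n_accessions,) str labels

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n_acc, n_snp = self.calls.shape
        if len(self.accessions) != n_acc:
            raise ValueError("accession list length does not match call matrix")
        if len(self.chrom) != n_snp or len(self.pos) != n_snp:
            raise ValueError("SNP metadata length does not match call matrix")
        if self.snp_id is None:
            self.snp_id = np.array([f"{c}_{p}" for c, p in zip(self.chrom, self.pos)], dtype=object)
        if self.ref is None:
            self.ref = np.full(n_snp, "A", dtype=object)
        if self.alt is None:
            self.alt = np.full(n_snp, "G", dtype=object)
        if self.subpop is not None:
            self.subpop = np.asarray(self.subpop, dtype=object)
            if len(self.subpop) != n_acc:
                raise ValueError("subpop labels length does not match accessions")

    # -- basic properties -------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the coded allele among non-missing calls."""
        masked = np.ma.masked_equal(self.calls, MISSING)
        return np.asarray(masked.mean(axis=0).filled(np.nan)) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP on non-missing calls."""
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def dosage(self, mean_impute: bool = False) -> np.ndarray:
        """Float dosage matrix; missing as NaN or per-SNP mean-imputed."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        if mean_impute:
            col_mean = np.nanmean(d, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(d))
            d[idx] = col_mean[idx[1]]
        return d

    # -- subsetting -------------------------------------------------------

    def take_snps(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            calls=self.calls[:, index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            accessions=list(self.accessions),
            snp_id=self.snp_id[index],
            ref=self.ref[index],
            alt=self.alt[index],
            subpop=None if self.subpop is None else self.subpop.copy(),
        )

    def region(self, chrom: str, start: int, end: int) -> "GenotypePanel":
        """SNPs on ``chrom`` with start <= pos <= end (closed, 1-based)."""
        mask = (self.chrom == chrom) & (self.pos >= start) & (self.pos <= end)
        return self.take_snps(np.where(mask)[0])

    def locate(self, chrom: str, pos: int) -> int:
        """Column index of the SNP at (chrom, pos)."""
        hits = np.where((self.chrom == chrom) & (self.pos == pos))[0]
        if hits.size == 0:
            raise KeyError(f"no SNP at {chrom}:{pos}")
        return int(hits[0])

    # -- I/O --------------------------------------------------------------

    def to_vcf(self, path: str | Path) -> None:
        """Write a GT-only VCF v4.2."""
        path = Path(path)
        header = pysam.VariantHeader()
        header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lengths: dict[str, int] = {}
        for c, p in zip(self.chrom, self.pos):
            lengths[c] = max(lengths.get(c, 0), int(p))
        for c, ln in lengths.items():
            header.contigs.add(c, length=ln)
        for acc in self.accessions:
            header.add_sample(acc)
        with pysam.VariantFile(str(path), "w", header=header) as vf:
            for j in range(self.n_snps):
                rec = vf.new_record(
                    contig=str(self.chrom[j]),
                    start=int(self.pos[j]) - 1,
                    stop=int(self.pos[j]),
                    alleles=(str(self.ref[j]), str(self.alt[j])),
                    id=str(self.snp_id[j]),
                )
                col = self.calls[:, j]
                for i, acc in enumerate(self.accessions):
                    g = col[i]
                    if g == MISSING:
                        rec.samples[acc]["GT"] = (None, None)
                    else:
                        rec.samples[acc]["GT"] = (0, 0) if g == 0 else ((0, 1) if g == 1 else (1, 1))
                vf.write(rec)

    @classmethod
    def from_vcf(cls, path: str | Path, subpop_tsv: str | Path | None = None) -> "GenotypePanel":
        with pysam.VariantFile(str(path)) as vf:
            accessions = list(vf.header.samples)
            chrom, pos, snp_id, ref, alt, rows = [], [], [], [], [], []
            for rec in vf:
                if rec.alts is None or len(rec.alts) != 1:
                    continue  # biallelic only
                chrom.append(rec.chrom)
                pos.append(rec.pos)
                snp_id.append(rec.id or f"{rec.chrom}_{rec.pos}")
                ref.append(rec.ref)
                alt.append(rec.alts[0])
                row = np.empty(len(accessions), dtype=np.int8)
                for i, acc in enumerate(accessions):
                    gt = rec.samples[acc].get("GT")
                    if gt is None or any(a is None for a in gt):
                        row[i] = MISSING
                    else:
                        row[i] = sum(gt)
                rows.append(row)
        panel = cls(
            calls=np.array(rows, dtype=np.int8).T if rows else np.empty((len(accessions), 0), dtype=np.int8),
            chrom=np.array(chrom, dtype=object),
            pos=np.array(pos, dtype=np.int64),
            accessions=accessions,
            snp_id=np.array(snp_id, dtype=object),
            ref=np.array(ref, dtype=object),
            alt=np.array(alt, dtype=object),
        )
        if subpop_tsv is not None:
            panel.subpop = read_subpops(subpop_tsv, accessions)
        return panel

    def to_tsv(self, path: str | Path) -> None:
        """Simple tabular dialect: rows = SNPs, columns = accessions,
        leading columns chrom/pos/snp_id/ref/alt; missing written as NA."""
        df = pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "snp_id": self.snp_id, "ref": self.ref, "alt": self.alt}
        )
        geno = pd.DataFrame(self.calls.T, columns=self.accessions).replace(int(MISSING), pd.NA)
        pd.concat([df, geno], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path, subpop_tsv: str | Path | None = None) -> "GenotypePanel":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        meta_cols = ["chrom", "pos", "snp_id", "ref", "alt"]
        acc = [c for c in df.columns if c not in meta_cols]
        calls = df[acc].to_numpy(dtype=float)
        calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8).T
        panel = cls(
            calls=calls,
            chrom=df["chrom"].to_numpy(dtype=object),
            pos=df["pos"].to_numpy(dtype=np.int64),
            accessions=acc,
            snp_id=df["snp_id"].to_numpy(dtype=object),
            ref=df["ref"].to_numpy(dtype=object),
            alt=df["alt"].to_numpy(dtype=object),
        )
        if subpop_tsv is not None:
            panel.subpop = read_subpops(subpop_tsv, acc)
        return panel

    def write_subpops(self, path: str | Path) -> None:
        if self.subpop is None:
            raise ValueError("panel carries no subpopulation labels")
        pd.DataFrame({"accession": self.accessions, "subpop": self.subpop}).to_csv(path, sep="\t", index=False)


def read_subpops(path: str | Path, accessions: list[str]) -> np.ndarray:
    df = pd.read_csv(path, sep="\t").set_index("accession")
    missing = [a for a in accessions if a not in df.index]
    if missing:
        raise ValueError(f"subpopulation file lacks labels for {len(missing)} accessions, e.g. {missing[:3]}")
    return df.loc[accessions, "subpop"].to_numpy(dtype=object)
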