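"""End-to-end orchestration: simulate -> phenotype -> scan -> QTL ->
triage -> haplotype, with a reproducibility manifest.

A single YAML (or dict) config drives every stage; all analysis thresholds
(the 54 kb QTL window, the family-wise alpha behind the Bonferroni GLM
threshold, the fixed MLM threshold, the annotation keyword set) surface
there. Outputs are plain text (VCF/TSV/CSV/GFF3/JSON) and every written
file is recorded in the manifest with its SHA-256 hash, so a rerun with the
same config and seed is verifiably identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import assoc, haplo, phenotyping, qtl, syndata, triage
from .config import ConfigurationError, PlantedQTL, ScanConfig, SimConfig, demo_planted_qtls
from .panel import GenotypePanel

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def default_config() -> dict:
    return {
        "sim": {},  # SimConfig fields; planted_qtls: "demo" or list of dicts
        "genes": {"genes_per_chrom": 200, "mean_len": 3000},
        "deg": {"fraction_up": 0.05, "fraction_down": 0.05},
        "annotation": {"salt_fraction": 0.2},
        "scan": {},  # ScanConfig fields
        "qtl": {"half_width": qtl.DEFAULT_HALF_WIDTH, "require_multi_context": True, "distinct_positions": False},
        "triage": {"keywords": list(triage.DEFAULT_KEYWORDS)},
        "haplo": {"trait": "RGR-AVG", "max_snps": 5},
    }


def load_config(source: dict | str | Path | None) -> dict:
    cfg = default_config()
    if source is None:
        return cfg
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = source
    if not isinstance(user, dict):
        raise ConfigurationError("pipeline config must be a mapping")
    unknown = set(user) - set(cfg)
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    for key, val in user.items():
        if not isinstance(val, dict):
            raise ConfigurationError(f"config section {key!r} must be a mapping")
        cfg[key] = {**cfg[key], **val}
    return cfg


def _build_sim_config(section: dict, seed: int) -> SimConfig:
    section = dict(section)
    qtls = section.pop("planted_qtls", "demo")
    if qtls == "demo":
        planted = demo_planted_qtls()
    else:
        planted = [q if isinstance(q, PlantedQTL) else PlantedQTL(**q) for q in (qtls or [])]
    try:
        return SimConfig(**section, planted_qtls=planted, seed=seed)
    except TypeError as exc:
        raise ConfigurationError(f"bad sim section: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunResult:
    manifest: dict
    out_dir: Path
    panel: GenotypePanel
    traits: pd.DataFrame
    scores: pd.DataFrame
    results: pd.DataFrame
    qtls: list
    candidates: pd.DataFrame


def run_pipeline(config: dict | str | Path | None, out_dir: str | Path, seed: int = 0) -> RunResult:
    """Execute every stage and write artifacts plus ``manifest.json``.

    Stage failures raise with the stage name; outputs written before the
    failure are left in place for debugging.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": seed, "config": _jsonable(cfg), "stages": {}, "files": {}}
    counts: dict[str, int] = {}

    def record(stage: str, t0: float, files: dict[str, Path]) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        for label, path in files.items():
            manifest["files"][label] = {"path": path.name, "sha256": _sha256(path)}

    stage = "simulate"
    try:
        t0 = time.time()
        sim_cfg = _build_sim_config(cfg["sim"], seed)
        panel = syndata.simulate_genotypes(sim_cfg)
        raw = syndata.simulate_phenotypes(panel, sim_cfg)
        genes = syndata.simulate_gene_models(sim_cfg, **cfg["genes"])
        deg_lists = syndata.simulate_deg_lists(genes, seed=seed + 1, **cfg["deg"])
        annot = syndata.simulate_annotations(genes, seed=seed + 2, **cfg["annotation"])
        panel.to_vcf(out / "panel.vcf")
        panel.write_subpops(out / "subpops.tsv")
        raw.to_csv(out / "traits_raw.csv", index=False)
        syndata.write_gff3(genes, out / "genes.gff3")
        for i, deg in enumerate(deg_lists, start=1):
            deg.to_csv(out / f"deg_list{i}.tsv", sep="\t", index=False)
        annot.to_csv(out / "annotations.tsv", sep="\t", index=False)
        record(stage, t0, {"panel": out / "panel.vcf", "traits_raw": out / "traits_raw.csv", "genes": out / "genes.gff3"})
        counts["n_accessions"] = panel.n_accessions
        counts["n_snps_simulated"] = panel.n_snps

        stage = "phenotype"
        t0 = time.time()
        traits = phenotyping.relative_traits(raw)
        scores = phenotyping.d_scores(traits)
        scores["grade"] = phenotyping.assign_grades(scores["D"])
        per_acc = traits.join(scores)
        per_acc.to_csv(out / "scores.csv")
        phenotyping.trait_summary(traits).to_csv(out / "trait_summary.csv")
        record(stage, t0, {"scores": out / "scores.csv"})

        stage = "scan"
        t0 = time.time()
        scan_cfg = ScanConfig(**cfg["scan"])
        fpanel, filt_report = assoc.filter_snps(panel, scan_cfg)
        results = assoc.scan_traits(fpanel, traits, scan_cfg)
        results.to_csv(out / "assoc.tsv", sep="\t", index=False)
        n_tests = fpanel.n_snps
        glm_thr = assoc.bonferroni_threshold(n_tests, scan_cfg.alpha)
        hits = assoc.significant_hits(results, glm_thr, scan_cfg.mlm_threshold_log10p)
        deduped = assoc.dedupe_snps(hits)
        record(stage, t0, {"assoc": out / "assoc.tsv"})
        counts.update(
            n_snps_filtered=filt_report["n_retained"],
            glm_threshold=round(glm_thr, 4),
            n_hits=len(hits),
            n_snps_deduped=len(deduped),
        )

        stage = "qtl"
        t0 = time.time()
        windows = qtl.make_windows(hits, half_width=cfg["qtl"]["half_width"])
        merged = qtl.merge_windows(windows)
        retained = qtl.retain_qtls(
            merged,
            require_multi_context=cfg["qtl"]["require_multi_context"],
            distinct_positions=cfg["qtl"]["distinct_positions"],
        )
        named = qtl.select_lead_and_name(retained)
        table = qtl.qtl_table(named)
        table.to_csv(out / "qtl.tsv", sep="\t", index=False)
        qtl.write_bed(named, out / "qtl.bed")
        record(stage, t0, {"qtl": out / "qtl.tsv", "qtl_bed": out / "qtl.bed"})
        counts.update(n_windows=len(windows), n_merged=len(merged), n_qtls=len(named))

        stage = "triage"
        t0 = time.time()
        in_qtls = triage.genes_in_qtls(named, genes)
        deg_named = {f"list{i}": d for i, d in enumerate(deg_lists, start=1)}
        evidence, deg_counts = triage.intersect_deg(in_qtls, deg_named)
        candidates = triage.annotate_candidates(evidence, annot, keywords=tuple(cfg["triage"]["keywords"]))
        candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
        deg_counts.to_csv(out / "deg_counts.tsv", sep="\t", index=False)
        record(stage, t0, {"candidates": out / "candidates.tsv"})
        counts.update(n_genes_in_qtls=len(in_qtls), n_candidates=int(candidates["candidate"].sum()))

        stage = "haplo"
        t0 = time.time()
        hap_trait = cfg["haplo"]["trait"]
        trait_series = per_acc[hap_trait] if hap_trait in per_acc.columns else scores["D"]
        hap_rows = []
        for rec in named[: cfg["haplo"]["max_snps"]]:
            comp = haplo.compare_haplotypes(fpanel, rec.chrom, rec.lead_snp, trait_series)
            freqs = haplo.allele_freq_by_subpop(panel, rec.chrom, rec.lead_snp)
            for _, fr in freqs.iterrows():
                hap_rows.append(
                    {
                        "qtl": rec.name,
                        "chrom": rec.chrom,
                        "pos": rec.lead_snp,
                        "subpop": fr["subpop"],
                        "allele": fr["allele"],
                        "freq": fr["freq"],
                        "t": comp.t_statistic,
                        "p": comp.p_value,
                    }
                )
        pd.DataFrame(hap_rows).to_csv(out / "haplo.tsv", sep="\t", index=False)
        record(stage, t0, {"haplo": out / "haplo.tsv"})
    except ConfigurationError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["counts"] = counts
    # every artifact in the output directory is declared with its hash
    for path in sorted(out.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][path.name] = {"path": path.name, "sha256": _sha256(path)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline funnel: %s", counts)
    return RunResult(manifest, out, panel, traits, scores, results, named, candidates)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj):
        return _jsonable(dataclasses.asdict(obj))
    return obj
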