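"""Candidate-gene triage inside QTL intervals.

Genes overlapping a retained QTL by at least one base pair are preliminary
candidates; evidence is then accumulated from (i) intersection with
differential-expression lists from salt-stress transcriptomes (direction
kept per list, conflicts preserved) and (ii) keyword matches against
homolog functional annotations. A gene is flagged candidate when it has
differential-expression evidence in at least one list or an annotation
match — adding a list or a keyword can only add candidates, never remove
one.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: default salt-stress annotation keywords (case-insensitive whole-word);
#: a configurable stand-in for literature-based manual curation
DEFAULT_KEYWORDS = (
    "salt",
    "saline",
    "osmotic",
    "ABA",
    "GST",
    "glutathione",
    "SnRK",
    "NAC",
    "WRKY",
    "bZIP",
    "ERF",
    "AP2",
    "MYB",
    "C2H2",
    "ABC transporter",
    "RING",
)


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Gene records from a GFF3 file as (gene_id, chrom, start, end, strand).

    Non-gene features are ignored; malformed records are skipped with a
    logged warning.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                logger.warning("skipping malformed GFF3 line %d in %s", ln, path)
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            m = re.search(r"ID=([^;]+)", attrs)
            if m is None or not start.isdigit() or not end.isdigit():
                logger.warning("skipping gene without ID or coordinates at line %d in %s", ln, path)
                continue
            rows.append((m.group(1), chrom, int(start), int(end), strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def genes_in_qtls(qtls, genes: pd.DataFrame, full_containment: bool = False) -> pd.DataFrame:
    """Genes intersecting at least one QTL interval.

    ``qtls`` is a list of QTLRecord or a frame with name/chrom/start/end.
    Overlap requires >=1 shared bp (closed 1-based coordinates); with
    ``full_containment=True`` the gene must lie entirely inside the QTL.
    Returns one row per gene with the comma-joined overlapping QTL names.
    """
    if not isinstance(qtls, pd.DataFrame):
        qtls = pd.DataFrame(
            [{"name": r.name, "chrom": r.chrom, "start": r.start, "end": r.end} for r in qtls]
        )
    trees: dict[str, IntervalTree] = {}
    for _, q in qtls.iterrows():
        # +1: IntervalTree is half-open, our coordinates closed
        trees.setdefault(q["chrom"], IntervalTree()).addi(int(q["start"]), int(q["end"]) + 1, q["name"])
    rows = []
    for _, g in genes.iterrows():
        tree = trees.get(g["chrom"])
        if tree is None:
            continue
        hits = tree.overlap(int(g["start"]), int(g["end"]) + 1)
        if full_containment:
            hits = {h for h in hits if h.begin <= int(g["start"]) and h.end >= int(g["end"]) + 1}
        if hits:
            names = sorted(h.data for h in hits)
            rows.append({**g.to_dict(), "qtl_names": ",".join(names)})
    return pd.DataFrame(rows, columns=list(genes.columns) + ["qtl_names"])


def intersect_deg(genes: pd.DataFrame, deg_lists: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential-expression evidence per gene and per-list overlap counts.

    Each DEG list is a frame (gene_id, direction in {up, down}). Returns
    (evidence, counts): evidence adds one ``deg_<list>`` column per list
    with values absent/up/down; counts reports per-list overlap and up/down
    split plus a ``common`` row for genes present in every list.
    """
    evidence = genes.copy()
    count_rows = []
    per_list_sets = []
    for name, deg in deg_lists.items():
        if len(deg):
            mapping = deg.set_index("gene_id")["direction"]
            overlap = evidence["gene_id"].isin(mapping.index)
            if not overlap.any() and len(evidence):
                logger.warning("DEG list %r shares no gene IDs with the QTL gene set (namespace mismatch?)", name)
            col = evidence["gene_id"].map(mapping).fillna("absent")
        else:
            overlap = pd.Series(False, index=evidence.index)
            col = pd.Series("absent", index=evidence.index)
        evidence[f"deg_{name}"] = col
        per_list_sets.append(set(evidence.loc[overlap, "gene_id"]))
        count_rows.append(
            {
                "list": name,
                "overlap": int(overlap.sum()),
                "up": int((col == "up").sum()),
                "down": int((col == "down").sum()),
            }
        )
    common = set.intersection(*per_list_sets) if per_list_sets else set()
    count_rows.append({"list": "common", "overlap": len(common), "up": None, "down": None})
    return evidence, pd.DataFrame(count_rows)


def _keyword_pattern(keywords) -> re.Pattern | None:
    if not keywords:
        return None
    parts = [r"\b" + re.escape(k) + r"\b" for k in keywords]
    return re.compile("|".join(parts), flags=re.IGNORECASE)


def annotate_candidates(
    evidence: pd.DataFrame,
    annotation_map: pd.DataFrame | None = None,
    keywords=DEFAULT_KEYWORDS,
) -> pd.DataFrame:
    """Final candidate flags from DEG evidence plus annotation keywords.

    ``annotation_map`` is (gene_id, homolog_id, function); a gene gains
    annotation evidence when its function text contains any keyword
    (case-insensitive, whole-word). candidate = any DEG evidence or
    annotation evidence. Genes absent from the map simply lack annotation
    evidence.
    """
    out = evidence.copy()
    pattern = _keyword_pattern(keywords)
    if annotation_map is not None and pattern is not None:
        amap = annotation_map.set_index("gene_id")
        out["homolog_id"] = out["gene_id"].map(amap["homolog_id"])
        funcs = out["gene_id"].map(amap["function"]).fillna("")
        out["annotation_function"] = funcs
        out["annotation_keyword"] = funcs.map(lambda s: (m.group(0) if (m := pattern.search(s)) else ""))
        out["annotation_evidence"] = out["annotation_keyword"] != ""
    else:
        out["homolog_id"] = pd.NA
        out["annotation_function"] = ""
        out["annotation_keyword"] = ""
        out["annotation_evidence"] = False
    deg_cols = [c for c in out.columns if c.startswith("deg_")]
    deg_any = (out[deg_cols] != "absent").any(axis=1) if deg_cols else pd.Series(False, index=out.index)
    out["deg_evidence"] = deg_any
    out["candidate"] = deg_any | out["annotation_evidence"]
    return out
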