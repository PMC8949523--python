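"""QTL integration from significant association hits.

Each significant SNP defines a closed 1-based window of +/- ``half_width``
(default 54 kb, the distance at which panel LD decays to r^2 ~ 0.1);
overlapping windows on a chromosome are merged transitively (touching
endpoints count as overlap); merged intervals are retained as QTLs only
when they contain two or more distinct SNP positions whose detections span
at least two environments or two traits. Each retained QTL is named
"q" + trait family + chromosome number + "." + order number, the family
taken from its lead (most significant) SNP and the order number from the
start-position rank among same-family QTLs on the chromosome.
"""

from __future__ import annotations

import dataclasses
import re
import warnings

import numpy as np
import pandas as pd

DEFAULT_HALF_WIDTH = 54_000

_TRAIT_RE = re.compile(r"^([A-Za-z]+)[-_]?(\d+|AVG)?$")


def trait_family(trait: str) -> str:
    """Strip the environment suffix: RGR2 -> RGR, RSL-AVG -> RSL."""
    m = _TRAIT_RE.match(str(trait))
    return m.group(1) if m else str(trait)


def trait_env(trait: str) -> str | None:
    """Environment label from a trait name: RGR2 -> E2; None for averages."""
    m = _TRAIT_RE.match(str(trait))
    if m and m.group(2) and m.group(2) != "AVG":
        return f"E{m.group(2)}"
    return None


@dataclasses.dataclass
class QTLRecord:
    name: str | None
    chrom: str
    start: int
    end: int
    members: pd.DataFrame  # columns: pos, trait, env, model, neg_log10_p, r2_pve
    lead_snp: int | None = None
    lead_trait: str | None = None
    lead_neg_log10_p: float | None = None
    lead_r2_pve: float | None = None

    @property
    def supporting_traits(self) -> set[str]:
        return set(self.members["trait"])

    @property
    def supporting_envs(self) -> set[str]:
        return {e for e in self.members["env"] if e is not None}

    def detected_all_envs(self, all_envs: set[str] | None = None) -> bool:
        envs = all_envs or {"E1", "E2", "E3"}
        return envs <= self.supporting_envs


def make_windows(hits: pd.DataFrame, half_width: int = DEFAULT_HALF_WIDTH) -> pd.DataFrame:
    """Closed window [max(1, pos-half_width), pos+half_width] per hit."""
    out = hits.copy()
    out["start"] = np.maximum(1, out["pos"] - half_width)
    out["end"] = out["pos"] + half_width
    if "env" not in out.columns:
        out["env"] = out["trait"].map(trait_env)
    return out.sort_values(["chrom", "start", "pos"]).reset_index(drop=True)


def merge_windows(windows: pd.DataFrame) -> list[QTLRecord]:
    """Transitive closure of same-chromosome interval overlap.

    Closed intervals; touching endpoints (next.start <= current.end) merge.
    The merged span is [min starts, max ends] and member hits concatenate.
    """
    records: list[QTLRecord] = []
    member_cols = [c for c in ["pos", "trait", "env", "model", "neg_log10_p", "r2_pve"] if c in windows.columns]
    for chrom, grp in windows.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        cur_start = cur_end = None
        cur_members: list[pd.DataFrame] = []
        for _, row in grp.iterrows():
            if cur_start is None:
                cur_start, cur_end = int(row["start"]), int(row["end"])
                cur_members = [row[member_cols].to_frame().T]
            elif int(row["start"]) <= cur_end:
                cur_end = max(cur_end, int(row["end"]))
                cur_members.append(row[member_cols].to_frame().T)
            else:
                records.append(QTLRecord(None, chrom, cur_start, cur_end, _member_frame(cur_members)))
                cur_start, cur_end = int(row["start"]), int(row["end"])
                cur_members = [row[member_cols].to_frame().T]
        if cur_start is not None:
            records.append(QTLRecord(None, chrom, cur_start, cur_end, _member_frame(cur_members)))
    return records


def _member_frame(parts: list[pd.DataFrame]) -> pd.DataFrame:
    df = pd.concat(parts, ignore_index=True)
    df["pos"] = df["pos"].astype(int)
    if "neg_log10_p" in df.columns:
        df["neg_log10_p"] = df["neg_log10_p"].astype(float)
    return df


def retain_qtls(
    merged: list[QTLRecord],
    require_multi_context: bool = True,
    distinct_positions: bool = False,
) -> list[QTLRecord]:
    """Keep intervals supported by two or more detections spanning at least
    two environments or two traits.

    A detection is a (position, trait, environment) hit record, so a single
    position repeatedly detected across environments qualifies — the pattern
    single-point QTLs show when a lead SNP is not linked to other assayed
    sites. With ``distinct_positions=True`` the two supporting detections
    must additionally come from two distinct SNP positions (a stricter
    reading under which repeat detections of one SNP never suffice). With
    ``require_multi_context=False`` only the detection-count clause applies.
    """
    kept = []
    for rec in merged:
        n_det = len(rec.members.drop_duplicates(subset=[c for c in ("pos", "trait", "env") if c in rec.members.columns]))
        n_pos = rec.members["pos"].nunique()
        if n_det < 2 or (distinct_positions and n_pos < 2):
            continue
        if require_multi_context:
            n_envs = rec.members["env"].dropna().nunique()
            n_traits = rec.members["trait"].nunique()
            if n_envs < 2 and n_traits < 2:
                continue
        kept.append(rec)
    return kept


def select_lead_and_name(records: list[QTLRecord]) -> list[QTLRecord]:
    """Choose each QTL's lead SNP and assign Table-style names.

    Lead = member with maximum -log10(p); ties break to the smaller
    position. Name = "q" + lead trait family + chromosome number + "." +
    order number, order being the start-position rank among QTLs of the
    same family on the same chromosome (1-based).
    """
    for rec in records:
        m = rec.members.sort_values(["neg_log10_p", "pos"], ascending=[False, True], kind="mergesort")
        # ties on score: the first row after a stable sort has the smaller pos
        top_score = m["neg_log10_p"].iloc[0]
        tied = m[m["neg_log10_p"] == top_score].sort_values("pos")
        lead = tied.iloc[0]
        rec.lead_snp = int(lead["pos"])
        rec.lead_trait = str(lead["trait"])
        rec.lead_neg_log10_p = float(lead["neg_log10_p"])
        rec.lead_r2_pve = float(lead["r2_pve"]) if "r2_pve" in m.columns and pd.notna(lead.get("r2_pve")) else None

    counters: dict[tuple[str, str], list[QTLRecord]] = {}
    for rec in records:
        fam = trait_family(rec.lead_trait)
        counters.setdefault((fam, rec.chrom), []).append(rec)
    for (fam, chrom), group in counters.items():
        chrom_num = re.sub(r"^\D*", "", chrom) or chrom
        for order, rec in enumerate(sorted(group, key=lambda r: r.start), start=1):
            rec.name = f"q{fam}{chrom_num}.{order}"
    return records


def overlap_with_external(records: list[QTLRecord], external: pd.DataFrame) -> pd.DataFrame:
    """Pairs of (QTL, external interval) sharing >=1 bp.

    ``external`` needs columns chrom/start/end and optionally name.
    Chromosome names absent from the QTL set trigger a warning only.
    """
    qtl_chroms = {r.chrom for r in records}
    missing = set(external["chrom"]) - qtl_chroms
    if missing:
        warnings.warn(f"external chromosomes not present in QTL set: {sorted(missing)}", stacklevel=2)
    rows = []
    for rec in records:
        ext = external[external["chrom"] == rec.chrom]
        for _, e in ext.iterrows():
            if int(e["start"]) <= rec.end and int(e["end"]) >= rec.start:
                rows.append(
                    {
                        "qtl": rec.name,
                        "qtl_start": rec.start,
                        "qtl_end": rec.end,
                        "external": e.get("name", f"{e['chrom']}:{e['start']}-{e['end']}"),
                        "ext_start": int(e["start"]),
                        "ext_end": int(e["end"]),
                        "chrom": rec.chrom,
                    }
                )
    return pd.DataFrame(rows, columns=["qtl", "qtl_start", "qtl_end", "external", "ext_start", "ext_end", "chrom"])


def qtl_table(records: list[QTLRecord], all_envs: set[str] | None = None) -> pd.DataFrame:
    """Flat QTL report: name, chrom, span, lead SNP and score, supporting
    traits/environments/models, all-environments flag."""
    rows = []
    for rec in records:
        rows.append(
            {
                "name": rec.name,
                "chrom": rec.chrom,
                "start": rec.start,
                "end": rec.end,
                "n_snps": rec.members["pos"].nunique(),
                "lead_snp": rec.lead_snp,
                "lead_trait": rec.lead_trait,
                "lead_neg_log10_p": rec.lead_neg_log10_p,
                "lead_r2_pve": rec.lead_r2_pve,
                "traits": ",".join(sorted(rec.supporting_traits)),
                "envs": ",".join(sorted(rec.supporting_envs)),
                "models": ",".join(sorted(set(rec.members.get("model", pd.Series(dtype=object)).dropna()))),
                "detected_all_envs": rec.detected_all_envs(all_envs),
            }
        )
    return pd.DataFrame(rows)


def write_bed(records: list[QTLRecord], path) -> None:
    """0-based half-open BED for genome-browser use (converted on write)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.chrom}\t{rec.start - 1}\t{rec.end}\t{rec.name}\n")
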