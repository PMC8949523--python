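"""Window construction, interval merging, retention, lead selection and
naming, including brute-force oracle equivalence for the merging step."""

import numpy as np
import pandas as pd
import pytest

from saltgrain import qtl


def _hit(chrom, pos, trait="RGR1", model="GLM", score=8.0, r2=12.0):
    return {"chrom": chrom, "pos": pos, "snp_id": f"{chrom}_{pos}", "trait": trait,
            "model": model, "neg_log10_p": score, "r2_pve": r2}


def _windows(hits, half_width=54_000):
    return qtl.make_windows(pd.DataFrame(hits), half_width=half_width)


def test_make_windows_arithmetic():
    w = _windows([_hit("Chr1", 100_000), _hit("Chr1", 10_000), _hit("Chr2", 17_310_510)])
    w = w.set_index("pos")
    assert (w.loc[100_000, "start"], w.loc[100_000, "end"]) == (46_000, 154_000)
    assert (w.loc[10_000, "start"], w.loc[10_000, "end"]) == (1, 64_000)  # left-clipped
    assert (w.loc[17_310_510, "start"], w.loc[17_310_510, "end"]) == (17_256_510, 17_364_510)


def test_merge_disjoint_unchanged():
    recs = qtl.merge_windows(_windows([_hit("Chr1", 100_000), _hit("Chr1", 400_000), _hit("Chr2", 100_000)]))
    assert len(recs) == 3


def test_merge_transitive_chain():
    # A overlaps B, B overlaps C, A does not overlap C -> one interval
    recs = qtl.merge_windows(_windows([_hit("Chr1", 100_000), _hit("Chr1", 190_000), _hit("Chr1", 280_000)]))
    assert len(recs) == 1
    assert (recs[0].start, recs[0].end) == (46_000, 334_000)
    assert len(recs[0].members) == 3


def test_merge_touching_endpoints():
    # windows [46000,154000] and [154000,262000] share one bp -> merge
    recs = qtl.merge_windows(_windows([_hit("Chr1", 100_000), _hit("Chr1", 208_000)]))
    assert len(recs) == 1
    # one bp further apart -> closed intervals disjoint -> no merge
    recs = qtl.merge_windows(_windows([_hit("Chr1", 100_000), _hit("Chr1", 208_001)]))
    assert len(recs) == 2


def _bruteforce_merge(intervals):
    """O(n^2) union-find closure over pairwise-overlapping closed intervals."""
    parent = list(range(len(intervals)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, (ci, si, ei) in enumerate(intervals):
        for j, (cj, sj, ej) in enumerate(intervals):
            if ci == cj and si <= ej and sj <= ei:
                parent[find(i)] = find(j)
    groups = {}
    for i, (c, s, e) in enumerate(intervals):
        groups.setdefault(find(i), []).append((c, s, e))
    return sorted(
        (g[0][0], min(s for _, s, _ in g), max(e for _, _, e in g), len(g)) for g in groups.values()
    )


def test_merge_matches_bruteforce_oracle(rng):
    hits = [_hit(f"Chr{rng.integers(1, 4)}", int(rng.integers(1, 2_000_000))) for _ in range(50)]
    windows = _windows(hits, half_width=30_000)
    recs = qtl.merge_windows(windows)
    got = sorted((r.chrom, r.start, r.end, len(r.members)) for r in recs)
    expected = _bruteforce_merge(list(windows[["chrom", "start", "end"]].itertuples(index=False, name=None)))
    assert got == expected


def test_merge_idempotent_and_order_invariant(rng):
    hits = [_hit("Chr1", int(rng.integers(1, 1_000_000))) for _ in range(30)]
    windows = _windows(hits)
    recs = qtl.merge_windows(windows)
    spans = sorted((r.chrom, r.start, r.end) for r in recs)
    # merging the merged spans changes nothing
    again = qtl.merge_windows(pd.DataFrame(
        [{"chrom": r.chrom, "start": r.start, "end": r.end, "pos": r.members["pos"].iloc[0], "trait": "RGR1"} for r in recs]
    ))
    assert sorted((r.chrom, r.start, r.end) for r in again) == spans
    shuffled = windows.sample(frac=1, random_state=1)
    assert sorted((r.chrom, r.start, r.end) for r in qtl.merge_windows(shuffled)) == spans


def test_retention_rules():
    single = qtl.merge_windows(_windows([_hit("Chr1", 100_000)]))
    assert qtl.retain_qtls(single) == []  # one detection -> dropped

    same_context = qtl.merge_windows(_windows([_hit("Chr1", 100_000, "RGR1"), _hit("Chr1", 120_000, "RGR1")]))
    assert qtl.retain_qtls(same_context) == []  # 2 SNPs, same trait+env -> dropped

    two_envs = qtl.merge_windows(_windows([_hit("Chr1", 100_000, "RGR1"), _hit("Chr1", 120_000, "RGR2")]))
    kept = qtl.retain_qtls(two_envs)
    assert len(kept) == 1
    assert not kept[0].detected_all_envs()

    # a single position repeatedly detected in all three environments is a
    # valid (single-point) QTL
    repeat = qtl.merge_windows(_windows([_hit("Chr2", 17_310_510, f"RGR{e}") for e in (1, 2, 3)]))
    kept = qtl.retain_qtls(repeat)
    assert len(kept) == 1 and kept[0].detected_all_envs()
    # ... unless the stricter distinct-positions reading is requested
    assert qtl.retain_qtls(repeat, distinct_positions=True) == []


def test_retention_never_adds_members(rng):
    hits = [_hit("Chr1", int(rng.integers(1, 500_000)), f"RGR{rng.integers(1, 4)}") for _ in range(20)]
    merged = qtl.merge_windows(_windows(hits))
    sizes = {(r.chrom, r.start, r.end): len(r.members) for r in merged}
    for r in qtl.retain_qtls(merged):
        assert len(r.members) == sizes[(r.chrom, r.start, r.end)]


def test_lead_selection_and_naming():
    recs = qtl.merge_windows(_windows([
        _hit("Chr2", 17_310_510, "RGR1", score=9.5, r2=20.0),
        _hit("Chr2", 17_320_000, "RSL2", score=7.0, r2=11.0),
    ]))
    named = qtl.select_lead_and_name(qtl.retain_qtls(recs))
    assert named[0].name == "qRGR2.1"  # lead is the RGR hit
    assert named[0].lead_snp == 17_310_510
    assert named[0].lead_r2_pve == 20.0
    assert named[0].lead_snp in set(named[0].members["pos"])


def test_naming_order_follows_position():
    recs = qtl.merge_windows(_windows([
        _hit("Chr14", 7_956_601, "RSL1", score=6.0),
        _hit("Chr14", 7_956_700, "RSL2", score=6.5),
        _hit("Chr14", 7_354_242, "RSL1", score=8.0),
        _hit("Chr14", 7_354_300, "RSL3", score=7.0),
    ]))
    named = qtl.select_lead_and_name(qtl.retain_qtls(recs))
    by_name = {r.name: r for r in named}
    assert set(by_name) == {"qRSL14.1", "qRSL14.2"}
    assert by_name["qRSL14.1"].start < by_name["qRSL14.2"].start


def test_lead_tie_breaks_to_smaller_position():
    recs = qtl.merge_windows(_windows([
        _hit("Chr3", 200_000, "RGR1", score=7.0),
        _hit("Chr3", 150_000, "RGR2", score=7.0),
    ]))
    named = qtl.select_lead_and_name(qtl.retain_qtls(recs))
    assert named[0].lead_snp == 150_000


def test_overlap_with_external(rng):
    recs = qtl.select_lead_and_name(qtl.retain_qtls(qtl.merge_windows(_windows([
        _hit("Chr1", 100_000, "RGR1"), _hit("Chr1", 120_000, "RGR2"),
        _hit("Chr2", 500_000, "RSL1"), _hit("Chr2", 520_000, "RSL2"),
    ]))))
    own = pd.DataFrame([{"chrom": r.chrom, "start": r.start, "end": r.end, "name": r.name} for r in recs])
    assert len(qtl.overlap_with_external(recs, own)) == len(recs)  # self-overlap
    shifted = own.assign(start=own["end"] + 1, end=own["end"] + (own["end"] - own["start"]) + 1)
    assert len(qtl.overlap_with_external(recs, shifted)) == 0

    external = pd.DataFrame({
        "chrom": [f"Chr{rng.integers(1, 4)}" for _ in range(30)],
        "start": rng.integers(1, 1_000_000, 30),
    })
    external["end"] = external["start"] + rng.integers(1, 200_000, 30)
    with pytest.warns(UserWarning):
        got = qtl.overlap_with_external(recs, external)
    brute = sum(
        1
        for r in recs
        for _, e in external.iterrows()
        if e["chrom"] == r.chrom and e["start"] <= r.end and e["end"] >= r.start
    )
    assert len(got) == brute


def test_qtl_table_and_bed(tmp_path):
    recs = qtl.select_lead_and_name(qtl.retain_qtls(qtl.merge_windows(_windows(
        [_hit("Chr1", 100_000, "RGR1"), _hit("Chr1", 120_000, "RGR2")]
    ))))
    table = qtl.qtl_table(recs)
    assert table.loc[0, "name"] == "qRGR1.1"
    assert table.loc[0, "n_snps"] == 2
    bed = tmp_path / "q.bed"
    qtl.write_bed(recs, bed)
    chrom, start, end, name = bed.read_text().split()
    assert int(start) == recs[0].start - 1 and int(end) == recs[0].end  # 0-based half-open
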