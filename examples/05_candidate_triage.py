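"""Screen candidate genes inside QTLs with DEG and annotation evidence.

Places gene models on the panel genome, intersects the retained QTLs with
them, and flags candidates supported by differential-expression lists or
salt-stress annotation keywords.
"""

import saltgrain as sg
from saltgrain import assoc, qtl, triage

cfg = sg.SimConfig(seed=1, planted_qtls=sg.demo_planted_qtls())
panel = sg.syndata.simulate_genotypes(cfg)
raw = sg.syndata.simulate_phenotypes(panel, cfg)
traits = sg.phenotyping.relative_traits(raw)
fpanel, _ = assoc.filter_snps(panel)
results = assoc.scan_traits(fpanel, traits)
hits = assoc.significant_hits(results, assoc.bonferroni_threshold(fpanel.n_snps), 5.0)
named = qtl.select_lead_and_name(qtl.retain_qtls(qtl.merge_windows(qtl.make_windows(hits))))

genes = sg.syndata.simulate_gene_models(cfg, genes_per_chrom=200)
deg_a, deg_b = sg.syndata.simulate_deg_lists(genes, fraction_up=0.05, fraction_down=0.05, seed=2)
annot = sg.syndata.simulate_annotations(genes, salt_fraction=0.2, seed=3)

in_qtls = triage.genes_in_qtls(named, genes)
evidence, counts = triage.intersect_deg(in_qtls, {"listA": deg_a, "listB": deg_b})
cand = triage.annotate_candidates(evidence, annot)

print(f"{len(genes)} genes genome-wide, {len(in_qtls)} inside the {len(named)} QTLs")
print(counts.to_string(index=False))
flagged = cand[cand["candidate"]]
print(f"{len(flagged)} candidates:")
for _, g in flagged.iterrows():
    why = []
    if g["deg_evidence"]:
        why.append("DEG")
    if g["annotation_evidence"]:
        why.append(f"annotation '{g['annotation_keyword']}'")
    print(f"  {g['gene_id']} in {g['qtl_names']} [{' + '.join(why)}] {g['annotation_function']}")
# Every candidate traces to explicit evidence; adding a DEG list or a
# keyword can only grow this set, never shrink it.
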