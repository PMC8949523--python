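"""Compare tolerance between lead-SNP haplotype groups and report
subpopulation allele frequencies at the planted chromosome-2 locus.
"""

import saltgrain as sg
from saltgrain import haplo

cfg = sg.SimConfig(seed=1, planted_qtls=sg.demo_planted_qtls())
panel = sg.syndata.simulate_genotypes(cfg)
raw = sg.syndata.simulate_phenotypes(panel, cfg)
traits = sg.phenotyping.relative_traits(raw)

chrom, pos = "Chr2", 17_310_510
comp = haplo.compare_haplotypes(panel, chrom, pos, traits["RGR-AVG"])
print(f"lead SNP {chrom}:{pos}, trait RGR-AVG")
print(comp.group_stats.round(3).to_string())
print(f"Welch t = {comp.t_statistic:.2f}, df = {comp.df:.1f}, p = {comp.p_value:.2e} ({comp.note})")

freqs = haplo.allele_freq_by_subpop(panel, chrom, pos)
print(freqs.round(3).to_string(index=False))
# The GG group (favorable allele homozygotes) should show the higher mean
# relative germination, and the favorable G allele should be more frequent
# in the Oil subpopulation than in OF or Fiber.
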