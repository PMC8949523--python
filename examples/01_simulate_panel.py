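"""Simulate a structured flax-like diversity panel with planted tolerance loci.

Builds the default 200-accession, 15-chromosome panel with three
subpopulations (Oil/OF/Fiber) and three planted salt-tolerance QTLs, then
prints its shape and marker summaries.
"""

import saltgrain as sg

cfg = sg.SimConfig(seed=1, planted_qtls=sg.demo_planted_qtls())
panel = sg.syndata.simulate_genotypes(cfg)

print(f"panel: {panel.n_accessions} accessions x {panel.n_snps} SNPs "
      f"on {len(panel.chromosomes)} chromosomes")
import numpy as np

labels, sizes = np.unique(panel.subpop, return_counts=True)
print("subpopulation sizes:", {str(s): int(n) for s, n in zip(labels, sizes)})
print(f"MAF range: {panel.maf().min():.3f} - {panel.maf().max():.3f} (floor {cfg.maf_min})")
print(f"mean missingness: {panel.missing_fraction().mean():.3f} (target {cfg.missing_rate})")
for q in cfg.planted_qtls:
    j = panel.locate(q.chrom, q.pos)
    print(f"planted QTL at {q.chrom}:{q.pos} assayed (MAF {panel.maf()[j]:.2f}, "
          f"favored subpop {q.favored_subpop})")
# Every downstream stage consumes this panel; MAF/missingness honor the
# same filters a real variant-calling pipeline would apply.
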