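"""Score germination-stage salt tolerance with the weighted membership function.

Generates raw control/salt measurements over three environments, derives the
relative traits (RGR/RSL/RRL), computes the CV-weighted membership score D,
and assigns the five tolerance grades.
"""

import saltgrain as sg

cfg = sg.SimConfig(seed=1, planted_qtls=sg.demo_planted_qtls())
panel = sg.syndata.simulate_genotypes(cfg)
raw = sg.syndata.simulate_phenotypes(panel, cfg)

traits = sg.phenotyping.relative_traits(raw)
scores = sg.phenotyping.d_scores(traits)
grades = sg.phenotyping.assign_grades(scores["D"])

print("index weights (CV-proportional):",
      {k: round(float(v), 3) for k, v in scores.attrs["weights"].items()})
print(f"D range: {scores['D'].min():.2f} (most sensitive) - {scores['D'].max():.2f} (most tolerant)")
counts = grades.value_counts().sort_index()
names = grades.attrs["grade_names"]
for g, n in counts.items():
    print(f"  grade {g} ({names[g]}): {n} accessions "
          f"({sg.phenotyping.grade_percentages(counts.to_numpy())[g-1]:.2f}%)")
corr = sg.phenotyping.trait_correlations(traits)
print(f"cross-environment RGR correlation (E1,E2): {corr.loc['RGR1','RGR2']:.2f}")
print(f"within-environment RSL-RRL correlation (E1): {corr.loc['RSL1','RRL1']:.2f}")
# A higher D means stronger composite salt tolerance; weights favor the
# index that discriminates accessions most (largest CV of its membership).
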