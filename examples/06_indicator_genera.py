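"""Indicator-genus analysis with permutation FDR.

Generates habitats containing genera constructed to be exclusive to one
habitat, runs the Dufrene-Legendre IndVal statistic with a permutation
null and BH FDR control, and reports the fraction of genera per kingdom
significantly associated with a habitat at FDR < 0.3 (only genera with
more than 10 reads in total are tested).
"""
from habprof import (
    SynthConfig,
    gen_abundance_matrix,
    indicator_analysis,
    indicator_fractions,
)

cfg = SynthConfig(
    n_habitats=3, samples_per_habitat=10, n_exclusive_per_habitat=5,
    bf_ratio_per_habitat=20.0, depth_range=(5_000, 5_000),
    habitat_effect=1.0, seed=55,
)
cm, truth = gen_abundance_matrix(cfg)
table = indicator_analysis(cm, n_perm=999, seed=56, min_reads=10)

exclusive = [g for gs in truth.exclusive_genera.values() for g in gs]
print("constructed habitat-exclusive genera and their results:")
print(table.loc[exclusive].round(4).to_string())

totals = cm.feature_meta["kingdom"].value_counts().to_dict()
per_habitat, overall = indicator_fractions(table, totals, fdr_threshold=0.3)
print("\noverall % of genera significantly habitat-associated (FDR < 0.3):")
print(overall.round(1).to_string())
print("\nper habitat:")
print(per_habitat.to_string(index=False))
print(
    "\n-> every constructed exclusive genus reaches IndVal ~= 1 with "
    "q < 0.3; many background genera are also significant because the "
    "non-zero habitat effect gives them genuine habitat structure "
    "(set habitat_effect=0 for a null run)."
)
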