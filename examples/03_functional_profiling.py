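"""Functional and CAZyme profiling from protein-level hits.

Shows the pair-hit combination rule (lower e-value, summed bit scores),
deterministic best-hit selection, the identity/e-value exclusion filter,
the prokaryote/eukaryote domain split, and the seed-quality mapping of
orthologous groups (OGs) to CAZy families.
"""
from habprof import (
    AlignmentHit,
    FunctionalTarget,
    build_og_matrix,
    cazyme_profile,
    combine_pair_hits,
    filter_hits,
    map_og_to_cazy,
    select_best_hit,
)

h1 = AlignmentHit("r1/1", "tA", 80.0, 100, 1e-10, 50.0)
h2 = AlignmentHit("r1/2", "tA", 90.0, 110, 1e-12, 40.0)
pair = combine_pair_hits(h1, h2)
print(f"combined mate hits: e-value {pair.evalue:g}, bitscore {pair.bitscore}")

hits = [
    pair,
    AlignmentHit("r1", "tB", 95.0, 120, 1e-15, 85.0),
    AlignmentHit("r1", "tC", 45.0, 200, 1e-30, 300.0),  # identity < 50: excluded
]
best = select_best_hit(filter_hits(hits))
print(f"best surviving hit: {best.target} (bitscore {best.bitscore})")

targets = {
    "tA": FunctionalTarget("tA", "OG_prok_1", "prokaryote"),
    "tB": FunctionalTarget("tB", "OG_euk_1", "eukaryote"),
}
mats = build_og_matrix(
    {"sample1": [best]}, targets, total_reads={"sample1": 500}
)
print("eukaryote OG counts:", mats["eukaryote"].counts.loc["sample1"].to_dict())

seed_hits = [
    AlignmentHit("OG_prok_1", "cz1", 95.0, 200, 1e-30, 400.0, subject_coverage=88.0),
    AlignmentHit("OG_euk_1", "cz2", 90.0, 200, 1e-30, 400.0, subject_coverage=88.0),
]
og2cazy = map_og_to_cazy(seed_hits, {"cz1": "GH5", "cz2": "AA9"})
print("OG -> CAZy map (identity 90 fails the strict > 90 rule):", og2cazy)
profiles, ratio = cazyme_profile(mats, og2cazy)
print("per-sample prokaryote:eukaryote CAZyme ratio:", ratio.to_dict())
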