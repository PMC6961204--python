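#!/usr/bin/env python
"""Neutral-control selection for X-linked missense variants.

Builds a synthetic 22-record table emulating population-database
missense variants of an X-chromosomal repeat protein (the real database
records are not redistributed here), applies the male-observed filter —
a healthy hemizygous male carrier argues against pathogenicity — scores
substitution conservativeness on the shipped 10-property physicochemical
table, and ranks candidates by co-location with the known pathogenic
repeat units.

Writes results/variant_controls.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import tprspring as tp
from tprspring.io import default_annotation_path
from tprspring.variants import VariantRecord

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

PATHOGENIC_SITES = [254, 284, 319]  # L254F, R284P, A319T

# synthetic stand-in for the 22-variant missense table (9 male-observed)
CANDIDATES = [
    # pos   wt  alt  ac_total  ac_male
    (279, "I", "V", 40, 12),
    (310, "A", "T", 11, 3),
    (100, "L", "I", 9, 2),
    (130, "S", "T", 7, 1),
    (167, "V", "I", 6, 1),
    (200, "T", "S", 5, 1),
    (371, "N", "S", 4, 1),
    (345, "D", "E", 3, 1),
    (109, "K", "R", 2, 1),
    (61, "Q", "H", 3, 0), (75, "E", "K", 2, 0), (90, "G", "S", 2, 0),
    (121, "R", "W", 1, 0), (140, "P", "L", 1, 0), (155, "Y", "C", 2, 0),
    (181, "M", "V", 1, 0), (222, "F", "L", 1, 0), (240, "H", "Y", 1, 0),
    (260, "C", "R", 1, 0), (300, "W", "R", 1, 0), (390, "A", "V", 2, 0),
    (401, "T", "M", 1, 0),
]

ann = tp.load_annotation(default_annotation_path())
records = tp.annotate_variants(
    [VariantRecord(position=p, wt=w, alt=a, ac_total=t, ac_male=m)
     for p, w, a, t, m in CANDIDATES], ann)

male = tp.filter_male_observed(records)
print(f"{len(male)} of {len(records)} candidate variants are observed in "
      "at least one male and qualify as control candidates")

ranked = tp.rank_controls(male, ann, PATHOGENIC_SITES)
ranked.to_csv(OUT / "variant_controls.tsv", sep="\t")

co = ranked[ranked["co_located"]]
print(f"{len(co)} candidates co-locate with pathogenic repeats:")
for _, r in co.iterrows():
    print(f"  {r['variant']:7s} in {r['unit']} ({r['consensus']}), "
          f"conservation {r['conservation']:.1f}, "
          f"allele count {r['ac_total']} ({r['ac_male']} in males)")
print(f"top-ranked control: {ranked.iloc[0]['variant']} "
      "(most common candidate overall)")
print(f"Wrote {OUT/'variant_controls.tsv'}")
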