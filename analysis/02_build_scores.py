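#!/usr/bin/env python
"""Build the three genetic scores from the simulated dataset and validate
each against its respective phenotype with simple linear regression.

The maternal and fetal scores are validated against offspring
birthweight (adjusted scale); the paternal score — built with
unadjusted fetal weights — against the father's own reported
birthweight.  Strong positive slopes confirm the scores carry signal.
"""

from pathlib import Path

import pandas as pd

from bwvar import dataio, pipeline
from bwvar.scores import read_weights, validate_score

ROOT = Path(__file__).resolve().parents[1]
DATASET = ROOT / "scratch" / "dataset"

vcf = dataio.read_vcf(DATASET / "genotypes.vcf")
weights = read_weights(DATASET / "weights.tsv")
trios = dataio.read_trios(DATASET / "trios.tsv")
pheno = dataio.read_phenotypes(DATASET / "phenotypes.tsv")

score_table, excluded = pipeline.build_scores(vcf, weights, trios)
print(f"{len(weights) - len(excluded)} of {len(weights)} SNPs retained "
      f"(MAF > {pipeline.DEFAULT_MAF_MIN}, info > {pipeline.DEFAULT_INFO_MIN})")

merged = pheno.drop(columns=["maternal_score", "fetal_score", "paternal_score"]) \
              .merge(score_table, on="trio_id")
checks = {
    "maternal_score": "birthweight_adj",
    "fetal_score": "birthweight_adj",
    "paternal_score": "paternal_own_bw",
}
rows = []
for score, outcome in checks.items():
    res = validate_score(merged[score], merged[outcome])
    rows.append({"score": score, "phenotype": outcome, **res})
validation = pd.DataFrame(rows)

score_table.to_csv(ROOT / "scratch" / "scores.tsv", sep="\t", index=False)
out = ROOT / "results" / "score_validation.tsv"
validation.to_csv(out, sep="\t", index=False)
print(validation.round(4).to_string(index=False))
print(f"\nscore validation -> {out}")
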