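#!/usr/bin/env python
"""Maturity-filter the raw specimens and build species-mean log10 traits.

Applies the 60%-of-maximum-SCL adulthood rule (sex-specific thresholds,
larger-sex rule for unsexed specimens, somatic-immaturity exclusions) to
the specimen table from step 01, logs every exclusion with its rule, then
averages retained specimens per species on the raw mm scale and log10-
transforms the means.

Writes filtered_specimens.csv, exclusions.csv and species_means.csv under
results/filtered/.
"""

import argparse
from pathlib import Path

import pandas as pd

import carapace as cp

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/dataset"))
parser.add_argument("--out", type=Path, default=Path("results/filtered"))
args = parser.parse_args()

specimens = pd.read_csv(args.data / "specimens.csv")
maxima = pd.read_csv(args.data / "species_maxima.csv")

kept, excluded = cp.apply_maturity_filter(specimens, maxima)
species_means = cp.aggregate_species(kept)

args.out.mkdir(parents=True, exist_ok=True)
kept.to_csv(args.out / "filtered_specimens.csv", index=False)
excluded.to_csv(args.out / "exclusions.csv", index=False)
species_means.to_csv(args.out / "species_means.csv", index=False)

by_rule = excluded["rule"].value_counts().to_dict()
print(
    f"kept {len(kept)}/{len(specimens)} specimens across "
    f"{species_means.shape[0]} species; exclusions by rule: {by_rule}"
)
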