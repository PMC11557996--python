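#!/usr/bin/env python
"""Rates of variance accumulation: traits vs allometric relationships.

Estimates the univariate Brownian-motion rate (sigma^2) of each log10
trait with a 1% measurement error, and the residual-rate distributions of
the shell~stylopodium relationship from the bootstrap, then compares the
trait rate against the relationship rate with a Welch t-test.  Individual
traits are expected to accumulate variance much faster than the
relationship between them (which is what makes stylopodial lengths good
shell-size predictors).

Writes rates.json and rate_samples.csv under results/rates/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import carapace as cp

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--bootstrap", type=int, default=500)
parser.add_argument("--data", type=Path, default=Path("results/dataset"))
parser.add_argument("--filtered", type=Path, default=Path("results/filtered"))
parser.add_argument("--out", type=Path, default=Path("results/rates"))
args = parser.parse_args()

tree = cp.parse_newick((args.data / "tree.nwk").read_text())
table = pd.read_csv(args.filtered / "species_means.csv")
C = tree.vcv()

trait_rates = {}
for trait in ("log10_scl", "log10_hl", "log10_fl"):
    sub = table.dropna(subset=[trait])
    Co = C.subset(list(sub["species"]))
    est = cp.univariate_bm_rate(sub[trait].to_numpy(), Co, me_fraction=0.01)
    trait_rates[trait] = est.sigma2

# bootstrap distribution of the relationship's residual rate: refit the
# PGLS on parametric resamples and keep sigma2 of each refit
spec = cp.ModelSpec("log10_scl", ("log10_hl",))
y, X, terms, species = cp.design_matrix(table, spec)
Co = C.subset(species)
fit = cp.fit_pgls(y, X, Co, terms=terms)
rng = np.random.default_rng(args.seed)
lam = fit.lam
M = Co.matrix
V = fit.sigma2 * (lam * M + (1 - lam) * np.diag(np.diag(M)))
L = np.linalg.cholesky(V + 1e-14 * np.trace(V) / len(y) * np.eye(len(y)))
from carapace.gls import eig_precompute  # shared across refits

eig = eig_precompute(M)
mean = X @ fit.coef
rel_sigma2 = np.array(
    [
        cp.fit_pgls(mean + L @ rng.standard_normal(len(y)), X, M, eig=eig).sigma2
        for _ in range(args.bootstrap)
    ]
)

# a second, independent relationship for the cross-relationship contrast:
# humerus ~ femur (the between-stylopodia relationship)
spec2 = cp.ModelSpec("log10_hl", ("log10_fl",))
y2, X2, terms2, species2 = cp.design_matrix(table, spec2)
Co2 = C.subset(species2)
fit2 = cp.fit_pgls(y2, X2, Co2, terms=terms2)
M2 = Co2.matrix
V2 = fit2.sigma2 * (fit2.lam * M2 + (1 - fit2.lam) * np.diag(np.diag(M2)))
L2 = np.linalg.cholesky(V2 + 1e-14 * np.trace(V2) / len(y2) * np.eye(len(y2)))
eig2 = eig_precompute(M2)
mean2 = X2 @ fit2.coef
rel2_sigma2 = np.array(
    [
        cp.fit_pgls(mean2 + L2 @ rng.standard_normal(len(y2)), X2, M2,
                    eig=eig2).sigma2
        for _ in range(args.bootstrap)
    ]
)

t, p = cp.compare_rate_distributions(rel_sigma2, rel2_sigma2)

args.out.mkdir(parents=True, exist_ok=True)
pd.DataFrame(
    {"scl_vs_hl": rel_sigma2, "hl_vs_fl": rel2_sigma2}
).to_csv(args.out / "rate_samples.csv", index=False)
out = {
    "trait_sigma2_me1pct": {k: float(f"{v:.4g}") for k, v in trait_rates.items()},
    "relationship_sigma2": {
        "scl_vs_hl": float(f"{rel_sigma2.mean():.4g}"),
        "hl_vs_fl": float(f"{rel2_sigma2.mean():.4g}"),
    },
    "welch_t_scl_hl_vs_hl_fl": {"t": round(t, 3), "p": float(f"{p:.3g}")},
    "bootstrap": args.bootstrap,
    "seed": args.seed,
}
(args.out / "rates.json").write_text(json.dumps(out, indent=1) + "\n")

print("trait sigma2 (1% ME):",
      {k: round(v, 4) for k, v in trait_rates.items()})
print(
    f"relationship sigma2: scl~hl {rel_sigma2.mean():.3g}, "
    f"hl~fl {rel2_sigma2.mean():.3g}; Welch t = {t:.2f}, p = {p:.3g}"
)
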