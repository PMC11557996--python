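"""End-to-end evolutionary-allometry workflow for turtle size data.

Covers the full chain from raw specimen measurements to fossil size
predictions:

1. maturity filtering of specimens (60% of species maximum SCL, with
   sex-specific thresholds and a larger-sex rule for unsexed specimens);
2. species-mean aggregation and log10 transform;
3. construction and PGLS/OLS fitting of model sets with binary covariates
   (terrestrial ecology, trionychid clade membership), AICc ranking, and
   the "lowest AICc with all coefficients significant" selection rule;
4. nonparametric bootstrap (species rows resampled with replacement,
   covariance rows duplicated accordingly) for coefficient intervals;
5. classification of allometric strength from the fitted slope;
6. back-transformed shell-length and body-mass prediction for fossils,
   with shipped published equation constants as the default.

Specimen tables are pandas DataFrames with columns ``species``,
``specimen_id``, ``scl_mm``, ``hl_mm``, ``fl_mm``, ``sex``
(female/male/unknown), ``gravid``, ``somatic_mature``, ``include_override``.
Species maxima tables have columns ``species``, ``sex``, ``max_scl_mm``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gls import (
    FitResult,
    aicc_weights,
    eig_precompute,
    fit_ols,
    fit_pgls,
    likelihood_r2,
)
from .phylo import PhyloCov

__all__ = [
    "ModelSpec",
    "PredictionResult",
    "BodyMass",
    "MATURITY_THRESHOLD",
    "TABLE_EQUATIONS",
    "BM_COEFFS",
    "apply_maturity_filter",
    "aggregate_species",
    "build_model_set",
    "design_matrix",
    "fit_model",
    "select_best_model",
    "bootstrap_cis",
    "classify_allometry",
    "predict_scl",
    "predict_bm",
    "compare_rate_distributions",
    "fits_to_table",
]

#: fraction of the species maximum SCL above which a specimen is treated
#: as adult (sexual maturity threshold)
MATURITY_THRESHOLD = 0.60

#: published global and clade-specific equations for predicting log10 SCL
#: (mm) from stylopodial length (mm): intercept, slope, covariate effects
TABLE_EQUATIONS = {
    ("Testudinata", "humerus"): {
        "intercept": 0.85, "slope": 0.89, "covariates": {"terrestrial": -0.05},
    },
    ("Testudinata-no-ecology", "humerus"): {
        "intercept": 0.84, "slope": 0.88, "covariates": {},
    },
    ("Testudinata", "femur"): {
        "intercept": 0.64, "slope": 0.96, "covariates": {},
    },
    ("Pan-Chelonioidea", "humerus"): {
        "intercept": 1.13, "slope": 0.80, "covariates": {},
    },
    ("Pan-Chelonioidea", "femur"): {
        "intercept": 1.41, "slope": 0.71, "covariates": {},
    },
    ("Pan-Trionychia", "humerus"): {
        "intercept": 0.98, "slope": 0.86, "covariates": {"trionychid": -0.14},
    },
    ("Pan-Trionychia", "femur"): {
        "intercept": 0.97, "slope": 0.89, "covariates": {"trionychid": -0.20},
    },
}

#: published body-mass regression: log10(BM g) = slope*log10(SCL mm) + intercept
BM_COEFFS = (2.73, -3.18)


@dataclass(frozen=True)
class ModelSpec:
    """A regression model: response ~ predictors, with a residual structure."""

    response: str
    predictors: tuple = ()
    correlation: str = "phylogenetic-lambda"  # or "independent" (OLS)

    @property
    def name(self) -> str:
        rhs = " + ".join(self.predictors) if self.predictors else "1"
        tag = " [OLS]" if self.correlation == "independent" else ""
        return f"{self.response} ~ {rhs}{tag}"


@dataclass(frozen=True)
class PredictionResult:
    """Back-transformed size prediction on the original (mm or g) scale."""

    point: float
    ci95: tuple | None
    basis: str
    covariates_used: dict

    def __post_init__(self):
        if self.ci95 is not None:
            lo, hi = self.ci95
            if not (lo <= self.point <= hi):
                raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class BodyMass:
    grams: float

    @property
    def kg(self) -> float:
        return self.grams / 1000.0


# -- specimen filtering ----------------------------------------------------


def _max_lookup(maxima: pd.DataFrame):
    """species -> {sex: max_scl_mm} from the reference maxima table."""
    out: dict = {}
    for _, row in maxima.iterrows():
        out.setdefault(row["species"], {})[str(row["sex"])] = float(
            row["max_scl_mm"]
        )
    return out


def apply_maturity_filter(
    specimens: pd.DataFrame, maxima: pd.DataFrame
) -> tuple:
    """Keep only (presumably) adult specimens; log every exclusion.

    Rules, applied per specimen row:

    * ``somatic_mature == False`` excludes regardless (ontogenetic
      allometry is exactly what the filter removes);
    * ``include_override == True`` retains a somatically mature specimen
      even below the size threshold (used for rare large species kept
      2%-5% below it);
    * sexed specimens: keep iff SCL >= 0.60 x maximum SCL of that sex;
    * unsexed specimens: keep iff SCL >= 0.60 x maximum SCL of the
      *larger* sex (conservative, since the specimen might belong to it);
    * specimens without an SCL measurement cannot be assessed and are
      excluded unless overridden.

    Returns ``(filtered, exclusions)``; ``exclusions`` has columns
    ``species``, ``specimen_id``, ``rule``.
    """
    lookup = _max_lookup(maxima)
    keep_idx = []
    log_rows = []

    def exclude(row, rule):
        log_rows.append(
            {"species": row["species"], "specimen_id": row["specimen_id"],
             "rule": rule}
        )

    for idx, row in specimens.iterrows():
        sp = row["species"]
        if sp not in lookup:
            raise KeyError(f"no reference maximum SCL for species {sp!r}")
        by_sex = lookup[sp]
        if row.get("somatic_mature") is False or (
            isinstance(row.get("somatic_mature"), (bool, np.bool_))
            and not row.get("somatic_mature")
        ):
            exclude(row, "somatically_immature")
            continue
        if bool(row.get("include_override", False)):
            keep_idx.append(idx)
            continue
        scl = row.get("scl_mm")
        if scl is None or (isinstance(scl, float) and np.isnan(scl)):
            exclude(row, "missing_scl")
            continue
        sex = str(row.get("sex", "unknown"))
        if sex in ("female", "male"):
            if sex in by_sex:
                mx = by_sex[sex]
            elif "any" in by_sex:
                mx = by_sex["any"]
            else:
                raise KeyError(
                    f"no reference maximum SCL for {sp!r} sex {sex!r}"
                )
            if scl < MATURITY_THRESHOLD * mx:
                exclude(row, f"below_60pct_max_{sex}")
                continue
        else:
            mx = max(by_sex.values())  # larger-sex rule
            if scl < MATURITY_THRESHOLD * mx:
                exclude(row, "below_60pct_max_larger_sex_unsexed")
                continue
        keep_idx.append(idx)

    filtered = specimens.loc[keep_idx].copy()
    exclusions = pd.DataFrame(
        log_rows, columns=["species", "specimen_id", "rule"]
    )
    return filtered, exclusions


def aggregate_species(
    specimens: pd.DataFrame, geometric: bool = False
) -> pd.DataFrame:
    """Species-mean traits, log10-transformed.

    Means are arithmetic on the raw mm scale, then log10 (set
    ``geometric=True`` for geometric means, i.e., means of logs).
    Per-trait missingness propagates: a species' mean for a trait uses
    only the specimens measured for that trait.  Annotation columns
    (ecology/clade flags, group) are carried through as the first value
    per species.
    """
    if specimens.empty:
        raise ValueError("empty specimen table")
    trait_cols = [c for c in ("scl_mm", "hl_mm", "fl_mm", "bm_g")
                  if c in specimens.columns]
    rows = []
    for sp, grp in specimens.groupby("species", sort=True):
        row = {"species": sp, "n_specimens": len(grp)}
        for c in trait_cols:
            vals = grp[c].dropna()
            name = "log10_" + c.rsplit("_", 1)[0]
            if len(vals) == 0:
                row[name] = np.nan
            elif geometric:
                row[name] = float(np.mean(np.log10(vals)))
            else:
                row[name] = float(np.log10(np.mean(vals)))
        for c in specimens.columns:
            if c in ("species", "specimen_id") or c in trait_cols:
                continue
            if c in ("sex", "gravid", "somatic_mature", "include_override"):
                continue
            row[c] = grp[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


# -- model sets and selection ----------------------------------------------


def build_model_set(
    response: str,
    predictor: str,
    covariates=(),
    table: pd.DataFrame | None = None,
) -> list:
    """The candidate model set for one allometric relationship.

    {y ~ x (PGLS and OLS), y ~ x + cov for each covariate (PGLS),
    y ~ 1 (PGLS null, for likelihood R^2)}.  Covariates constant within
    ``table`` (when given) are dropped with a warning.
    """
    usable = []
    for cov in covariates:
        if table is not None and cov in table.columns:
            if table[cov].nunique(dropna=True) < 2:
                warnings.warn(
                    f"covariate {cov!r} is constant in this subset; dropped",
                    stacklevel=2,
                )
                continue
        usable.append(cov)
    models = [ModelSpec(response, (predictor,))]
    models += [ModelSpec(response, (predictor, cov)) for cov in usable]
    models.append(ModelSpec(response, (predictor,), correlation="independent"))
    models.append(ModelSpec(response, ()))  # intercept-only null
    return models


def design_matrix(table: pd.DataFrame, spec: ModelSpec):
    """(y, X, terms, species) for a model over a species trait table."""
    cols = [spec.response, *spec.predictors]
    sub = table.dropna(subset=cols)
    y = sub[spec.response].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(sub))] + [sub[p].to_numpy(float) for p in spec.predictors]
    )
    terms = ["intercept", *spec.predictors]
    return y, X, terms, list(sub["species"])


def fit_model(
    table: pd.DataFrame, C: PhyloCov, spec: ModelSpec
) -> FitResult:
    """Fit one ModelSpec over a species trait table aligned to C."""
    y, X, terms, species = design_matrix(table, spec)
    if spec.correlation == "independent":
        return fit_ols(y, X, terms=terms, model=spec.name)
    Csub = C.subset(species)
    return fit_pgls(y, X, Csub, terms=terms, model=spec.name)


def select_best_model(fits) -> tuple:
    """The paper-style selection rule over a fitted model set.

    Rank by AICc; choose the lowest-AICc model whose every non-intercept
    coefficient is significant at p < 0.05.  Intercept-only and OLS fits
    participate in the ranking/weights but not in selection (the null
    exists for R^2; the OLS twin exists for the slope comparison).  If no
    candidate qualifies, the purely allometric PGLS model is returned
    flagged ``fallback=True``.

    Returns ``(best_fit, ranked: DataFrame, fallback: bool)``.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fitted models")
    finite = [f for f in fits if np.isfinite(f.aicc)]
    ws = {}
    if len(finite) >= 2:
        w = aicc_weights([f.aicc for f in finite])
        ws = {id(f): wi for f, wi in zip(finite, w)}
    order = sorted(fits, key=lambda f: f.aicc)
    ranked = pd.DataFrame(
        {
            "model": [f.model for f in order],
            "aicc": [f.aicc for f in order],
            "aicc_w": [ws.get(id(f), np.nan) for f in order],
            "lambda": [f.lam for f in order],
            "n": [f.n for f in order],
        }
    )
    candidates = [
        f
        for f in order
        if f.noninterc_terms and f.method in ("PGLS", "GLS-fixed")
    ]
    for f in candidates:
        pv = [f.p_of(t) for t in f.noninterc_terms]
        if all(p < 0.05 for p in pv):
            return f, ranked, False
    # fallback: purely allometric PGLS model (fewest predictors)
    if not candidates:
        raise ValueError("model set contains no candidate with predictors")
    fallback = min(candidates, key=lambda f: len(f.terms))
    return fallback, ranked, True


# -- bootstrap -------------------------------------------------------------


def bootstrap_cis(
    table: pd.DataFrame,
    C: PhyloCov,
    spec: ModelSpec,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    method: str = "parametric",
    return_samples: bool = False,
):
    """Percentile bootstrap 95% CIs for the coefficients of one model.

    ``method="parametric"`` (default): refit the model, then repeatedly
    simulate the response from the fitted model — y* = X beta-hat + eps*,
    eps* ~ MVN(0, sigma2-hat C_lambda-hat) — and refit each simulated
    response (lambda re-estimated every time).  This mirrors how the
    model-fitting machinery the published analyses relied on bootstraps a
    phylogenetic regression, and its intervals attain near-nominal
    coverage; all refits share one covariance eigendecomposition, so
    B = 1000 costs seconds.

    ``method="rows"``: resample species rows with replacement and subset
    the phylogenetic covariance to the resampled species (duplicated rows
    contribute repeated observations with duplicated covariance rows;
    pruning the tree to the unique species and duplicating tips gives the
    identical matrix).  Resamples with fewer than 3 unique species are
    discarded and redrawn.  At lambda = 1 a resample with duplicates has
    an exactly singular covariance; the profile search treats it as
    likelihood -inf, so lambda-hat lands strictly below 1.  Row
    resampling ignores the phylogenetic dependence of the rows and its
    slope intervals are shifted relative to the point estimate; it is
    retained for comparison.

    Returns ``{term: (lo, hi)}`` (2.5/97.5 percentiles); with
    ``return_samples=True`` also the (B, k) coefficient sample matrix and
    the redraw count.
    """
    if B < 100:
        warnings.warn(
            f"B={B} is below the customary 1000 bootstrap replicates",
            stacklevel=2,
        )
    if method not in ("parametric", "rows"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    y, X, terms, species = design_matrix(table, spec)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 species for the bootstrap")
    Csub = C.subset(species)
    M = Csub.matrix
    use_ols = spec.correlation == "independent"

    samples = np.empty((B, X.shape[1]))
    redraws = 0

    if method == "parametric":
        diag = np.diag(M)
        equal_diag = np.ptp(diag) <= 1e-10 * max(float(diag.max()), 1e-300)
        eig = eig_precompute(M) if (equal_diag and not use_ols) else None
        if use_ols:
            fit = fit_ols(y, X, terms=terms)
            V = fit.sigma2 * np.eye(n)
        else:
            fit = fit_pgls(y, X, M, terms=terms, eig=eig)
            lam = fit.lam
            V = fit.sigma2 * (lam * M + (1.0 - lam) * np.diag(diag))
        if fit.degenerate:
            raise ValueError("cannot bootstrap a zero-residual (degenerate) fit")
        L = np.linalg.cholesky(V + 1e-14 * np.trace(V) / n * np.eye(n))
        mean = X @ fit.coef
        for b in range(B):
            yb = mean + L @ rng.standard_normal(n)
            if use_ols:
                fb = fit_ols(yb, X, terms=terms)
            else:
                fb = fit_pgls(yb, X, M, terms=terms, eig=eig)
            samples[b] = fb.coef
    else:
        b = 0
        while b < B:
            ix = rng.integers(0, n, size=n)
            if len(np.unique(ix)) < 3:
                redraws += 1
                continue
            yb, Xb = y[ix], X[ix]
            try:
                if use_ols:
                    fb = fit_ols(yb, Xb, terms=terms)
                else:
                    fb = fit_pgls(yb, Xb, M[np.ix_(ix, ix)], terms=terms)
            except np.linalg.LinAlgError:
                redraws += 1
                continue
            samples[b] = fb.coef
            b += 1

    lo = np.percentile(samples, 2.5, axis=0)
    hi = np.percentile(samples, 97.5, axis=0)
    cis = {t: (float(l), float(h)) for t, l, h in zip(terms, lo, hi)}
    if return_samples:
        return cis, samples, redraws
    return cis


# -- classification and prediction -----------------------------------------

_NEG_BANDS = [(0.85, "weak negative"), (0.70, "moderate negative")]
_POS_BANDS = [(1.15, "weak positive"), (1.30, "moderate positive")]


def classify_allometry(slope: float) -> str:
    """Strength label for a log-log scaling slope.

    Negative allometry: 0.99-0.85 weak, 0.84-0.7 moderate, < 0.7 strong;
    positive: 1.01-1.15 weak, 1.16-1.3 moderate, > 1.3 strong.  Slopes
    strictly between 0.99 and 1.01 are "near-isometric" (band edges are
    inclusive toward their named band).
    """
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    if 0.99 < slope < 1.01:
        return "near-isometric"
    if slope <= 0.99:
        for edge, label in _NEG_BANDS:
            if slope >= edge:
                return label
        return "strong negative"
    for edge, label in _POS_BANDS:
        if slope <= edge:
            return label
    return "strong positive"


def _resolve_equation(element: str, equation: str, covariates: dict | None):
    element = element.lower()
    if element not in ("humerus", "femur"):
        raise ValueError(f"element must be humerus or femur, got {element!r}")
    covariates = dict(covariates or {})
    key = (equation, element)
    if key not in TABLE_EQUATIONS:
        # ecology-free global variant when ecology is unknown
        if (
            equation == "Testudinata"
            and element == "humerus"
            and "terrestrial" not in covariates
        ):
            key = ("Testudinata-no-ecology", element)
        else:
            raise KeyError(f"no shipped equation for {equation!r} ({element})")
    eq = TABLE_EQUATIONS[key]
    if (
        key == ("Testudinata", "humerus")
        and "terrestrial" not in covariates
    ):
        key = ("Testudinata-no-ecology", "humerus")
        eq = TABLE_EQUATIONS[key]
    for cov in eq["covariates"]:
        if cov not in covariates:
            raise KeyError(
                f"equation {equation!r} ({element}) requires covariate "
                f"{cov!r}"
            )
    return key, eq, covariates


def predict_scl(
    length_mm: float,
    element: str,
    equation: str = "Testudinata",
    covariates: dict | None = None,
    fit: FitResult | None = None,
    boot_samples: np.ndarray | None = None,
    tip_depth: float | None = None,
    include_residual: bool = True,
    rng: np.random.Generator | None = None,
) -> PredictionResult:
    """Predict straight carapace length (mm) from a stylopodial length.

    With the default shipped equation constants the prediction is a point
    estimate only.  When a fitted model and its bootstrap coefficient
    samples are supplied, a 95% interval is formed by pushing every
    bootstrap coefficient vector through the linear predictor and (by
    default) adding a residual draw with variance sigma2_hat x tip depth,
    which widens the interval to a prediction interval for a new
    observation rather than a confidence band on the mean.
    """
    if length_mm <= 0:
        raise ValueError("length must be positive")
    lx = np.log10(length_mm)

    if fit is not None:
        covariates = dict(covariates or {})
        linpred = fit.coef_of("intercept")
        slope_term = fit.noninterc_terms[0]
        linpred += fit.coef_of(slope_term) * lx
        used = {}
        for t in fit.noninterc_terms[1:]:
            v = float(covariates.get(t, 0.0))
            linpred += fit.coef_of(t) * v
            used[t] = v
        ci = None
        if boot_samples is not None:
            rng = rng or np.random.default_rng(0)
            sims = boot_samples[:, 0] + boot_samples[:, 1] * lx
            for j, t in enumerate(fit.noninterc_terms[1:], start=2):
                sims = sims + boot_samples[:, j] * used.get(t, 0.0)
            if include_residual:
                depth = (
                    tip_depth
                    if tip_depth is not None
                    else 1.0
                )
                sd = float(np.sqrt(fit.sigma2 * depth))
                sims = sims + rng.normal(0.0, sd, size=len(sims))
            lo, hi = np.percentile(sims, [2.5, 97.5])
            lo, hi = 10.0 ** lo, 10.0 ** hi
            point = 10.0 ** linpred
            ci = (min(lo, point), max(hi, point))
        return PredictionResult(
            point=10.0 ** linpred,
            ci95=ci,
            basis="fitted",
            covariates_used=used,
        )

    key, eq, covariates = _resolve_equation(element, equation, covariates)
    linpred = eq["intercept"] + eq["slope"] * lx
    used = {}
    for cov, effect in eq["covariates"].items():
        v = float(covariates[cov])
        linpred += effect * v
        used[cov] = v
    basis = "global" if key[0].startswith("Testudinata") else "clade-specific"
    return PredictionResult(
        point=float(10.0 ** linpred), ci95=None, basis=basis,
        covariates_used=used,
    )


def predict_bm(scl_mm: float, coeffs=BM_COEFFS) -> BodyMass:
    """Body mass from straight carapace length.

    log10(BM grams) = slope * log10(SCL mm) + intercept, with the shipped
    published coefficients (2.73, -3.18) by default; a refit BM ~ SCL
    model's coefficients may be passed instead.
    """
    if scl_mm <= 0:
        raise ValueError("SCL must be positive")
    slope, intercept = coeffs
    return BodyMass(grams=float(10.0 ** (slope * np.log10(scl_mm) + intercept)))


# -- rates -----------------------------------------------------------------


def compare_rate_distributions(sigma2_a, sigma2_b):
    """Welch two-sample t-test between two bootstrap sigma^2 samples."""
    a = np.asarray(sigma2_a, float)
    b = np.asarray(sigma2_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("zero variance in both samples")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# -- reporting -------------------------------------------------------------


def fits_to_table(fits, r2s=None, cis=None) -> pd.DataFrame:
    """Long-format results table (one row per model term).

    Columns follow the published layout: Model, N, lambda, sigma2, AICc,
    AICc_w, R2, Variable, Coef (95% CI), SE, t, p.
    """
    fits = list(fits)
    finite = [f for f in fits if np.isfinite(f.aicc)]
    ws = {}
    if len(finite) >= 2:
        for f, w in zip(finite, aicc_weights([f.aicc for f in finite])):
            ws[id(f)] = w
    rows = []
    for f in fits:
        r2 = (r2s or {}).get(f.model, f.r2)
        fci = (cis or {}).get(f.model, f.ci95)
        for j, term in enumerate(f.terms):
            ci_txt = ""
            if fci and term in fci:
                lo, hi = fci[term]
                ci_txt = f" ({lo:.2f}, {hi:.2f})"
            rows.append(
                {
                    "Model": f.model if j == 0 else "",
                    "N": f.n if j == 0 else "",
                    "lambda": round(f.lam, 3) if j == 0 else "",
                    "sigma2": f"{f.sigma2:.3g}" if j == 0 else "",
                    "AICc": round(f.aicc, 1) if j == 0 else "",
                    "AICc_w": (
                        round(ws[id(f)], 3)
                        if j == 0 and id(f) in ws
                        else ""
                    ),
                    "R2": (
                        round(r2, 3) if j == 0 and r2 is not None else ""
                    ),
                    "Variable": term,
                    "Coef (95% CI)": f"{f.coef[j]:.3g}{ci_txt}",
                    "SE": f"{f.se[j]:.3g}",
                    "t": round(float(f.tvals[j]), 2),
                    "p": f"{f.pvals[j]:.2e}",
                }
            )
    return pd.DataFrame(rows)
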