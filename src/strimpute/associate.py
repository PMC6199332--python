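"""Association testing, power simulation and the eSTR regression.

Phenotypes are simulated from STR genotypes under three generative
models: additive (P = beta*G + E with G the standardised dosage and
E ~ N(0, 1 - beta), the noise term read as variance), case-control
(logit(p_i) = beta*X_i, Bernoulli outcomes) and quadratic
(P = beta*G^2 + E with G the squared dosage scaled by the cohort mean
allele length).  Power is the fraction of seeded simulations whose
nominal association p-value falls below alpha, evaluated separately for
the causal STR, the imputed STR and the best tag SNP.

The eSTR regression follows the standard cis-eQTL recipe: genes with
zero median expression are dropped, expression is quantile-normalized to
a standard normal, STR dosage is standardised, and expression is
regressed on dosage plus covariates.  A nested-model ANOVA (Y ~ eSNP vs
Y ~ eSNP + eSTR) quantifies the STR's explanatory value beyond the best
SNP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

PHENO_MODELS = ("additive", "case_control", "quadratic")


def scale_genotype(dosages: np.ndarray) -> np.ndarray:
    """Standardise a dosage vector to mean 0 and (population) variance 1."""
    x = np.asarray(dosages, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot scale a constant genotype vector")
    return (x - x.mean()) / sd


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Map values to standard-normal scores by rank.

    Ranks r (ties averaged) map to Phi^{-1}((r - 0.5) / n); the result is
    rank-preserving with mean ~0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / x.size)


@dataclass(frozen=True)
class PhenotypeSet:
    values: np.ndarray
    model: str
    beta: float
    seed: int


def _quadratic_g(dosages: np.ndarray, allele_lengths: np.ndarray | None) -> np.ndarray:
    """Squared sum of allele lengths scaled by the cohort mean allele length."""
    d = np.asarray(dosages, dtype=float)
    if allele_lengths is None:
        allele_lengths = d / 2.0
    mean_len = float(np.mean(allele_lengths))
    if mean_len == 0:
        raise ValueError("mean allele length is zero; quadratic scaling undefined")
    return d**2 / mean_len


def simulate_phenotype(
    dosages: np.ndarray,
    model: str,
    beta: float,
    seed: int,
    allele_lengths: np.ndarray | None = None,
) -> PhenotypeSet:
    """Simulate a phenotype from STR dosages under one generative model.

    additive: P = beta*G + E, G standardised dosage, E ~ N(0, 1 - beta)
    (variance); requires beta <= 1.  case_control: Bernoulli outcomes
    with logit(p_i) = beta * X_i on the standardised dosage.  quadratic:
    P = beta*G^2 + E with G the squared dosage scaled by the mean allele
    length (``allele_lengths`` supplies absolute per-allele lengths;
    defaults to dosage/2).
    """
    if model not in PHENO_MODELS:
        raise ValueError(f"model must be one of {PHENO_MODELS}, got {model!r}")
    rng = np.random.default_rng(seed)
    if model == "case_control":
        x = scale_genotype(dosages)
        p = 1.0 / (1.0 + np.exp(-beta * x))
        values = (rng.random(x.shape[0]) < p).astype(float)
        return PhenotypeSet(values, model, beta, seed)
    if beta > 1:
        raise ValueError(f"additive/quadratic noise variance 1 - beta < 0 for beta={beta}")
    noise_sd = float(np.sqrt(1.0 - beta))
    if model == "additive":
        g = scale_genotype(dosages)
    else:
        g = _quadratic_g(dosages, allele_lengths)
    values = beta * g + rng.normal(0.0, noise_sd, size=np.asarray(dosages).shape[0])
    return PhenotypeSet(values, model, beta, seed)


@dataclass(frozen=True)
class AssocResult:
    variant: str
    kind: str
    beta_hat: float
    se: float
    p_value: float
    converged: bool = True


def _ols_slope(x: np.ndarray, y: np.ndarray, variant: str) -> AssocResult:
    X = sm.add_constant(np.asarray(x, dtype=float))
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return AssocResult(variant, "linear", float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1]))


def _logit_slope(x: np.ndarray, y: np.ndarray, variant: str) -> AssocResult:
    X = sm.add_constant(np.asarray(x, dtype=float))
    try:
        fit = sm.Logit(np.asarray(y, dtype=float), X).fit(disp=0, maxiter=100)
    except Exception:
        return AssocResult(variant, "logistic", np.nan, np.nan, np.nan, converged=False)
    if not fit.mle_retvals.get("converged", True) or not np.all(np.isfinite(fit.bse)):
        return AssocResult(
            variant, "logistic", float(fit.params[1]), np.nan, np.nan, converged=False
        )
    return AssocResult(
        variant, "logistic", float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
    )


def association_test(
    genotype: np.ndarray,
    phenotype: np.ndarray,
    kind: str = "linear",
    variant: str = "variant",
    allele_pairs: Sequence[tuple[int, int]] | None = None,
) -> AssocResult | list[AssocResult]:
    """Single-variant association test.

    linear: OLS slope test of phenotype on dosage.  logistic: ML logit
    slope test; separation or non-convergence is flagged rather than
    raised.  per_allele: one linear test per distinct STR allele on its
    0/1/2 copy-count encoding (``allele_pairs`` supplies the unordered
    genotype pairs), returned as a list.
    """
    y = np.asarray(phenotype, dtype=float)
    if kind == "per_allele":
        if allele_pairs is None:
            raise ValueError("per_allele tests need the allele pairs")
        alleles = sorted({a for pair in allele_pairs for a in pair})
        out = []
        for a in alleles:
            counts = np.array([(p[0] == a) + (p[1] == a) for p in allele_pairs], dtype=float)
            if counts.std() == 0:
                continue
            out.append(_ols_slope(counts, y, variant=f"{variant}:allele={a}"))
        return out
    x = np.asarray(genotype, dtype=float)
    if x.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    if x.std() == 0:
        raise ValueError("constant genotype encoding")
    if kind == "linear":
        return _ols_slope(x, y, variant)
    if kind == "logistic":
        return _logit_slope(x, y, variant)
    raise ValueError(f"unknown test kind {kind!r}")


def _vectorized_ols_p(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Exact OLS slope-test p-values of each column of Y on x (with intercept)."""
    n = x.shape[0]
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt((xc**2).sum()) * np.sqrt((Yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ Yc) / denom
        r = np.clip(r, -1.0, 1.0)
        t2 = r**2 * (n - 2) / (1.0 - r**2)
    p = stats.f.sf(t2, 1, n - 2)
    return np.where(np.isfinite(p), p, 0.0)


def estimate_power(
    causal_dosages: np.ndarray,
    tested: Mapping[str, np.ndarray],
    model: str = "additive",
    beta: float = 0.1,
    n_sims: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    allele_lengths: np.ndarray | None = None,
    per_allele_pairs: Sequence[tuple[int, int]] | None = None,
) -> dict[str, float]:
    """Power per tested variant: fraction of simulations with p < alpha.

    Phenotypes are simulated from the causal STR dosages ``n_sims``
    times; each entry of ``tested`` (e.g. causal STR, imputed STR, best
    tag SNP dosages) is tested against every simulated phenotype.  For
    quantitative models the exact OLS slope test is applied in vectorised
    form; case-control uses the logit fit per simulation.  Passing
    ``per_allele_pairs`` adds a ``per_allele`` entry scored by the best
    (minimum) per-allele p-value per simulation.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    n = np.asarray(causal_dosages).shape[0]
    phenos = np.column_stack(
        [
            simulate_phenotype(causal_dosages, model, beta, seed + s, allele_lengths).values
            for s in range(n_sims)
        ]
    )
    power: dict[str, float] = {}
    for name, enc in tested.items():
        x = np.asarray(enc, dtype=float)
        if model == "case_control":
            hits = 0
            for s in range(n_sims):
                res = _logit_slope(x, phenos[:, s], name)
                hits += bool(res.converged and res.p_value < alpha)
            power[name] = hits / n_sims
        else:
            p = _vectorized_ols_p(x, phenos)
            power[name] = float(np.mean(p < alpha))
    if per_allele_pairs is not None and model != "case_control":
        alleles = sorted({a for pair in per_allele_pairs for a in pair})
        encodings = []
        for a in alleles:
            counts = np.array([(p0 == a) + (p1 == a) for p0, p1 in per_allele_pairs], dtype=float)
            if counts.std() > 0:
                encodings.append(counts)
        if encodings:
            pmat = np.column_stack([_vectorized_ols_p(e, phenos) for e in encodings])
            power["per_allele"] = float(np.mean(pmat.min(axis=1) < alpha))
    return power


def analytic_linear_power(beta: float, n: int, alpha: float = 0.05) -> float:
    """Noncentral-F power of the OLS slope test under the additive model.

    With G standardised and noise variance 1 - beta, the squared effect
    explains beta^2 of (beta^2 + 1 - beta) phenotype variance; the slope
    F(1, n-2) statistic has noncentrality n * beta^2 / (1 - beta).
    """
    if not 0 <= beta <= 1:
        raise ValueError("beta must be in [0, 1]")
    if beta == 1:
        return 1.0
    lam = n * beta**2 / (1.0 - beta)
    crit = stats.f.isf(alpha, 1, n - 2)
    return float(stats.ncf.sf(crit, 1, n - 2, lam))


@dataclass(frozen=True)
class EstrResult:
    gene: str
    str_id: str
    beta_hat: float
    se: float
    p_value: float
    n: int
    skipped: bool = False
    reason: str = ""


def estr_single(
    expression: np.ndarray,
    dosages: np.ndarray,
    covariates: np.ndarray | None = None,
    gene: str = "gene",
    str_id: str = "str",
    normalize: bool = True,
) -> EstrResult:
    """One gene x STR eSTR regression: qnorm(Y) ~ scaled dosage + covariates."""
    y = np.asarray(expression, dtype=float)
    n = y.shape[0]
    if normalize:
        y = quantile_normalize(y)
    try:
        x = scale_genotype(dosages)
    except ValueError:
        return EstrResult(gene, str_id, np.nan, np.nan, np.nan, n, True, "constant dosage")
    cols = [np.ones(n), x]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariate rows must match the number of samples")
        cols.extend(C.T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return EstrResult(gene, str_id, np.nan, np.nan, np.nan, n, True, "collinear design")
    fit = sm.OLS(y, X).fit()
    return EstrResult(gene, str_id, float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1]), n)


def estr_scan(
    expression: "pd.DataFrame",
    gene_positions: Mapping[str, int],
    str_dosages: "pd.DataFrame",
    str_positions: Mapping[str, int],
    covariates: np.ndarray | None = None,
    window_bp: int = 100_000,
) -> list[EstrResult]:
    """cis eSTR scan: every STR within the window of each expressed gene.

    ``expression`` is genes x samples; ``str_dosages`` is STRs x samples
    with matching sample columns.  Genes with median expression of zero
    are excluded; remaining expression rows are quantile-normalized.
    """
    import pandas as pd  # local: keeps module import light

    if list(expression.columns) != list(str_dosages.columns):
        raise ValueError("expression and dosage tables must share sample columns")
    out: list[EstrResult] = []
    for gene, row in expression.iterrows():
        if np.median(row.values) == 0:
            continue
        gpos = gene_positions[gene]
        for str_id, drow in str_dosages.iterrows():
            if abs(str_positions[str_id] - gpos) > window_bp:
                continue
            out.append(
                estr_single(row.values, drow.values, covariates, gene=str(gene), str_id=str(str_id))
            )
    return out


def anova_nested_comparison(
    expression: np.ndarray, esnp_dosage: np.ndarray, estr_dosage: np.ndarray
) -> float:
    """F-test of Y ~ eSNP vs Y ~ eSNP + eSTR (one extra parameter).

    Returns the p-value for the STR's added explanatory value; NaN when
    the STR dosage is collinear with the SNP dosage.
    """
    y = np.asarray(expression, dtype=float)
    n = y.shape[0]
    if n <= 3:
        raise ValueError("need more than 3 samples")
    snp = np.asarray(esnp_dosage, dtype=float)
    strd = np.asarray(estr_dosage, dtype=float)
    X_full = sm.add_constant(np.column_stack([snp, strd]))
    if np.linalg.matrix_rank(X_full) < 3:
        return float("nan")
    reduced = sm.OLS(y, sm.add_constant(snp)).fit()
    full = sm.OLS(y, X_full).fit()
    table = sm.stats.anova_lm(reduced, full)
    return float(table["Pr(>F)"].iloc[1])
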