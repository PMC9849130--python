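"""Covariate-adjusted case-control association testing.

Two genotype codings are supported: additive (allele count 0/1/2) and
recessive, which contrasts homozygous-alternate carriers against everyone
else ({0,1} -> 0, 2 -> 1).  P values come from the score test of the
covariate-only null model (robust at low counts); effect sizes from a
Firth-penalized fit, which stays finite under separation.  When the Firth
fit does not converge within 25 iterations, or a genotype-by-outcome cell
is empty under recessive coding, the test falls back to Fisher's exact
test on the collapsed 2x2 table and the result is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io import MISSING, GenotypeMatrix, PhenotypeTable, PipelineConfig

MODELS = ("additive", "recessive")

#: HLA region excluded from recessive scans: chr6, [25 Mb, 35 Mb)
HLA_REGION = ("6", 25_000_000, 35_000_000)

FIRTH_MAX_ITER = 25


class DegenerateInput(ValueError):
    """Outcome or genotype vector is constant among complete cases."""


@dataclass
class AssociationResult:
    """One variant x phenotype x model test outcome."""

    variant_key: str
    phenotype: str
    model: str
    beta: float
    se: float
    p: float
    n_cases: int
    n_controls: int
    n_hom: int
    n_het: int
    method: str  # logistic_score | logistic_firth_wald | fisher_exact
    or_ci: tuple[float, float, float] | None = None  # (OR, lo, hi), fisher path

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0.0 < self.p <= 1.0:
            raise ValueError(f"p value outside (0,1]: {self.p}")
        if self.n_hom + self.n_het > self.n_cases + self.n_controls:
            raise ValueError("carrier counts exceed sample size")
        if self.method == "fisher_exact" and self.or_ci is None:
            raise ValueError("fisher_exact results must carry an odds-ratio CI")


def code_genotype(g: np.ndarray, model: str) -> np.ndarray:
    """Recode a dosage vector for the requested model; missing preserved.

    additive -> identity; recessive -> {0,1} -> 0, 2 -> 1.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    g = np.asarray(g)
    if model == "additive":
        return g.copy()
    coded = np.where(g == 2, 1, 0).astype(g.dtype)
    if np.issubdtype(g.dtype, np.floating):
        coded = np.where(np.isnan(g), np.nan, coded)
    else:
        coded = np.where(g == MISSING, MISSING, coded)
    return coded


def filter_variants(geno: GenotypeMatrix, min_hom: int = 5,
                    exclude_regions: Sequence[tuple[str, int, int]] = (HLA_REGION,),
                    ) -> tuple[list[int], list[dict]]:
    """Recessive-eligible variant subset plus a per-drop reason log.

    Keeps variants with at least ``min_hom`` homozygous-alternate
    individuals that fall outside every excluded ``(chrom, start, end)``
    half-open interval.
    """
    kept: list[int] = []
    log: list[dict] = []
    for j, rec in enumerate(geno.variants):
        masked = False
        for chrom, start, end in exclude_regions:
            if rec.chrom == chrom and start <= rec.pos < end:
                log.append({"variant": rec.key, "reason": f"excluded_region:{chrom}:{start}-{end}"})
                masked = True
                break
        if masked:
            continue
        n_hom = int((geno.dosage(j) == 2).sum())
        if n_hom < min_hom:
            log.append({"variant": rec.key, "reason": f"n_hom={n_hom}<{min_hom}"})
            continue
        kept.append(j)
    return kept, log


# ---------------------------------------------------------------------------
# Core fitting machinery
# ---------------------------------------------------------------------------

def _logistic_irls(y: np.ndarray, X: np.ndarray, max_iter: int = 50,
                   tol: float = 1e-10) -> np.ndarray:
    """Plain maximum-likelihood logistic fit (used for the null model)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise DegenerateInput("rank-deficient covariate matrix in null fit") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def score_test(y: np.ndarray, x: np.ndarray, C: np.ndarray) -> tuple[float, float]:
    """Score test for adding ``x`` to the logistic null model with design ``C``.

    Returns ``(chi2_statistic, two_sided_p)``.  ``C`` must include an
    intercept column.
    """
    beta0 = _logistic_irls(y, C)
    p = 1.0 / (1.0 + np.exp(-(C @ beta0)))
    w = p * (1.0 - p)
    u = float(x @ (y - p))
    cwc = (C * w[:, None]).T @ C
    cwx = C.T @ (w * x)
    v = float(x @ (w * x) - cwx @ np.linalg.solve(cwc, cwx))
    if v <= 0:
        return np.nan, np.nan
    t = u * u / v
    return t, float(stats.chi2.sf(t, df=1))


def firth_logit(y: np.ndarray, X: np.ndarray, max_iter: int = FIRTH_MAX_ITER,
                tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray, bool]:
    """Firth (Jeffreys-penalized) logistic regression.

    Returns ``(beta, se, converged)``.  The penalized score is
    ``X' (y - p + h*(0.5 - p))`` with ``h`` the hat diagonal; estimates
    remain finite under separation.
    """
    n, k = X.shape
    beta = np.zeros(k)

    def penalized_loglik(b: np.ndarray) -> float:
        eta = X @ b
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        info = (X * w[:, None]).T @ X
        sign, logdet = np.linalg.slogdet(info)
        return ll + 0.5 * logdet if sign > 0 else -np.inf

    ll_old = penalized_loglik(beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        info = (X * w[:, None]).T @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise DegenerateInput("singular information matrix in Firth fit") from exc
        # hat diagonal of the weighted design
        h = np.einsum("ij,jk,ik->i", X * w[:, None], info_inv, X)
        u_star = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ u_star
        # step-halving on the penalized likelihood
        for _half in range(10):
            ll_new = penalized_loglik(beta + step)
            if ll_new >= ll_old - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        ll_old = ll_new
        if np.max(np.abs(u_star)) < tol or np.max(np.abs(step)) < 1e-8:
            converged = True
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = (X * w[:, None]).T @ X
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se, converged


def _fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher P: sum of hypergeometric probabilities (over
    tables with the observed margins) not exceeding the observed table's.

    Vectorized over the support, so sweeps over many tables stay fast.
    Uses the conventional relative tie tolerance of 1e-7 (as
    ``scipy.stats.fisher_exact`` does).
    """
    from scipy.special import gammaln

    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    x = np.arange(lo, hi + 1)
    logpmf = (gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
              + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - c1 + x + 1)
              - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1)))
    pmf = np.exp(logpmf)
    p = pmf[pmf <= pmf[a - lo] * (1.0 + 1e-7)].sum()
    return float(min(p, 1.0))


def fisher_fallback(table: np.ndarray | Sequence[Sequence[int]], ci: bool = True,
                    ) -> tuple[float, float, tuple[float, float]]:
    """Fisher's exact test on a 2x2 table.

    Two-sided P is the sum of hypergeometric probabilities of tables (with
    the same margins) no more probable than the observed one; the odds
    ratio is the conditional MLE with an exact (conditional) 95% CI.  Pass
    ``ci=False`` to skip the (comparatively slow) odds-ratio machinery,
    e.g. in large calibration sweeps.  Returns
    ``(p, odds_ratio, (ci_low, ci_high))``.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t < 0) or np.any(t != np.floor(t)):
            raise ValueError("table entries must be nonnegative integers")
        t = t.astype(np.int64)
    p = _fisher_two_sided_p(int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1]))
    if not ci:
        return p, float("nan"), (float("nan"), float("nan"))
    res = stats.contingency.odds_ratio(t, kind="conditional")
    conf = res.confidence_interval(confidence_level=0.95)
    return p, float(res.statistic), (float(conf.low), float(conf.high))


def fit_association(y: np.ndarray, x: np.ndarray, C: np.ndarray | None = None,
                    dosage: np.ndarray | None = None, variant_key: str = "",
                    phenotype: str = "", model: str = "additive") -> AssociationResult:
    """Test a coded genotype ``x`` against a binary outcome ``y``.

    ``C`` is the covariate matrix WITHOUT intercept (one is added); pass
    ``None`` for an intercept-only null.  ``dosage`` (raw 0/1/2) is used
    for the homozygote/heterozygote counts when given; otherwise counts are
    derived from ``x``.  Missing values (NaN or negative) in ``y``/``x``
    drop the individual (complete-case).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if dosage is not None:
        dosage = np.asarray(dosage, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x) & (y >= 0) & (x >= 0)
    if C is not None:
        C = np.asarray(C, dtype=float)
        keep &= np.isfinite(C).all(axis=1)
    y, x = y[keep], x[keep]
    d = dosage[keep] if dosage is not None else x
    design_c = np.ones((len(y), 1)) if C is None else np.column_stack(
        [np.ones(len(y)), C[keep]])

    if len(y) == 0 or np.all(y == y[0]):
        raise DegenerateInput("outcome is constant (or empty) among complete cases")
    if np.all(x == x[0]):
        raise DegenerateInput("coded genotype is constant among complete cases")

    n_cases = int((y == 1).sum())
    n_controls = int((y == 0).sum())
    if dosage is not None:
        n_hom, n_het = int((d == 2).sum()), int((d == 1).sum())
    elif model == "additive":
        n_hom, n_het = int((x == 2).sum()), int((x == 1).sum())
    else:  # recessive coding: coded 1 means homozygous, hets not recoverable
        n_hom, n_het = int((x == 1).sum()), 0

    # collapsed 2x2: carrier (coded > 0) vs outcome
    carrier = x > 0
    tab = np.array([[int((carrier & (y == 1)).sum()), int((carrier & (y == 0)).sum())],
                    [int((~carrier & (y == 1)).sum()), int((~carrier & (y == 0)).sum())]])
    zero_cell = (model == "recessive") and (tab == 0).any()

    method = "logistic_score"
    beta = se = np.nan
    p = np.nan
    if not zero_cell:
        t_stat, p = score_test(y, x, design_c)
        X = np.column_stack([design_c, x])
        fbeta, fse, converged = firth_logit(y, X)
        if converged:
            beta, se = float(fbeta[-1]), float(fse[-1])
            if not np.isfinite(p):
                p = float(2.0 * stats.norm.sf(abs(beta / se)))
                method = "logistic_firth_wald"
        else:
            zero_cell = True  # treat non-convergence like separation

    or_ci = None
    if zero_cell:
        method = "fisher_exact"
        p, or_est, (lo, hi) = fisher_fallback(tab)
        or_ci = (or_est, lo, hi)
        beta = float(np.log(or_est)) if 0 < or_est < np.inf else np.nan
        se = np.nan

    return AssociationResult(variant_key=variant_key, phenotype=phenotype, model=model,
                             beta=beta, se=se, p=float(p), n_cases=n_cases,
                             n_controls=n_controls, n_hom=n_hom, n_het=n_het,
                             method=method, or_ci=or_ci)


def run_phewas(geno: GenotypeMatrix, pheno: PhenotypeTable,
               models: Iterable[str] = MODELS,
               config: PipelineConfig | None = None,
               endpoints: Sequence[str] | None = None,
               use_covariates: bool = True) -> list[AssociationResult]:
    """All eligible variant x endpoint x model tests, deterministically ordered.

    Recessive eligibility applies :func:`filter_variants` (min_hom, HLA
    mask); the additive scan tests every variant.  Individuals must match
    between genotype and phenotype tables.
    """
    config = config or PipelineConfig()
    models = list(models)
    for m in models:
        if m not in MODELS:
            raise ValueError(f"unknown model {m!r}")
    g_ids, p_ids = list(geno.sample_ids), list(pheno.sample_ids)
    if g_ids != p_ids:
        only_g = set(g_ids) - set(p_ids)
        only_p = set(p_ids) - set(g_ids)
        raise ValueError(
            f"individual id mismatch: {len(only_g)} only in genotypes "
            f"(e.g. {sorted(only_g)[:3]}), {len(only_p)} only in phenotypes "
            f"(e.g. {sorted(only_p)[:3]})")
    endpoints = list(endpoints) if endpoints is not None else list(pheno.endpoints.columns)
    rec_eligible, _ = filter_variants(geno, min_hom=config.min_hom)
    rec_set = set(rec_eligible)
    C = pheno.covariates.to_numpy(dtype=float) if use_covariates else None

    results: list[AssociationResult] = []
    for j, rec in enumerate(geno.variants):
        g = geno.dosage(j).astype(float)
        g[g == MISSING] = np.nan
        for ep in endpoints:
            y = pheno.endpoint(ep)
            if (y == 1).sum() == 0 or (y == 0).sum() == 0:
                continue  # degenerate endpoint, skipped
            for model in models:
                if model == "recessive" and j not in rec_set:
                    continue
                x = code_genotype(g, model)
                try:
                    res = fit_association(y, x, C=C, dosage=g, variant_key=rec.key,
                                          phenotype=ep, model=model)
                except DegenerateInput:
                    continue
                results.append(res)
    return results
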