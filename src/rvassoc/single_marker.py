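"""Single-marker association tests for common and low-frequency variants.

Variants showing differential missingness or coverage between groups are
removed first, then each remaining variant with MAF >= 1% is tested by
logistic regression of phenotype on allele dosage with age as a
covariate. Statistical significance is assessed by permutation of the
phenotype labels (ages stay attached to their samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, fisher_exact, mannwhitneyu

from .core import MISSING, Cohort, DataError, GenotypeMatrix


@dataclass
class MarkerResult:
    variant_id: str
    maf: float
    beta: float
    statistic: float
    asymptotic_p: float
    permutation_p: float
    n_permutations: int
    flagged: bool = False


def differential_qc(
    gm: GenotypeMatrix,
    cohort: Cohort,
    alpha: float = 1e-5,
) -> list[str]:
    """Variant ids failing the between-group call-rate or depth tests.

    Per variant: (a) two-sided Fisher's exact test on the missing /
    called x case / control table; (b) two-sided rank-sum test on
    per-sample depths by group (skipped when no depths are available).
    A variant is removed when either p-value falls below ``alpha``.
    """
    case = cohort.is_case
    removed = []
    ids = gm.variants.variant_ids()
    for j in range(gm.n_variants):
        miss = gm.dosage[j] == MISSING
        table = [
            [int(miss[case].sum()), int((~miss)[case].sum())],
            [int(miss[~case].sum()), int((~miss)[~case].sum())],
        ]
        p_call = float(fisher_exact(table)[1])
        p_depth = 1.0
        if gm.depth is not None:
            dc, dx = gm.depth[j][case], gm.depth[j][~case]
            if len(dc) and len(dx) and not (
                np.all(dc == dc[0]) and np.all(dx == dx[0]) and dc[0] == dx[0]
            ):
                p_depth = float(
                    mannwhitneyu(dc, dx, alternative="two-sided").pvalue
                )
        if p_call < alpha or p_depth < alpha:
            removed.append(ids[j])
    return removed


def _irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10):
    """Newton/IRLS logistic fit; returns (beta, cov) or None on failure."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if w.max() < 1e-12:
            return None
        XtW = X.T * w
        H = XtW @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return None
        beta_new = beta + step
        if not np.isfinite(beta_new).all() or np.abs(beta_new).max() > 50:
            return None  # divergence / separation
        if np.abs(step).max() < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    try:
        cov = np.linalg.inv((X.T * w) @ X)
    except np.linalg.LinAlgError:
        return None
    return beta, cov


def logistic_score(
    dosage: np.ndarray, cohort: Cohort
) -> tuple[float, float, float, bool]:
    """Wald test of the dosage term in ``phenotype ~ 1 + age + dosage``.

    Returns ``(beta, z^2 statistic, asymptotic p, flagged)``. Missing
    dosages are excluded. Monomorphic dosage or failure to converge
    (e.g. perfect separation) yields a flagged NaN result rather than an
    exception.
    """
    dosage = np.asarray(dosage)
    obs = dosage != MISSING
    d = dosage[obs].astype(float)
    if len(d) == 0 or d.var() == 0:
        return float("nan"), float("nan"), float("nan"), True
    y = cohort.is_case[obs].astype(float)
    age = cohort.age[obs]
    X = np.column_stack([np.ones(len(d)), age, d])
    fit = _irls_logistic(X, y)
    if fit is None:
        return float("nan"), float("nan"), float("nan"), True
    beta, cov = fit
    se2 = cov[2, 2]
    if se2 <= 0 or not np.isfinite(se2):
        return float(beta[2]), float("nan"), float("nan"), True
    stat = beta[2] ** 2 / se2
    return float(beta[2]), float(stat), float(chi2.sf(stat, 1)), False


def permutation_p(
    statistic_fn,
    cohort: Cohort,
    b: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, int]:
    """Label-permutation p-value for an arbitrary cohort statistic.

    ``statistic_fn(cohort) -> float`` is evaluated on the observed
    cohort and on ``b`` cohorts with case/control labels shuffled across
    samples (ages keep their samples). Non-finite permuted statistics
    count as non-exceedances. ``p = (1 + #{perm >= obs}) / (b + 1)``.
    """
    if b < 1:
        raise DataError("need at least one permutation")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    observed = statistic_fn(cohort)
    r = 0
    labels = cohort.is_case
    for _ in range(b):
        perm = Cohort(
            cohort.sample_ids, rng.permutation(labels), cohort.age
        )
        s = statistic_fn(perm)
        if np.isfinite(s) and s >= observed - 1e-12:
            r += 1
    return (r + 1.0) / (b + 1.0), b


def run_single_marker(
    gm: GenotypeMatrix,
    cohort: Cohort,
    min_maf: float = 0.01,
    qc_alpha: float = 1e-5,
    b: int = 10_000,
    seed: int = 0,
) -> tuple[list[MarkerResult], list[str]]:
    """Differential QC then per-variant logistic + permutation tests."""
    removed = set(differential_qc(gm, cohort, qc_alpha))
    rng = np.random.default_rng(seed)
    ids = gm.variants.variant_ids()
    results = []
    for j in range(gm.n_variants):
        if ids[j] in removed or gm.maf[j] < min_maf:
            continue
        dosage = gm.dosage[j]
        beta, stat, p_asym, flagged = logistic_score(dosage, cohort)
        if flagged:
            continue
        p_perm, used = permutation_p(
            lambda ch: logistic_score(dosage, ch)[1], cohort, b=b, seed=rng
        )
        results.append(
            MarkerResult(ids[j], float(gm.maf[j]), beta, stat, p_asym, p_perm, used)
        )
    return results, sorted(removed)
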