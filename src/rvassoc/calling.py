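"""Genotype-likelihood variant calling.

The calling stage turns per-site allele-supporting read evidence into a
called genotype matrix:

1. per-sample genotype log-likelihoods from base qualities,
2. maximum-likelihood population allele frequency via EM under
   Hardy-Weinberg equilibrium,
3. a site is called a SNP when twice the log-likelihood ratio of the
   polymorphic model against the monomorphic-reference null exceeds 24,
4. per-sample Bayesian genotype calls with the HWE prior at the ML
   allele frequency; samples covered by fewer than 8 reads are set
   missing,
5. a QC filter bank: base-quality rank-sum, strand-bias Fisher test,
   and depth / mapping-quality bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import fisher_exact, mannwhitneyu

from .core import (
    MISSING,
    Cohort,
    DataError,
    GenotypeMatrix,
    SiteReads,
    VariantTable,
)

LRT_THRESHOLD: float = 24.0
MIN_SAMPLE_DEPTH: int = 8
FILTER_ALPHA: float = 1e-5
MIN_MEAN_MAPQ: float = 20.0
DEPTH_N_SD: float = 3.0


@dataclass
class GenotypeLikelihoods:
    """Per-sample log-likelihood triples for (hom-ref, het, hom-alt)."""

    loglik: np.ndarray  # (n_samples, 3)
    depth: np.ndarray  # (n_samples,)

    def __post_init__(self) -> None:
        self.loglik = np.asarray(self.loglik, dtype=float)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.loglik.ndim != 2 or self.loglik.shape[1] != 3:
            raise DataError("loglik must be (n_samples, 3)")
        if not np.isfinite(self.loglik).all():
            raise DataError("non-finite genotype log-likelihoods")

    @property
    def n_samples(self) -> int:
        return self.loglik.shape[0]


@dataclass
class AFEstimate:
    """ML population allele-frequency estimate from an EM fit."""

    p_hat: float
    loglik: float
    iterations: int
    converged: bool


@dataclass
class SiteCall:
    """Full calling result for one site."""

    site_id: str
    af: AFEstimate
    lrt_statistic: float
    called: bool
    genotypes: np.ndarray  # per-sample dosage, MISSING where masked
    posteriors: np.ndarray  # posterior prob of the called genotype
    bq_p: float
    strand_p: float
    keep_bq: bool
    keep_strand: bool
    keep_depth_mapq: bool

    @property
    def passed_filters(self) -> bool:
        return self.keep_bq and self.keep_strand and self.keep_depth_mapq


def genotype_likelihoods(reads: SiteReads) -> GenotypeLikelihoods:
    """Per-read genotype log-likelihoods from Phred base qualities.

    With per-read error probability ``e = 10**(-Q/10)`` the emission
    probabilities for an allele-supporting read are::

        hom-ref:  P(ref) = 1 - e      P(alt) = e / 3
        het:      P(ref) = P(alt) = (1 - e)/2 + e/6
        hom-alt:  P(ref) = e / 3      P(alt) = 1 - e

    (a sequencing error hits each of the three other bases equally).
    Samples with zero depth get a flat ``(0, 0, 0)`` triple.
    """
    n = reads.n_samples
    ll = np.zeros((n, 3))
    for i in range(n):
        rq = reads.ref_quals[i]
        aq = reads.alt_quals[i]
        if len(rq) == 0 and len(aq) == 0:
            continue
        e_ref = 10.0 ** (-rq / 10.0)
        e_alt = 10.0 ** (-aq / 10.0)
        # log P(read | genotype) summed over ref- then alt-supporting reads
        ll[i, 0] = np.log(1.0 - e_ref).sum() + np.log(e_alt / 3.0).sum()
        ll[i, 2] = np.log(e_ref / 3.0).sum() + np.log(1.0 - e_alt).sum()
        het_ref = 0.5 * (1.0 - e_ref) + 0.5 * e_ref / 3.0
        het_alt = 0.5 * (1.0 - e_alt) + 0.5 * e_alt / 3.0
        ll[i, 1] = np.log(het_ref).sum() + np.log(het_alt).sum()
    return GenotypeLikelihoods(ll, reads.depth)


def _hwe_log_prior(p: float) -> np.ndarray:
    p = min(max(p, 0.0), 1.0)
    with np.errstate(divide="ignore"):
        return np.log(np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p]))


def marginal_loglik(gls: GenotypeLikelihoods, p: float) -> float:
    """Cohort log-likelihood of allele frequency ``p`` under HWE."""
    has_data = gls.depth > 0
    if not has_data.any():
        return 0.0
    return float(
        logsumexp(gls.loglik[has_data] + _hwe_log_prior(p), axis=1).sum()
    )


def estimate_af_em(
    gls: GenotypeLikelihoods,
    tol: float = 1e-8,
    max_iter: int = 100,
    p_init: float = 0.05,
) -> AFEstimate:
    """EM maximum-likelihood allele frequency under the HWE model.

    Each iteration computes genotype posteriors at the current frequency
    and re-estimates ``p`` as the posterior-expected alternate-allele
    fraction over samples with read data. The marginal likelihood is
    non-decreasing across iterations (a standard EM guarantee that the
    test-suite asserts).
    """
    has_data = gls.depth > 0
    n_eff = int(has_data.sum())
    if n_eff == 0:
        return AFEstimate(0.0, 0.0, 0, True)
    ll = gls.loglik[has_data]
    dosage = np.array([0.0, 1.0, 2.0])
    p = p_init
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        joint = ll + _hwe_log_prior(p)
        post = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
        p_new = float((post @ dosage).sum()) / (2.0 * n_eff)
        p_new = min(max(p_new, 0.0), 1.0)
        if abs(p_new - p) < tol:
            p = p_new
            converged = True
            break
        p = p_new
    return AFEstimate(p, marginal_loglik(gls, p), it, converged)


def lrt_call(
    gls: GenotypeLikelihoods,
    af: AFEstimate,
    threshold: float = LRT_THRESHOLD,
) -> tuple[float, bool]:
    """Likelihood-ratio SNP call against the monomorphic-reference null.

    Returns ``2 * (logL(p_hat) - logL(0))`` and whether it strictly
    exceeds ``threshold`` (default 24).
    """
    stat = 2.0 * (marginal_loglik(gls, af.p_hat) - marginal_loglik(gls, 0.0))
    stat = max(stat, 0.0)  # guard tiny negative round-off when p_hat ~ 0
    return stat, stat > threshold


def call_genotypes(
    gls: GenotypeLikelihoods,
    af: AFEstimate,
    min_depth: int = MIN_SAMPLE_DEPTH,
) -> tuple[np.ndarray, np.ndarray]:
    """Bayesian per-sample genotype calls with the HWE prior at ``p_hat``.

    Returns ``(genotypes, posteriors)``; samples covered by fewer than
    ``min_depth`` reads are set missing with posterior ``nan``.
    """
    joint = gls.loglik + _hwe_log_prior(af.p_hat)
    post = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
    geno = post.argmax(axis=1).astype(np.int8)
    best = post[np.arange(len(geno)), geno]
    masked = gls.depth < min_depth
    geno[masked] = MISSING
    best = np.where(masked, np.nan, best)
    return geno, best


def _pool_quals(reads: SiteReads) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (major, minor) base-quality arrays across all samples."""
    ref_q = np.concatenate([q for q in reads.ref_quals] or [np.empty(0, int)])
    alt_q = np.concatenate([q for q in reads.alt_quals] or [np.empty(0, int)])
    if len(alt_q) <= len(ref_q):
        return ref_q, alt_q
    return alt_q, ref_q


def filter_base_quality(
    reads: SiteReads, alpha: float = FILTER_ALPHA
) -> tuple[float, bool]:
    """Rank-sum test: are minor-allele base qualities lower than major's?

    One-sided Wilcoxon rank-sum on qualities pooled across all samples
    (exact for small pools without ties, normal approximation with tie
    correction otherwise). The site is kept when ``p >= alpha``.
    """
    major, minor = _pool_quals(reads)
    if len(minor) == 0 or len(major) == 0:
        return 1.0, True
    p = float(mannwhitneyu(minor, major, alternative="less", method="auto").pvalue)
    return p, p >= alpha


def strand_table(reads: SiteReads) -> np.ndarray:
    """Pooled 2x2 table: rows (major, minor allele), cols (fwd, rev)."""
    ref = np.array([reads.ref_fwd.sum(), reads.ref_rev.sum()], dtype=np.int64)
    alt = np.array([reads.alt_fwd.sum(), reads.alt_rev.sum()], dtype=np.int64)
    if alt.sum() <= ref.sum():
        return np.array([ref, alt])
    return np.array([alt, ref])


def filter_strand_bias(
    reads: SiteReads, alpha: float = FILTER_ALPHA
) -> tuple[float, bool]:
    """Two-sided Fisher's exact test for allele x strand association."""
    p = float(fisher_exact(strand_table(reads), alternative="two-sided")[1])
    return p, p >= alpha


def filter_depth_mapq(
    site_depth: float,
    depth_mean: float,
    depth_sd: float,
    mean_mapq: float,
    n_sd: float = DEPTH_N_SD,
    min_mapq: float = MIN_MEAN_MAPQ,
) -> bool:
    """Keep sites with unexceptional total depth and adequate MAPQ.

    Depth must lie within ``mean +/- n_sd * sd`` (lower bound floored at
    zero) and mean mapping quality must be at least ``min_mapq``.
    """
    lo = max(depth_mean - n_sd * depth_sd, 0.0)
    hi = depth_mean + n_sd * depth_sd
    return (lo <= site_depth <= hi) and mean_mapq >= min_mapq


def cohort_depth_stats(sites: list[SiteReads]) -> tuple[float, float]:
    """Mean and SD of per-site total depth across candidate sites."""
    totals = np.array([s.depth.sum() for s in sites], dtype=float)
    if len(totals) < 2:
        import warnings

        warnings.warn("fewer than 2 sites for depth stats; keeping all")
        return float(totals.mean()) if len(totals) else 0.0, math.inf
    return float(totals.mean()), float(totals.std(ddof=1))


def call_site(
    reads: SiteReads,
    depth_mean: float,
    depth_sd: float,
    lrt_threshold: float = LRT_THRESHOLD,
    min_depth: int = MIN_SAMPLE_DEPTH,
    alpha: float = FILTER_ALPHA,
) -> SiteCall:
    """Run the full calling + filter stack on a single site."""
    gls = genotype_likelihoods(reads)
    af = estimate_af_em(gls)
    stat, called = lrt_call(gls, af, threshold=lrt_threshold)
    if called:
        geno, post = call_genotypes(gls, af, min_depth=min_depth)
    else:
        geno = np.full(reads.n_samples, MISSING, dtype=np.int8)
        post = np.full(reads.n_samples, np.nan)
    bq_p, keep_bq = filter_base_quality(reads, alpha)
    sb_p, keep_sb = filter_strand_bias(reads, alpha)
    keep_dm = filter_depth_mapq(
        float(reads.depth.sum()), depth_mean, depth_sd, reads.mean_mapq
    )
    return SiteCall(
        reads.site_id, af, stat, called, geno, post,
        bq_p, sb_p, keep_bq, keep_sb, keep_dm,
    )


def call_cohort(
    sites: list[SiteReads],
    cohort: Cohort,
    genes: list[str] | None = None,
    vclasses: list[str] | None = None,
    lrt_threshold: float = LRT_THRESHOLD,
    min_depth: int = MIN_SAMPLE_DEPTH,
    alpha: float = FILTER_ALPHA,
) -> tuple[GenotypeMatrix, list[SiteCall]]:
    """Call every site and assemble the passing calls into a matrix.

    Only sites that are called SNPs and survive all three filters enter
    the returned :class:`GenotypeMatrix`. ``genes`` / ``vclasses``
    supply per-site annotation (defaulting to placeholders).
    """
    depth_mean, depth_sd = cohort_depth_stats(sites)
    calls = [
        call_site(s, depth_mean, depth_sd, lrt_threshold, min_depth, alpha)
        for s in sites
    ]
    kept = [
        i for i, c in enumerate(calls) if c.called and c.passed_filters
    ]
    genes = genes if genes is not None else ["NA"] * len(sites)
    vclasses = vclasses if vclasses is not None else ["non-silent"] * len(sites)
    table = VariantTable(
        [sites[i].chrom for i in kept],
        np.array([sites[i].pos for i in kept], dtype=np.int64),
        [sites[i].ref for i in kept],
        [sites[i].alt for i in kept],
        [genes[i] for i in kept],
        [vclasses[i] for i in kept],
    )
    dosage = (
        np.vstack([calls[i].genotypes for i in kept])
        if kept
        else np.empty((0, cohort.n_samples), dtype=np.int8)
    )
    depth = (
        np.vstack([sites[i].depth for i in kept])
        if kept
        else np.empty((0, cohort.n_samples), dtype=np.int64)
    )
    gm = GenotypeMatrix(table, list(cohort.sample_ids), dosage, depth=depth)
    return gm, calls
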