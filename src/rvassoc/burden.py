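"""Gene-based rare-variant association tests.

Four complementary collapsing statistics per gene, each one-sided for
excess minor alleles in cases:

``burden``
    total minor-allele count among cases.
``frqwgt``
    control-frequency weighted sum: variant ``j`` gets weight
    ``1 / sqrt(n_ctrl_j * q_j * (1 - q_j))`` with
    ``q_j = (ctrl minor count + 1) / (2 * n_ctrl_j + 2)``, so alleles
    absent from controls weigh most.
``vt``
    variable-threshold: the maximum over observed MAF cutoffs of the
    case burden standardized under label exchangeability.
``uniq``
    minor alleles carried by cases at variants never seen in controls.

Significance comes from adaptive permutation of case/control labels:
permutation stops once the observed statistic has been met or exceeded
``r_stop`` times, and reports ``p = (r + 1) / (b + 1)``.

Missing genotypes contribute zero minor alleles throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact

from .core import (
    LOWFREQ_MAF,
    MISSING,
    RARE_MAF,
    Cohort,
    DataError,
    GenotypeMatrix,
)

logger = logging.getLogger(__name__)

TESTS = ("burden", "frqwgt", "vt", "uniq")

STRATA = {
    "rare": (0.0, RARE_MAF),
    "rare_lowfreq": (0.0, LOWFREQ_MAF),
}


def classify_maf(maf: float) -> str:
    """Assign a MAF to its stratum: rare, low-frequency or common.

    Boundaries: rare is ``maf < 0.01``; low-frequency is
    ``0.01 <= maf < 0.05``; common is ``maf >= 0.05``.
    """
    if not 0.0 <= maf <= 0.5:
        raise DataError(f"MAF {maf} outside [0, 0.5]")
    if maf < RARE_MAF:
        return "rare"
    if maf < LOWFREQ_MAF:
        return "low-frequency"
    return "common"


def _clean(dosages: np.ndarray) -> np.ndarray:
    """Missing dosages count as zero minor alleles."""
    d = np.asarray(dosages)
    return np.where(d == MISSING, 0, d).astype(np.int64)


def burden_stat(dosages: np.ndarray, case_mask: np.ndarray) -> float:
    """Total minor-allele count among cases."""
    return float(_clean(dosages)[:, case_mask].sum())


def _frqwgt_weights(dosages: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    d = np.asarray(dosages)
    ctrl = ~np.asarray(case_mask, bool)
    n_ctrl = (d[:, ctrl] != MISSING).sum(axis=1)
    ctrl_count = _clean(d)[:, ctrl].sum(axis=1)
    q = (ctrl_count + 1.0) / (2.0 * n_ctrl + 2.0)
    return 1.0 / np.sqrt(np.maximum(n_ctrl, 1) * q * (1.0 - q))


def frqwgt_stat(dosages: np.ndarray, case_mask: np.ndarray) -> float:
    """Control-frequency-weighted minor-allele sum among cases."""
    w = _frqwgt_weights(dosages, case_mask)
    return float((w @ _clean(dosages))[np.asarray(case_mask, bool)].sum())


def uniq_stat(dosages: np.ndarray, case_mask: np.ndarray) -> float:
    """Case minor alleles at variants with zero control minor alleles."""
    d = _clean(dosages)
    case_mask = np.asarray(case_mask, bool)
    ctrl_count = d[:, ~case_mask].sum(axis=1)
    return float(d[ctrl_count == 0][:, case_mask].sum())


def vt_stat(
    dosages: np.ndarray, mafs: np.ndarray, case_mask: np.ndarray
) -> float:
    """Max over MAF thresholds of the standardized case burden.

    For each threshold ``t`` in the observed variant MAFs, the burden of
    variants with ``MAF <= t`` among cases is standardized by its mean
    and SD under random assignment of case labels (sampling ``n_case``
    of ``n`` samples without replacement); the statistic is the maximum
    standardized burden. Thresholds with zero variance contribute 0.
    """
    d = _clean(dosages)
    case_mask = np.asarray(case_mask, bool)
    mafs = np.asarray(mafs, float)
    thresholds = np.unique(mafs)
    n = d.shape[1]
    n_case = int(case_mask.sum())
    best = -np.inf
    for t in thresholds:
        y = d[mafs <= t].sum(axis=0).astype(float)  # per-sample score
        s = y[case_mask].sum()
        mu = n_case * y.mean()
        pop_var = y.var()
        var = n_case * (n - n_case) / max(n - 1, 1) * pop_var
        z = (s - mu) / np.sqrt(var) if var > 0 else 0.0
        best = max(best, z)
    return float(best)


# --- vectorized permutation kernels --------------------------------------
# Each kernel evaluates its statistic for a batch of candidate case-label
# assignments (mask matrix of shape (B, n_samples)) in one pass.


def _burden_batch(d: np.ndarray, masks: np.ndarray) -> np.ndarray:
    y = d.sum(axis=0).astype(float)
    return masks @ y


def _uniq_batch(d: np.ndarray, masks: np.ndarray) -> np.ndarray:
    case_counts = masks.astype(float) @ d.T  # (B, J)
    ctrl_counts = d.sum(axis=1)[None, :] - case_counts
    return (case_counts * (ctrl_counts == 0)).sum(axis=1)


def _frqwgt_batch(d: np.ndarray, missing: np.ndarray, masks: np.ndarray) -> np.ndarray:
    masks_f = masks.astype(float)
    case_counts = masks_f @ d.T  # (B, J)
    ctrl_counts = d.sum(axis=1)[None, :] - case_counts
    nonmiss = (~missing).astype(float)
    n_ctrl = nonmiss.sum(axis=1)[None, :] - masks_f @ nonmiss.T
    q = (ctrl_counts + 1.0) / (2.0 * n_ctrl + 2.0)
    w = 1.0 / np.sqrt(np.maximum(n_ctrl, 1.0) * q * (1.0 - q))
    return (w * case_counts).sum(axis=1)


def _vt_batch(d: np.ndarray, mafs: np.ndarray, masks: np.ndarray) -> np.ndarray:
    thresholds = np.unique(mafs)
    n = d.shape[1]
    n_case = masks[0].sum()
    Y = np.vstack([d[mafs <= t].sum(axis=0) for t in thresholds]).astype(float)  # (T, n)
    S = masks @ Y.T  # (B, T)
    mu = n_case * Y.mean(axis=1)
    var = n_case * (n - n_case) / max(n - 1, 1) * Y.var(axis=1)
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (S - mu[None, :]) / sd[None, :], 0.0)
    return Z.max(axis=1)


@dataclass
class GeneTest:
    """One gene's qualifying variants, bound to a statistic."""

    name: str
    dosages: np.ndarray  # (J, n) cleaned, missing -> 0
    missing: np.ndarray  # (J, n) bool
    mafs: np.ndarray

    @classmethod
    def from_dosages(cls, name: str, dosages: np.ndarray, mafs: np.ndarray) -> "GeneTest":
        d = np.asarray(dosages)
        return cls(name, _clean(d), d == MISSING, np.asarray(mafs, float))

    def observed(self, case_mask: np.ndarray) -> float:
        return self.batch(np.asarray(case_mask, bool)[None, :])[0]

    def batch(self, masks: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class BurdenTest(GeneTest):
    def batch(self, masks: np.ndarray) -> np.ndarray:
        return _burden_batch(self.dosages, masks)


class FrqwgtTest(GeneTest):
    def batch(self, masks: np.ndarray) -> np.ndarray:
        return _frqwgt_batch(self.dosages, self.missing, masks)


class VtTest(GeneTest):
    def batch(self, masks: np.ndarray) -> np.ndarray:
        return _vt_batch(self.dosages, self.mafs, masks)


class UniqTest(GeneTest):
    def batch(self, masks: np.ndarray) -> np.ndarray:
        return _uniq_batch(self.dosages, masks)


_TEST_CLASSES = {
    "burden": BurdenTest,
    "frqwgt": FrqwgtTest,
    "vt": VtTest,
    "uniq": UniqTest,
}


def make_test(name: str, dosages: np.ndarray, mafs: np.ndarray) -> GeneTest:
    return _TEST_CLASSES[name].from_dosages(name, dosages, mafs)


def adaptive_permutation(
    test: GeneTest,
    case_mask: np.ndarray,
    r_stop: int = 10,
    b_max: int = 100_000,
    seed: int | np.random.Generator = 0,
    batch_size: int = 200,
) -> tuple[float, int]:
    """Adaptive label-permutation empirical p-value.

    Case/control labels are permuted in batches; once the permuted
    statistic has met or exceeded the observed one ``r_stop`` times the
    procedure stops. Returns ``p = (r + 1)/(b + 1)`` and ``b``, the
    permutations actually performed.
    """
    if not 1 <= r_stop <= b_max:
        raise DataError("need b_max >= r_stop >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    case_mask = np.asarray(case_mask, bool)
    n = len(case_mask)
    n_case = int(case_mask.sum())
    observed = test.observed(case_mask)
    r = 0
    b = 0
    while b < b_max:
        size = min(batch_size, b_max - b)
        masks = np.zeros((size, n), dtype=bool)
        for i in range(size):
            masks[i, rng.permutation(n)[:n_case]] = True
        stats = test.batch(masks)
        r += int((stats >= observed - 1e-12).sum())
        b += size
        if r >= r_stop:
            break
    return (r + 1.0) / (b + 1.0), b


def gene_carrier_fisher(
    dosages: np.ndarray, case_mask: np.ndarray
) -> tuple[float, float, float, float, bool]:
    """Carrier-based 2x2 statistics for one gene (or gene set).

    A carrier holds at least one qualifying minor allele. Returns
    ``(carrier freq cases %, carrier freq controls %, odds ratio,
    two-sided Fisher p, continuity_flagged)``. The OR is the
    cross-product ratio; with a zero cell, 0.5 is added to every cell
    (Haldane correction) and the result is flagged.
    """
    d = _clean(dosages)
    case_mask = np.asarray(case_mask, bool)
    carrier = (d > 0).any(axis=0)
    a = int(carrier[case_mask].sum())
    b = int(case_mask.sum()) - a
    c = int(carrier[~case_mask].sum())
    dd = int((~case_mask).sum()) - c
    return carrier_table_stats(a, b, c, dd)


def carrier_table_stats(
    a: int, b: int, c: int, d: int
) -> tuple[float, float, float, float, bool]:
    """Statistics for a carrier table (a,b = case carriers/non; c,d = control)."""
    n_case, n_ctrl = a + b, c + d
    freq_case = 100.0 * a / n_case if n_case else 0.0
    freq_ctrl = 100.0 * c / n_ctrl if n_ctrl else 0.0
    flagged = 0 in (a, b, c, d)
    if flagged:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return freq_case, freq_ctrl, float(orr), p, flagged


def reconstruct_count(pct: float, n: int, decimals: int = 2) -> int:
    """Invert a rounded percentage back to the unique integer count.

    Finds the unique ``k`` in ``[0, n]`` with
    ``round(100 * k / n, decimals) == pct``; raises :class:`DataError`
    if no or multiple candidates exist.
    """
    hits = [k for k in range(n + 1) if round(100.0 * k / n, decimals) == round(pct, decimals)]
    if len(hits) != 1:
        raise DataError(
            f"{pct}% of {n} maps to {len(hits)} candidate counts: {hits[:5]}"
        )
    return hits[0]


@dataclass
class GeneTestResult:
    """Per-gene association results in the shape of a summary-table row."""

    gene: str
    stratum: str
    vclass: str
    n_variants: int
    p_values: dict[str, float]
    permutations: dict[str, int]
    carrier_freq_cases: float
    carrier_freq_controls: float
    odds_ratio: float
    fisher_p: float
    or_flagged: bool


def select_variants(
    gm: GenotypeMatrix,
    stratum: str = "rare",
    vclass: str = "non-silent",
    gene: str | None = None,
) -> np.ndarray:
    """Indices of qualifying variants: polymorphic, right class/stratum."""
    if stratum not in STRATA:
        raise DataError(f"unknown stratum {stratum!r}")
    lo, hi = STRATA[stratum]
    keep = (gm.maf > lo) & (gm.maf < hi)
    keep &= np.array([c == vclass for c in gm.variants.vclass], dtype=bool)
    if gene is not None:
        keep &= np.array([g == gene for g in gm.variants.gene], dtype=bool)
    return np.flatnonzero(keep)


def run_gene_tests(
    gm: GenotypeMatrix,
    cohort: Cohort,
    stratum: str = "rare",
    vclass: str = "non-silent",
    tests: tuple[str, ...] = TESTS,
    r_stop: int = 10,
    b_max: int = 100_000,
    seed: int = 0,
    genes: list[str] | None = None,
) -> list[GeneTestResult]:
    """Run the selected burden tests for every gene with qualifying variants."""
    if genes is None:
        genes = sorted(set(gm.variants.gene))
    case_mask = cohort.is_case
    rng = np.random.default_rng(seed)
    results = []
    for gene in genes:
        idx = select_variants(gm, stratum, vclass, gene)
        if len(idx) == 0:
            logger.info("gene %s: no qualifying variants, skipped", gene)
            continue
        d = gm.dosage[idx]
        mafs = gm.maf[idx]
        pvals: dict[str, float] = {}
        perms: dict[str, int] = {}
        for t in tests:
            gt = make_test(t, d, mafs)
            pvals[t], perms[t] = adaptive_permutation(
                gt, case_mask, r_stop=r_stop, b_max=b_max, seed=rng
            )
        fc, fx, orr, fp, flag = gene_carrier_fisher(d, case_mask)
        results.append(
            GeneTestResult(
                gene, stratum, vclass, len(idx), pvals, perms, fc, fx, orr, fp, flag
            )
        )
    return results
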