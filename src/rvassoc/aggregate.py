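"""Gene-set aggregation of qualifying variants.

Tabulates, per gene and in total, the minor-allele counts of all
qualifying variants, of group-exclusive variants (zero minor alleles in
the other group), and the number of distinctive variant loci per group
(sites where the group carries at least one minor allele). Burden excess
is tested with two-sided Fisher's exact tests on allele counts against
total chromosomes, and summarized by the normalized per-capita
distinctive-loci ratio R.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import fisher_exact

from .burden import STRATA, _clean, carrier_table_stats
from .core import Cohort, DataError, GenotypeMatrix


@dataclass
class AggregateTable:
    """Per-gene and total qualifying-variant counts by group."""

    genes: list[str]
    case_alleles: np.ndarray
    control_alleles: np.ndarray
    case_exclusive: np.ndarray
    control_exclusive: np.ndarray
    case_loci: np.ndarray
    control_loci: np.ndarray
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        k = len(self.genes)
        for name in (
            "case_alleles", "control_alleles", "case_exclusive",
            "control_exclusive", "case_loci", "control_loci",
        ):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.shape != (k,):
                raise DataError(f"{name} has wrong length")
            setattr(self, name, arr)
        if (self.case_exclusive > self.case_alleles).any() or (
            self.control_exclusive > self.control_alleles
        ).any():
            raise DataError("exclusive counts exceed all-variant counts")
        if (self.case_loci > self.case_alleles).any() or (
            self.control_loci > self.control_alleles
        ).any():
            raise DataError("loci counts exceed allele counts")

    @property
    def total_alleles_cases(self) -> int:
        return 2 * self.n_cases

    @property
    def total_alleles_controls(self) -> int:
        return 2 * self.n_controls

    def totals(self) -> dict[str, int]:
        return {
            "case_alleles": int(self.case_alleles.sum()),
            "control_alleles": int(self.control_alleles.sum()),
            "case_exclusive": int(self.case_exclusive.sum()),
            "control_exclusive": int(self.control_exclusive.sum()),
            "case_loci": int(self.case_loci.sum()),
            "control_loci": int(self.control_loci.sum()),
        }

    @classmethod
    def from_counts(
        cls,
        genes: list[str],
        rows: list[tuple[int, int, int, int, int, int]],
        n_cases: int,
        n_controls: int,
    ) -> "AggregateTable":
        """Build a table from per-gene count rows (ordered as Totals keys)."""
        cols = list(zip(*rows)) if rows else [[]] * 6
        return cls(genes, *[np.array(c) for c in cols], n_cases, n_controls)


@dataclass
class BurdenTestReport:
    """Fisher tests and the normalized loci ratio for one aggregate table."""

    all_or: float
    all_p: float
    exclusive_or: float
    exclusive_p: float
    carrier_freq_cases: float
    carrier_freq_controls: float
    carrier_or: float
    carrier_p: float
    loci_ratio: float
    flags: dict[str, bool] = field(default_factory=dict)


def aggregate_counts(
    gm: GenotypeMatrix,
    gene_set: list[str],
    cohort: Cohort,
    stratum: str = "rare",
    vclass: str = "non-silent",
) -> AggregateTable:
    """Tabulate qualifying variant alleles and loci for a gene set."""
    if not gene_set:
        raise DataError("gene_set must be non-empty")
    known = set(gm.variants.gene)
    unknown = sorted(set(gene_set) - known)
    if unknown and gm.n_variants > 0:
        raise DataError(f"unknown genes: {', '.join(unknown)}")
    if stratum not in STRATA:
        raise DataError(f"unknown stratum {stratum!r}")
    lo, hi = STRATA[stratum]
    case = cohort.is_case
    d = _clean(gm.dosage)
    qual = (gm.maf > lo) & (gm.maf < hi)
    qual &= np.array([c == vclass for c in gm.variants.vclass], dtype=bool)
    rows = []
    for gene in gene_set:
        in_gene = qual & np.array([g == gene for g in gm.variants.gene], dtype=bool)
        dg = d[in_gene]
        ca = dg[:, case].sum(axis=1)
        co = dg[:, ~case].sum(axis=1)
        rows.append((
            int(ca.sum()),
            int(co.sum()),
            int(ca[co == 0].sum()),
            int(co[ca == 0].sum()),
            int((ca > 0).sum()),
            int((co > 0).sum()),
        ))
    return AggregateTable.from_counts(
        list(gene_set), rows, cohort.n_cases, cohort.n_controls
    )


def fisher_allele_burden(
    table: AggregateTable, which: str = "all"
) -> tuple[float, float, bool]:
    """Two-sided Fisher test of allele counts against total chromosomes.

    ``which`` selects the all-variant or exclusive-variant totals. The
    2x2 table is ``(count, 2N - count)`` per group; returns
    ``(odds ratio, p, continuity_flagged)``.
    """
    t = table.totals()
    if which == "all":
        a, c = t["case_alleles"], t["control_alleles"]
    elif which == "exclusive":
        a, c = t["case_exclusive"], t["control_exclusive"]
    else:
        raise DataError(f"which must be 'all' or 'exclusive', got {which!r}")
    b = table.total_alleles_cases - a
    d = table.total_alleles_controls - c
    flagged = 0 in (a, b, c, d)
    if flagged:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return float(orr), p, flagged


def carrier_burden(
    gm: GenotypeMatrix,
    gene_set: list[str],
    cohort: Cohort,
    stratum: str = "rare",
    vclass: str = "non-silent",
) -> tuple[float, float, float, float, bool]:
    """Carrier-level Fisher test across the whole gene set.

    A carrier holds >= 1 qualifying minor allele in any gene of the set.
    Returns ``(freq cases %, freq controls %, OR, two-sided p, flagged)``.
    """
    lo, hi = STRATA[stratum]
    qual = (gm.maf > lo) & (gm.maf < hi)
    qual &= np.array([c == vclass for c in gm.variants.vclass], dtype=bool)
    qual &= np.array([g in set(gene_set) for g in gm.variants.gene], dtype=bool)
    d = _clean(gm.dosage[qual])
    carrier = (d > 0).any(axis=0) if d.size else np.zeros(gm.n_samples, bool)
    case = cohort.is_case
    a = int(carrier[case].sum())
    c = int(carrier[~case].sum())
    return carrier_table_stats(a, cohort.n_cases - a, c, cohort.n_controls - c)


def normalized_loci_ratio(table: AggregateTable) -> float:
    """Per-capita distinctive-loci ratio R = (case loci / N_case) / (control loci / N_control)."""
    t = table.totals()
    if t["control_loci"] == 0:
        return float("nan")
    return (t["case_loci"] / table.n_cases) / (t["control_loci"] / table.n_controls)


def burden_report(table: AggregateTable, carrier: tuple[float, float, float, float, bool]) -> BurdenTestReport:
    """Assemble the full Fisher/R summary for one aggregate table."""
    all_or, all_p, f1 = fisher_allele_burden(table, "all")
    ex_or, ex_p, f2 = fisher_allele_burden(table, "exclusive")
    fc, fx, c_or, c_p, f3 = carrier
    return BurdenTestReport(
        all_or, all_p, ex_or, ex_p, fc, fx, c_or, c_p,
        normalized_loci_ratio(table),
        flags={"all": f1, "exclusive": f2, "carrier": f3},
    )
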