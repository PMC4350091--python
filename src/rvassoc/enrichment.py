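"""Pathway over-representation analysis of nominally associated genes.

Genes are flagged nominal when any of their empirical gene-test p-values
falls below 0.05. Each pathway with more than ``min_genes`` sequenced
members is tested for enrichment of nominal genes with the upper-tail
hypergeometric test, and the resulting p-values are adjusted with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .core import DataError


@dataclass
class GeneUniverse:
    """Sequenced gene universe, nominal subset and pathway definitions."""

    universe: set[str]
    nominal: set[str]
    pathways: dict[str, set[str]]

    def __post_init__(self) -> None:
        extra = self.nominal - self.universe
        if extra:
            raise DataError(f"nominal genes outside universe: {sorted(extra)[:5]}")
        for name, members in self.pathways.items():
            out = members - self.universe
            if out:
                raise DataError(
                    f"pathway {name!r} has genes outside universe: {sorted(out)[:5]}"
                )


@dataclass
class EnrichmentRow:
    pathway: str
    n_sequenced: int
    n_nominal: int
    p: float
    fdr: float


def flag_nominal(
    gene_pvalues: dict[str, dict[str, float]], alpha: float = 0.05
) -> set[str]:
    """Genes whose smallest empirical p across tests is strictly < alpha."""
    return {
        gene
        for gene, tests in gene_pvalues.items()
        if tests and min(tests.values()) < alpha
    }


def hypergeom_enrichment(universe: GeneUniverse, pathway: set[str]) -> float:
    """Upper-tail hypergeometric p for nominal-gene overlap with a pathway.

    ``P(X >= k)`` where X counts nominal genes among ``len(pathway)``
    draws from a universe of ``N`` genes containing ``len(nominal)``
    nominal ones, and ``k`` is the observed overlap.
    """
    if not pathway <= universe.universe:
        raise DataError("pathway not contained in universe")
    n_draws = len(pathway)
    if n_draws == 0:
        return 1.0
    k = len(pathway & universe.nominal)
    return float(
        hypergeom.sf(k - 1, len(universe.universe), len(universe.nominal), n_draws)
    )


def bh_fdr(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.empty(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def enrichment_report(
    universe: GeneUniverse, min_genes: int = 10
) -> list[EnrichmentRow]:
    """Enrichment rows for pathways with more than ``min_genes`` members.

    Rows are sorted by p-value; FDR is computed across the analyzed
    pathways only.
    """
    analyzed = {
        name: members
        for name, members in universe.pathways.items()
        if len(members) > min_genes
    }
    names = sorted(analyzed)
    ps = [hypergeom_enrichment(universe, analyzed[n]) for n in names]
    fdrs = bh_fdr(ps)
    rows = [
        EnrichmentRow(
            n,
            len(analyzed[n]),
            len(analyzed[n] & universe.nominal),
            p,
            float(q),
        )
        for n, p, q in zip(names, ps, fdrs)
    ]
    rows.sort(key=lambda r: (r.p, r.pathway))
    return rows
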