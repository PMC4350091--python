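"""Synthetic case-control cohort generator.

Produces cohorts with the statistical structure the downstream analysis
assumes: a rare-skewed site-frequency spectrum, Hardy-Weinberg genotypes,
a logistic disease model on carriage of rare non-silent alleles in a
designated risk gene set, and optional read-level evidence for the
calling stage. Ground truth (site frequencies, genotypes, causal genes)
is returned alongside so every stage can be validated.

Sites are simulated independently: no linkage disequilibrium, no
population structure, no indels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist

from .core import (
    Cohort,
    ConfigError,
    GenotypeMatrix,
    SiteReads,
    TruthTable,
    VariantTable,
)


@dataclass
class MafSpectrum:
    """Minor-allele-frequency distribution for simulated sites.

    A Beta(a, b) distribution truncated to ``(0, max_maf]``. The default
    ``a = 0.04, b = 1`` places ~85.5% of mass below 0.01 and ~91.2%
    below 0.05, matching a heavily rare-skewed targeted-sequencing
    spectrum. Setting ``fixed`` collapses the spectrum to a point mass.
    """

    a: float = 0.04
    b: float = 1.0
    max_maf: float = 0.5
    fixed: float | None = None

    def __post_init__(self) -> None:
        if self.fixed is not None:
            if not 0.0 < self.fixed <= 0.5:
                raise ConfigError("fixed MAF must be in (0, 0.5]")
            return
        if self.a <= 0 or self.b <= 0:
            raise ConfigError("Beta spectrum parameters must be positive")
        if not 0.0 < self.max_maf <= 0.5:
            raise ConfigError("max_maf must be in (0, 0.5]")

    def fraction_below(self, x: float) -> float:
        """Expected fraction of sites with MAF below ``x``."""
        if self.fixed is not None:
            return float(self.fixed < x)
        cap = beta_dist.cdf(self.max_maf, self.a, self.b)
        return float(beta_dist.cdf(min(x, self.max_maf), self.a, self.b) / cap)


@dataclass
class GeneSpec:
    """One simulated gene: site count and functional-class mix."""

    name: str
    n_sites: int
    class_mix: tuple[float, float, float] = (0.6, 0.25, 0.15)  # non-silent, silent, UTR

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ConfigError(f"gene {self.name}: negative site count")
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or min(self.class_mix) < 0:
            raise ConfigError(f"gene {self.name}: class mix must sum to 1")


@dataclass
class SimulationConfig:
    """Full parameterization of one synthetic cohort."""

    n_cases: int = 757
    n_controls: int = 709
    genes: list[GeneSpec] = field(default_factory=list)
    risk_gene_set: set[str] = field(default_factory=set)
    carrier_odds_ratio: float = 1.0
    maf_spectrum: MafSpectrum = field(default_factory=MafSpectrum)
    mean_depth: float = 30.0
    base_error_rate: float = 0.005
    age_range: tuple[int, int] = (22, 45)
    baseline_log_odds: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigError("need at least one case and one control")
        if self.carrier_odds_ratio <= 0:
            raise ConfigError("carrier_odds_ratio must be positive")
        if not 0.0 < self.base_error_rate < 0.5:
            raise ConfigError("base_error_rate must be in (0, 0.5)")
        if self.age_range[0] > self.age_range[1]:
            raise ConfigError("age_range reversed")
        names = {g.name for g in self.genes}
        if len(names) != len(self.genes):
            raise ConfigError("duplicate gene names")
        unknown = self.risk_gene_set - names
        if unknown:
            raise ConfigError(
                f"risk genes not simulated: {', '.join(sorted(unknown))}"
            )


@dataclass
class SimulatedCohort:
    """Bundle of everything the simulator knows about one cohort."""

    genotypes: GenotypeMatrix
    cohort: Cohort
    truth: TruthTable
    site_reads: list[SiteReads] | None = None


def default_genes(
    n_genes: int = 20, sites_per_gene: int = 10, n_risk: int = 5
) -> tuple[list[GeneSpec], set[str]]:
    """Convenience gene panel: ``GENE000..`` with the first genes causal."""
    genes = [GeneSpec(f"GENE{i:03d}", sites_per_gene) for i in range(n_genes)]
    risk = {g.name for g in genes[:n_risk]}
    return genes, risk


def simulate_spectrum(
    n_sites: int, spectrum: MafSpectrum | None = None, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n_sites`` true minor-allele frequencies from the spectrum."""
    if n_sites < 0:
        raise ConfigError("n_sites must be non-negative")
    spectrum = spectrum or MafSpectrum()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n_sites == 0:
        return np.empty(0)
    if spectrum.fixed is not None:
        return np.full(n_sites, spectrum.fixed)
    # inverse-CDF sampling from the truncated Beta
    cap = beta_dist.cdf(spectrum.max_maf, spectrum.a, spectrum.b)
    u = rng.uniform(0.0, cap, size=n_sites)
    maf = beta_dist.ppf(u, spectrum.a, spectrum.b)
    return np.clip(maf, np.finfo(float).tiny, spectrum.max_maf)


def _hwe_genotypes(
    maf: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_sites, n) genotypes: two independent allele draws per site."""
    p = maf[:, None]
    return (
        (rng.random((len(maf), n)) < p).astype(np.int8)
        + (rng.random((len(maf), n)) < p).astype(np.int8)
    )


def simulate_cohort(
    config: SimulationConfig, include_reads: bool = True
) -> SimulatedCohort:
    """Simulate a full cohort under the configured disease model.

    Genotypes are Hardy-Weinberg draws at each site's true MAF.
    Disease status follows a logistic model on the indicator of carrying
    at least one rare (true MAF < 1%) non-silent allele in a risk gene:
    ``logit P(case) = baseline_log_odds + log(carrier_odds_ratio) * carrier``.
    Individuals are drawn and assigned until the case and control quotas
    are filled (rejection sampling), which reproduces case-control
    ascertainment exactly.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.genes or default_genes()[0]

    # --- site panel -------------------------------------------------------
    gene_names: list[str] = []
    vclasses: list[str] = []
    classes = np.array(["non-silent", "silent", "UTR"])
    for g in genes:
        gene_names.extend([g.name] * g.n_sites)
        vclasses.extend(rng.choice(classes, size=g.n_sites, p=g.class_mix))
    n_sites = len(gene_names)
    maf = simulate_spectrum(n_sites, config.maf_spectrum, rng)
    risk_site = np.array(
        [
            (gene_names[j] in config.risk_gene_set)
            and vclasses[j] == "non-silent"
            and maf[j] < 0.01
            for j in range(n_sites)
        ]
    )

    # --- rejection sampling of cases and controls -------------------------
    n_total = config.n_cases + config.n_controls
    log_or = math.log(config.carrier_odds_ratio)
    geno_cols: list[np.ndarray] = []
    labels: list[bool] = []
    need_cases, need_controls = config.n_cases, config.n_controls
    while need_cases > 0 or need_controls > 0:
        chunk = max(64, need_cases + need_controls)
        g = _hwe_genotypes(maf, chunk, rng)
        carrier = (g[risk_site] > 0).any(axis=0) if risk_site.any() else np.zeros(chunk, bool)
        logit = config.baseline_log_odds + log_or * carrier
        p_case = 1.0 / (1.0 + np.exp(-logit))
        is_case = rng.random(chunk) < p_case
        for k in range(chunk):
            if is_case[k] and need_cases > 0:
                geno_cols.append(g[:, k])
                labels.append(True)
                need_cases -= 1
            elif not is_case[k] and need_controls > 0:
                geno_cols.append(g[:, k])
                labels.append(False)
                need_controls -= 1

    order = np.argsort(~np.array(labels), kind="stable")  # cases first
    genotypes = np.column_stack([geno_cols[i] for i in order]).astype(np.int8)
    is_case = np.array(labels)[order]
    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n_total)
    ids = [
        f"{'CASE' if c else 'CTRL'}{i:05d}"
        for i, c in enumerate(is_case)
    ]
    cohort = Cohort(ids, is_case, ages.astype(float))

    table = VariantTable(
        ["chr1"] * n_sites,
        np.arange(1, n_sites + 1) * 1000,
        ["A"] * n_sites,
        ["G"] * n_sites,
        gene_names,
        vclasses,
    )
    truth = TruthTable(maf, genotypes, set(config.risk_gene_set))
    gm = GenotypeMatrix(table, ids, genotypes.copy())

    reads = None
    if include_reads:
        reads = simulate_reads(
            truth,
            config.mean_depth,
            config.base_error_rate,
            rng,
            variants=table,
        )
        gm.depth = np.vstack([s.depth for s in reads]) if reads else None
    return SimulatedCohort(gm, cohort, truth, reads)


def simulate_reads(
    truth: TruthTable,
    mean_depth: float,
    base_error_rate: float,
    seed: int | np.random.Generator = 0,
    variants: VariantTable | None = None,
) -> list[SiteReads]:
    """Generate allele-supporting read evidence from true genotypes.

    Depth is Poisson(``mean_depth``) per sample per site. Each read
    derives from one of the two true alleles (heterozygotes: fair coin);
    a sequencing error (probability ``base_error_rate``) substitutes one
    of the three other bases uniformly, so a read supports the wrong
    modeled allele with probability ``e/3`` and a dropped third base with
    ``2e/3``. Strands are fair coin flips; every read carries the Phred
    quality corresponding to ``base_error_rate``.
    """
    if mean_depth <= 0:
        raise ConfigError("mean_depth must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    e = base_error_rate
    qual = int(round(-10.0 * math.log10(e))) if e > 0 else 60
    n_sites, n_samples = truth.genotypes.shape
    # P(read supports ref / alt | genotype)
    p_alt = {0: e / 3.0, 1: 0.5 * (1 - e) + 0.5 * e / 3.0, 2: 1.0 - e}
    p_ref = {0: 1.0 - e, 1: 0.5 * (1 - e) + 0.5 * e / 3.0, 2: e / 3.0}
    out: list[SiteReads] = []
    for j in range(n_sites):
        depth = rng.poisson(mean_depth, size=n_samples)
        g = truth.genotypes[j]
        pr = np.array([p_ref[int(x)] for x in g])
        pa = np.array([p_alt[int(x)] for x in g])
        n_ref = rng.binomial(depth, pr)
        # remaining reads split between alt and the dropped third bases
        rest = depth - n_ref
        with np.errstate(invalid="ignore", divide="ignore"):
            pa_given = np.where(rest > 0, pa / np.maximum(1.0 - pr, 1e-300), 0.0)
        n_alt = rng.binomial(rest, np.clip(pa_given, 0.0, 1.0))
        ref_fwd = rng.binomial(n_ref, 0.5)
        alt_fwd = rng.binomial(n_alt, 0.5)
        out.append(
            SiteReads(
                chrom=variants.chrom[j] if variants else "chr1",
                pos=int(variants.pos[j]) if variants else (j + 1) * 1000,
                ref=variants.ref[j] if variants else "A",
                alt=variants.alt[j] if variants else "G",
                ref_fwd=ref_fwd,
                ref_rev=n_ref - ref_fwd,
                alt_fwd=alt_fwd,
                alt_rev=n_alt - alt_fwd,
                ref_quals=[np.full(int(k), qual, dtype=np.int64) for k in n_ref],
                alt_quals=[np.full(int(k), qual, dtype=np.int64) for k in n_alt],
            )
        )
    return out
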