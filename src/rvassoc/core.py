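"""Shared domain types for the rare-variant association pipeline.

Conventions used throughout the package:

* genotypes are minor-allele dosages in ``{0, 1, 2}``; ``-1`` marks a
  missing call,
* coordinates are 1-based inclusive (VCF convention),
* minor-allele frequency (MAF) lives in ``[0, 0.5]`` and is computed on
  the combined cohort unless stated otherwise,
* variant functional classes are ``non-silent``, ``silent`` and ``UTR``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING: int = -1

VARIANT_CLASSES = ("non-silent", "silent", "UTR")

#: MAF stratum boundaries: rare < RARE_MAF <= low-frequency < LOWFREQ_MAF <= common
RARE_MAF: float = 0.01
LOWFREQ_MAF: float = 0.05


class DataError(ValueError):
    """Raised when input data violate a documented contract."""


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass
class Cohort:
    """Case-control cohort: sample identifiers, phenotype and age.

    ``is_case`` is a boolean array aligned with ``sample_ids``; ``age`` is
    in years. Sample ids must be unique.
    """

    sample_ids: list[str]
    is_case: np.ndarray
    age: np.ndarray

    def __post_init__(self) -> None:
        self.is_case = np.asarray(self.is_case, dtype=bool)
        self.age = np.asarray(self.age, dtype=float)
        n = len(self.sample_ids)
        if self.is_case.shape != (n,) or self.age.shape != (n,):
            raise DataError("cohort fields must share one length")
        if len(set(self.sample_ids)) != n:
            seen: set[str] = set()
            dup = sorted({s for s in self.sample_ids if s in seen or seen.add(s)})
            raise DataError(f"duplicate sample ids: {', '.join(dup)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return self.n_samples - self.n_cases

    def subset(self, idx: np.ndarray) -> "Cohort":
        idx = np.asarray(idx)
        return Cohort(
            [self.sample_ids[i] for i in idx], self.is_case[idx], self.age[idx]
        )


@dataclass
class VariantTable:
    """Per-variant annotation columns, aligned with a genotype matrix."""

    chrom: list[str]
    pos: np.ndarray
    ref: list[str]
    alt: list[str]
    gene: list[str]
    vclass: list[str]

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n = len(self.chrom)
        for name in ("ref", "alt", "gene", "vclass"):
            if len(getattr(self, name)) != n:
                raise DataError(f"annotation column {name!r} has wrong length")
        bad = sorted(set(self.vclass) - set(VARIANT_CLASSES))
        if bad:
            raise DataError(f"unknown variant classes: {', '.join(bad)}")

    @property
    def n_variants(self) -> int:
        return len(self.chrom)

    def variant_ids(self) -> list[str]:
        return [
            f"{c}:{p}:{r}:{a}"
            for c, p, r, a in zip(self.chrom, self.pos, self.ref, self.alt)
        ]


@dataclass
class GenotypeMatrix:
    """Sites x samples minor-allele dosage matrix with site annotation.

    ``dosage`` has shape ``(n_variants, n_samples)`` with entries in
    ``{0, 1, 2, MISSING}``. ``maf`` is the combined-cohort minor-allele
    frequency computed over non-missing calls; it can be recomputed with
    :meth:`recompute_maf` after subsetting samples.
    """

    variants: VariantTable
    sample_ids: list[str]
    dosage: np.ndarray
    maf: np.ndarray | None = None
    depth: np.ndarray | None = None  # per variant x sample read depth, optional

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        shape = (self.variants.n_variants, len(self.sample_ids))
        if self.dosage.shape != shape:
            raise DataError(
                f"dosage shape {self.dosage.shape} != (variants, samples) {shape}"
            )
        valid = np.isin(self.dosage, (MISSING, 0, 1, 2))
        if not valid.all():
            raise DataError("dosages must be in {0, 1, 2} or missing")
        if self.maf is None:
            self.maf = self.recompute_maf()
        else:
            self.maf = np.asarray(self.maf, dtype=float)
            if self.maf.shape != (shape[0],):
                raise DataError("maf has wrong length")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != shape:
                raise DataError("depth has wrong shape")

    @property
    def n_variants(self) -> int:
        return self.variants.n_variants

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def recompute_maf(self) -> np.ndarray:
        """Minor-allele frequency per site over non-missing calls."""
        d = self.dosage
        obs = d != MISSING
        alleles = 2 * obs.sum(axis=1)
        counts = np.where(obs, d, 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            af = np.where(alleles > 0, counts / np.maximum(alleles, 1), 0.0)
        return np.minimum(af, 1.0 - af)

    def subset_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        v = self.variants
        sub = VariantTable(
            [v.chrom[i] for i in idx],
            v.pos[idx],
            [v.ref[i] for i in idx],
            [v.alt[i] for i in idx],
            [v.gene[i] for i in idx],
            [v.vclass[i] for i in idx],
        )
        return GenotypeMatrix(
            sub,
            self.sample_ids,
            self.dosage[idx],
            self.maf[idx],
            None if self.depth is None else self.depth[idx],
        )


@dataclass
class SiteReads:
    """Allele-supporting read evidence at one site, per sample.

    Counts are split by strand; base qualities are Phred-scaled integers,
    one array per sample for ref- and alt-supporting reads respectively.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ref_fwd: np.ndarray
    ref_rev: np.ndarray
    alt_fwd: np.ndarray
    alt_rev: np.ndarray
    ref_quals: list[np.ndarray]
    alt_quals: list[np.ndarray]
    mean_mapq: float = 60.0

    def __post_init__(self) -> None:
        for name in ("ref_fwd", "ref_rev", "alt_fwd", "alt_rev"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if (arr < 0).any():
                raise DataError(f"{name} contains negative counts")
            setattr(self, name, arr)
        n = len(self.ref_fwd)
        if not (
            len(self.ref_rev) == len(self.alt_fwd) == len(self.alt_rev) == n
            and len(self.ref_quals) == len(self.alt_quals) == n
        ):
            raise DataError("per-sample fields must share one length")
        for i in range(n):
            rq = np.asarray(self.ref_quals[i], dtype=np.int64)
            aq = np.asarray(self.alt_quals[i], dtype=np.int64)
            if len(rq) != self.ref_fwd[i] + self.ref_rev[i]:
                raise DataError(f"sample {i}: ref qualities do not match counts")
            if len(aq) != self.alt_fwd[i] + self.alt_rev[i]:
                raise DataError(f"sample {i}: alt qualities do not match counts")
            if (rq < 0).any() or (aq < 0).any():
                raise DataError("base qualities must be non-negative")
            self.ref_quals[i] = rq
            self.alt_quals[i] = aq

    @property
    def n_samples(self) -> int:
        return len(self.ref_fwd)

    @property
    def depth(self) -> np.ndarray:
        return self.ref_fwd + self.ref_rev + self.alt_fwd + self.alt_rev

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class TruthTable:
    """Ground truth emitted by the simulator."""

    site_maf: np.ndarray
    genotypes: np.ndarray  # (n_sites, n_samples), values in {0, 1, 2}
    causal_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.site_maf = np.asarray(self.site_maf, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise DataError("true genotypes must be in {0, 1, 2}")
        if self.genotypes.shape[0] != self.site_maf.shape[0]:
            raise DataError("site_maf and genotypes disagree on site count")
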