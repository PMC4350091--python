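import numpy as np
import pytest

from rvassoc.core import Cohort, GenotypeMatrix, SiteReads, VariantTable


def make_cohort(n_cases, n_controls, seed=0):
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    return Cohort(
        [f"S{i:04d}" for i in range(n)],
        np.r_[np.ones(n_cases, bool), np.zeros(n_controls, bool)],
        rng.integers(22, 46, size=n).astype(float),
    )


def make_matrix(dosage, genes=None, vclass=None, mafs=None, sample_ids=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    j, n = dosage.shape
    table = VariantTable(
        ["chr1"] * j,
        np.arange(1, j + 1) * 100,
        ["A"] * j,
        ["G"] * j,
        genes or ["GENE0"] * j,
        vclass or ["non-silent"] * j,
    )
    return GenotypeMatrix(
        table,
        sample_ids or [f"S{i:04d}" for i in range(n)],
        dosage,
        maf=None if mafs is None else np.asarray(mafs, float),
    )


def make_site_reads(ref_counts, alt_counts, ref_qual=30, alt_qual=30, seed=0):
    """Site with given per-sample ref/alt read counts, constant qualities."""
    rng = np.random.default_rng(seed)
    ref_counts = np.asarray(ref_counts, dtype=np.int64)
    alt_counts = np.asarray(alt_counts, dtype=np.int64)
    ref_fwd = rng.binomial(ref_counts, 0.5)
    alt_fwd = rng.binomial(alt_counts, 0.5)
    return SiteReads(
        "chr1", 100, "A", "G",
        ref_fwd, ref_counts - ref_fwd, alt_fwd, alt_counts - alt_fwd,
        [np.full(int(k), ref_qual, dtype=np.int64) for k in ref_counts],
        [np.full(int(k), alt_qual, dtype=np.int64) for k in alt_counts],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_cohort():
    return make_cohort(4, 4)
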