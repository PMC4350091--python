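"""End-to-end orchestration: call -> QC -> single-marker -> gene tests ->
gene-set aggregation -> pathway enrichment.

Every stage logs record counts in and out, all randomness derives from
the master seed, and a JSON manifest summarizing the run is written at
the end.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate as agg
from . import burden, enrichment, io, single_marker
from .config import PipelineConfig
from .core import ConfigError

logger = logging.getLogger(__name__)


def _stage_seed(master: int, stage: str) -> int:
    """Stable per-stage substream from the master seed."""
    import zlib

    ss = np.random.SeedSequence([master, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0])


def results_frame(results: list[burden.GeneTestResult]) -> pd.DataFrame:
    rows = [
        {
            "gene": r.gene,
            "stratum": r.stratum,
            "class": r.vclass,
            "n_variants": r.n_variants,
            **{t.upper(): r.p_values.get(t, float("nan")) for t in burden.TESTS},
            "carrier_freq_cases": r.carrier_freq_cases,
            "carrier_freq_controls": r.carrier_freq_controls,
            "OR": r.odds_ratio,
            "fisher_p": r.fisher_p,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def aggregate_frame(table: agg.AggregateTable) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "gene": table.genes,
            "case_alleles": table.case_alleles,
            "control_alleles": table.control_alleles,
            "case_exclusive": table.case_exclusive,
            "control_exclusive": table.control_exclusive,
            "case_loci": table.case_loci,
            "control_loci": table.control_loci,
        }
    )
    totals = table.totals()
    df.loc[len(df)] = {"gene": "Total", **totals}
    return df


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on the configured inputs; returns the manifest.

    Required ``config.paths``: ``vcf``, ``phenotypes``, ``annotation``,
    ``gene_sets``. Optional: ``reads`` (runs the calling stage first and
    replaces the VCF).
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": config.seed, "config": config.__dict__.copy()}
    manifest["config"]["paths"] = dict(config.paths)

    for key in ("vcf", "phenotypes", "annotation", "gene_sets"):
        if key not in config.paths:
            raise ConfigError(f"config.paths missing {key!r}")
        if not Path(config.paths[key]).exists():
            raise ConfigError(f"input path does not exist: {config.paths[key]}")

    def stage(name: str, **info) -> None:
        logger.info("stage %s: %s", name, info)
        manifest["stages"].append({"name": name, **info})

    # --- optional calling stage ------------------------------------------
    vcf_path = config.paths["vcf"]
    cohort = io.read_phenotypes(config.paths["phenotypes"])
    if "reads" in config.paths:
        from . import calling

        sites, sample_ids = io.read_site_reads(config.paths["reads"])
        if sample_ids != cohort.sample_ids:
            cohort = cohort.subset(
                np.array([cohort.sample_ids.index(s) for s in sample_ids])
            )
        gm_called, calls = calling.call_cohort(
            sites, cohort,
            lrt_threshold=config.lrt_threshold,
            min_depth=config.min_depth,
            alpha=config.filter_alpha,
        )
        vcf_path = out / "called.vcf"
        io.write_vcf(gm_called, vcf_path, [c for c in calls if c.called and c.passed_filters])
        stage("call", sites_in=len(sites), sites_called=gm_called.n_variants)

    # --- load & annotate --------------------------------------------------
    gm = io.read_vcf(vcf_path)
    gm = io.attach_annotation(gm, config.paths["annotation"])
    gm = io.orient_minor(gm)
    cohort = io.align_cohort(gm, cohort)
    stage("load", variants=gm.n_variants, samples=gm.n_samples,
          skipped_records=getattr(gm, "n_skipped", 0))

    # --- single-marker ----------------------------------------------------
    sm_results, removed = single_marker.run_single_marker(
        gm, cohort,
        min_maf=config.rare_maf,
        qc_alpha=config.qc_alpha,
        b=config.permutations,
        seed=_stage_seed(config.seed, "single_marker"),
    )
    pd.DataFrame(
        [
            {
                "variant": r.variant_id, "maf": r.maf, "beta": r.beta,
                "statistic": r.statistic, "asymptotic_p": r.asymptotic_p,
                "permutation_p": r.permutation_p, "n_permutations": r.n_permutations,
            }
            for r in sm_results
        ]
    ).to_csv(out / "single_marker.tsv", sep="\t", index=False)
    stage("single_marker", tested=len(sm_results), removed_qc=len(removed))

    # --- gene-based tests -------------------------------------------------
    gene_results: dict[tuple[str, str], list[burden.GeneTestResult]] = {}
    for stratum in ("rare", "rare_lowfreq"):
        for vclass in ("non-silent", "UTR"):
            res = burden.run_gene_tests(
                gm, cohort, stratum=stratum, vclass=vclass,
                r_stop=config.r_stop, b_max=config.b_max,
                seed=_stage_seed(config.seed, f"burden:{stratum}:{vclass}"),
            )
            gene_results[(stratum, vclass)] = res
            results_frame(res).to_csv(
                out / f"gene_tests.{stratum}.{vclass.replace('-', '')}.tsv",
                sep="\t", index=False,
            )
            stage(f"gene_tests:{stratum}:{vclass}", genes=len(res))

    # --- gene-set aggregation --------------------------------------------
    gene_sets = io.read_gene_sets(config.paths["gene_sets"])
    known = set(gm.variants.gene)
    agg_reports = {}
    for name, members in gene_sets.items():
        present = sorted(members & known)
        if not present:
            continue
        for stratum in ("rare", "rare_lowfreq"):
            table = agg.aggregate_counts(gm, present, cohort, stratum=stratum)
            carrier = agg.carrier_burden(gm, present, cohort, stratum=stratum)
            report = agg.burden_report(table, carrier)
            aggregate_frame(table).to_csv(
                out / f"aggregate.{name}.{stratum}.tsv", sep="\t", index=False
            )
            agg_reports[f"{name}:{stratum}"] = report.__dict__
    stage("aggregate", sets=len(gene_sets))

    # --- pathway enrichment ----------------------------------------------
    nominal = enrichment.flag_nominal(
        {
            r.gene: r.p_values
            for res in gene_results.values()
            for r in res
        },
        alpha=config.nominal_alpha,
    )
    universe = enrichment.GeneUniverse(
        known, nominal & known, {n: m & known for n, m in gene_sets.items()}
    )
    rows = enrichment.enrichment_report(universe, min_genes=config.min_pathway_genes)
    pd.DataFrame(
        [
            {
                "pathway": r.pathway, "n_sequenced": r.n_sequenced,
                "n_nominal": r.n_nominal, "p": r.p, "fdr": r.fdr,
            }
            for r in rows
        ]
    ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    stage("enrichment", pathways=len(rows), nominal_genes=len(nominal))

    manifest["aggregate_reports"] = agg_reports
    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
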