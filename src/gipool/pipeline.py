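"""End-to-end orchestration: simulate -> count -> qc -> score -> diff.

:func:`analyze_counts` is the in-memory core used by tests and scripts;
:func:`run_pipeline` wraps it with file IO, stage outputs and a manifest so
every stage can be re-run from written intermediates.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from gipool.core import BarcodeLibrary, FusedCountTable
from gipool.counting import count_fused_barcodes
from gipool.differential import (
    DELTA_EFFECT_CUTOFF,
    DELTA_Q_CUTOFF,
    call_differentials,
    cluster_conditions,
)
from gipool.genecalls import EFFECT_CUTOFF, Q_CUTOFF, combine_to_gene_level
from gipool.qc import CXY_THRESHOLD, LINKAGE_CUTOFF_BP, REPLICATE_R_CUTOFF, run_qc
from gipool.scoring import score_barcode_pairs
from gipool.simulate import SimulationConfig, simulate_pool, simulate_reads


@dataclass
class PipelineConfig:
    """Everything one run needs: inputs, thresholds, seed.

    Either ``simulation`` is set (synthetic run) or the three input TSV
    paths are. ``via_reads`` routes a synthetic run through FASTQ emission
    and re-counting instead of using the simulator's count table directly.
    """

    simulation: SimulationConfig | None = None
    counts_tsv: str | None = None
    samples_tsv: str | None = None
    library_tsv: str | None = None
    via_reads: bool = False
    error_rate: float = 0.0
    cxy_threshold: int = CXY_THRESHOLD
    linkage_cutoff_bp: int = LINKAGE_CUTOFF_BP
    replicate_r_cutoff: float = REPLICATE_R_CUTOFF
    q_cutoff: float = Q_CUTOFF
    effect_cutoff: float = EFFECT_CUTOFF
    delta_q_cutoff: float = DELTA_Q_CUTOFF
    delta_effect_cutoff: float = DELTA_EFFECT_CUTOFF
    seed: int = 0

    def validate(self) -> None:
        if self.simulation is None:
            missing = [
                name
                for name in ("counts_tsv", "samples_tsv", "library_tsv")
                if getattr(self, name) is None
            ]
            if missing:
                raise ValueError(f"no simulation config and missing inputs: {missing}")
        for name in (
            "cxy_threshold",
            "linkage_cutoff_bp",
            "replicate_r_cutoff",
            "q_cutoff",
            "effect_cutoff",
            "delta_q_cutoff",
            "delta_effect_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


def _validate_samples(samples: pd.DataFrame) -> None:
    bad = samples[samples["gen_pool"].isna()]
    if len(bad):
        raise ValueError(
            f"samples missing gen_pool: {list(bad['sample_id'])}"
        )


def analyze_counts(
    table: FusedCountTable,
    library: BarcodeLibrary,
    config: PipelineConfig | None = None,
) -> dict:
    """QC, score and call one count table; returns a dict of result tables."""
    config = config or PipelineConfig()
    _validate_samples(table.samples)
    classification = run_qc(
        table,
        library,
        cxy_threshold=config.cxy_threshold,
        linkage_cutoff_bp=config.linkage_cutoff_bp,
        replicate_r_cutoff=config.replicate_r_cutoff,
    )
    records, error_model = score_barcode_pairs(table, classification.frame)
    gene_table = combine_to_gene_level(
        records, q_cutoff=config.q_cutoff, effect_cutoff=config.effect_cutoff
    )
    results = {
        "classification": classification,
        "barcode_records": records,
        "error_model": error_model,
        "gene_table": gene_table,
    }
    if gene_table["condition"].nunique() >= 2:
        differentials, diff_summary = call_differentials(
            gene_table,
            q_cutoff=config.delta_q_cutoff,
            effect_cutoff=config.delta_effect_cutoff,
        )
        _, order, newick = cluster_conditions(gene_table)
        results.update(
            differentials=differentials,
            diff_summary=diff_summary,
            condition_order=order,
            newick=newick,
        )
    return results


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all stages and write every output table plus a manifest.

    Deterministic given ``config`` (including its seed): identical configs
    produce byte-identical outputs.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.simulation is not None:
        sim = config.simulation
        truth, table, library = simulate_pool(sim)
        library.write_tsv(out / "library.tsv")
        truth.strains.to_csv(out / "truth_strains.tsv", sep="\t", index=False)
        truth.w_true.to_csv(out / "truth_w.tsv", sep="\t")
        truth.epsilon_true.to_csv(out / "truth_epsilon.tsv", sep="\t", index=False)
        if config.via_reads:
            sheet = simulate_reads(
                table,
                library,
                config.error_rate,
                out / "reads_R1.fastq",
                out / "reads_R2.fastq",
                out / "reads_index.fastq",
                seed=config.seed,
            )
            sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
            table, report = count_fused_barcodes(
                out / "reads_R1.fastq",
                out / "reads_R2.fastq",
                out / "reads_index.fastq",
                library,
                sheet,
            )
            report.write_tsv(out / "mapping_report.tsv")
    else:
        library = BarcodeLibrary.read_tsv(config.library_tsv)
        table = FusedCountTable.read_tsv(config.counts_tsv, config.samples_tsv)
    table.write_tsv(out / "counts.tsv", out / "samples.tsv")

    results = analyze_counts(table, library, config)
    classification = results["classification"]
    classification.write_tsv(out / "qc_pairs.tsv")
    if classification.replicate_report is not None:
        classification.replicate_report.to_csv(
            out / "qc_replicates.tsv", sep="\t", index=False
        )
    results["barcode_records"].to_csv(out / "barcode_gis.tsv", sep="\t", index=False)
    results["error_model"].to_csv(out / "error_model.tsv", sep="\t", index=False)
    results["gene_table"].to_csv(out / "gene_gis.tsv", sep="\t", index=False)
    edge_dir = out / "edges"
    edge_dir.mkdir(exist_ok=True)
    gt = results["gene_table"]
    for cond, sub in gt.groupby("condition"):
        edges = sub[sub["call"].isin(["positive", "negative"])]
        edges[["gene1", "gene2", "GIS", "q_neutral", "call"]].to_csv(
            edge_dir / f"edges_{cond}.tsv", sep="\t", index=False
        )
    if "differentials" in results:
        results["differentials"].to_csv(out / "differential_gis.tsv", sep="\t", index=False)
        results["diff_summary"].to_csv(out / "differential_summary.tsv", sep="\t", index=False)
        (out / "condition_dendrogram.nwk").write_text(results["newick"] + "\n")

    cfg_dict = asdict(config)
    if cfg_dict.get("simulation") is not None:
        sim_d = cfg_dict["simulation"]
        sim_d["true_epsilon"] = {
            "|".join(k): v for k, v in sim_d["true_epsilon"].items()
        }
    from gipool import __version__ as pkg_version

    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    gene_table = results["gene_table"]
    manifest = {
        "version": pkg_version,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": json.loads(cfg_json),
        "n_pairs": int(len(table.counts)),
        "n_samples": int(len(table.samples)),
        "n_retained_pairs": int(classification.frame["retained"].sum()),
        "n_excluded_barcodes": len(classification.excluded_barcodes),
        "n_barcode_records": int(len(results["barcode_records"])),
        "n_gene_records": int(len(gene_table)),
        "n_significant_calls": int((gene_table["call"].isin(["positive", "negative"])).sum()),
    }
    if "diff_summary" in results:
        manifest["n_significant_differentials"] = int(
            results["diff_summary"]["n_significant"].sum()
        )
        manifest["n_type_changing_differentials"] = int(
            results["diff_summary"]["n_type_changing"].sum()
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    results["manifest"] = manifest
    results["table"] = table
    results["library"] = library
    if truth is not None:
        results["truth"] = truth
    return results
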