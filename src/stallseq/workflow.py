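"""Configuration-driven end-to-end pipeline.

Sequences the assay stages: design the dicodon library, simulate truth and
reads, build the barcode map from linkage reads, count barcode samples,
quantify per-insert levels, and run the downstream analyses.  Every stage
writes a table into the run directory, and a JSON run log records the seed,
per-stage record counts, and (for simulated runs, where truth is known) the
rank correlation between true and estimated levels.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .analysis_models import (
    fit_physicochemical_model,
    frame_correlations,
    positional_effects,
)
from .linkage import LibraryIndex, build_barcode_map
from .quantify import count_barcodes, quantify_with_sem
from .reporter_library import enumerate_codon_pairs, library_manifest
from .simulate import (
    GenerativeModel,
    simulate_count_reads,
    simulate_linkage_reads,
    simulate_true_levels,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of a simulated end-to-end run."""

    seed: int
    outdir: str = "stallseq_run"
    # library
    subsample_inserts: int | None = None  # scaled-down runs; None = full 4096
    # generative model
    beta_pI: float = 0.31
    beta_bulk: float = 0.20
    beta_inter: float = -0.03
    beta_strand: float = -0.52
    noise_sd: float = 0.5
    stop_penalty: float = -2.0
    # linkage simulation
    median_barcodes: int = 15
    reads_per_barcode: float = 10.0
    linkage_error_rate: float = 0.001
    read_count_model: str = "poisson"
    # count simulation
    gdna_depth: int = 2_000_000
    mrna_depth: int = 2_000_000
    dispersion: float = 0.2
    count_error_rate: float = 0.001
    # filters
    min_count: int = 4
    collision_distance: int = 2
    max_mismatches: int = 2
    min_reads: int = 200
    min_barcodes: int = 6
    # quantification / analyses
    bootstrap_B: int | None = None
    run_positional: bool = True
    run_model: bool = True
    run_frames: bool = True
    write_fastq: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate → link → count → quantify → analyze; write run directory.

    Returns a dict with the main tables and the run log.
    """
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    log: dict = {"stallseq_version": __version__, "seed": config.seed, "stages": {}}

    # --- design ---
    inserts = enumerate_codon_pairs()
    if config.subsample_inserts is not None:
        idx = rng.choice(len(inserts), size=config.subsample_inserts, replace=False)
        inserts = [inserts[i] for i in sorted(idx)]
    manifest = library_manifest(inserts)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    log["stages"]["design"] = {"n_inserts": len(inserts)}

    # --- simulate ---
    model = GenerativeModel(
        beta_pI=config.beta_pI,
        beta_bulk=config.beta_bulk,
        beta_inter=config.beta_inter,
        beta_strand=config.beta_strand,
        noise_sd=config.noise_sd,
        stop_penalty=config.stop_penalty,
    )
    truth_levels = simulate_true_levels(inserts, model, rng)
    pd.DataFrame(
        {"insert_id": list(truth_levels), "true_level": list(truth_levels.values())}
    ).to_csv(outdir / "truth_levels.tsv", sep="\t", index=False)

    linkage_reads, linkage_truth = simulate_linkage_reads(
        inserts,
        rng,
        median_barcodes=config.median_barcodes,
        reads_per_barcode=config.reads_per_barcode,
        read_count_model=config.read_count_model,
        error_rate=config.linkage_error_rate,
    )
    linkage_truth.to_csv(outdir / "linkage_truth.tsv", sep="\t", index=False)
    log["stages"]["simulate_linkage"] = {
        "n_reads": len(linkage_reads),
        "n_true_barcodes": len(linkage_truth),
    }
    if config.write_fastq:
        linkage_reads.write_fastq(outdir / "linkage.fastq")

    # --- link ---
    index = LibraryIndex(inserts)
    barcode_map = build_barcode_map(
        linkage_reads,
        index,
        min_count=config.min_count,
        collision_distance=config.collision_distance,
        max_mismatches=config.max_mismatches,
    )
    barcode_map.to_tsv(outdir / "barcode_map.tsv.gz")
    log["stages"]["link"] = {
        "n_kept": len(barcode_map.entries),
        "dispositions": barcode_map.filter_log["disposition"].value_counts().to_dict(),
    }

    # --- count ---
    gdna_reads, mrna_reads, count_truth = simulate_count_reads(
        truth_levels,
        barcode_map.entries,
        rng,
        gdna_depth=config.gdna_depth,
        mrna_depth=config.mrna_depth,
        dispersion=config.dispersion,
        error_rate=config.count_error_rate,
    )
    if config.write_fastq:
        gdna_reads.write_fastq(outdir / "gdna.fastq")
        mrna_reads.write_fastq(outdir / "mrna.fastq")
    gdna_table = count_barcodes(gdna_reads, barcode_map)
    mrna_table = count_barcodes(mrna_reads, barcode_map)
    log["stages"]["count"] = {
        "gdna_reads": len(gdna_reads),
        "mrna_reads": len(mrna_reads),
        "gdna_unmatched": gdna_table.unmatched,
        "mrna_unmatched": mrna_table.unmatched,
    }

    # --- quantify ---
    quant = quantify_with_sem(
        mrna_table,
        gdna_table,
        barcode_map,
        rng,
        B=config.bootstrap_B,
        min_reads=config.min_reads,
        min_barcodes=config.min_barcodes,
    )
    quant.to_csv(outdir / "insert_quant.tsv", sep="\t", index=False)
    ok = quant[quant["status"] == "ok"]
    log["stages"]["quantify"] = {
        "n_ok": len(ok),
        "n_missing": int((quant["status"] == "missing").sum()),
    }

    merged = ok.merge(
        pd.DataFrame({"insert_id": list(truth_levels), "true_level": list(truth_levels.values())}),
        on="insert_id",
    )
    if len(merged) >= 3:
        rho = float(stats.spearmanr(merged["true_level"], merged["level"]).statistic)
        log["recovery_spearman"] = rho

    # --- analyze ---
    # inserts that lost every barcode upstream have no quant row -> NaN level
    qlev = quant.set_index("insert_id")["level"].reindex(manifest["insert_id"])
    by_pair = {
        (row.codon1, row.codon2): lvl
        for row, lvl in zip(manifest.itertuples(), qlev)
        if row.codon1
    }
    results: dict = {
        "manifest": manifest,
        "barcode_map": barcode_map,
        "quant": quant,
        "truth_levels": truth_levels,
        "log": log,
    }
    if config.run_positional:
        pos = positional_effects(by_pair)
        pos.to_csv(outdir / "positional_effects.tsv", sep="\t", index=False)
        results["positional_effects"] = pos
    if config.run_model:
        dipep_levels = _dipeptide_levels(manifest, quant)
        if len(dipep_levels) >= 8:
            fit = fit_physicochemical_model(dipep_levels, include_strand=True)
            fit_df = pd.DataFrame(fit.terms, columns=["term", "coefficient", "p_value"])
            fit_df["retained"] = fit_df["p_value"] < 0.05
            fit_df.to_csv(outdir / "physicochemical_model.tsv", sep="\t", index=False)
            log["stages"]["model"] = {"adjusted_r2": fit.adjusted_r2}
            results["model_fit"] = fit
    if config.run_frames:
        frames = frame_correlations(by_pair)
        frames.to_csv(outdir / "frame_correlations.tsv", sep="\t", index=False)
        results["frame_correlations"] = frames

    log["runtime_s"] = round(time.time() - t_start, 2)
    log["config"] = asdict(config)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return results


def _dipeptide_levels(manifest: pd.DataFrame, quant: pd.DataFrame) -> dict[str, float]:
    """Mean measured level per stop-free encoded dipeptide."""
    df = manifest.merge(quant[["insert_id", "level", "status"]], on="insert_id")
    df = df[(df["status"] == "ok") & ~df["peptide"].str.contains(r"\*", regex=True)]
    df = df.assign(dipeptide=df["peptide"].str[:2])
    return df.groupby("dipeptide")["level"].mean().to_dict()
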