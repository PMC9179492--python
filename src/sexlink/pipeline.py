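"""End-to-end pipeline: simulate/read → QC → scan → Monte Carlo →
chromosome mapping → repeat composition, with a machine-readable
summary.

Every run writes a fixed-layout run directory and a ``summary.json``
that embeds the fully resolved configuration, the package version and
the seed, so each reported number is traceable to a stage and its
parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .io import read_dart_pa, read_dart_snp, read_sample_sheet, write_matrix, \
    write_sample_sheet
from .mapping import SdrInterval, chromosome_counts, filter_and_assign, \
    loci_in_region, read_blast_tab, sdr_interval, write_karyotype_bed
from .monte_carlo import McConfig, subsample_reproducibility
from .qc import QcConfig, apply_qc
from .repeats import read_repeat_table, region_composition, composition_from_counts
from .scan import ScanConfig, run_scan
from .simulate import SimConfig, simulate_alignment_hits, simulate_dataset, \
    simulate_repeat_annotation, write_blast_tab
from .stats import expected_spurious, spurious_probability

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run (JSON-serializable)."""

    seed: int = 1
    simulate: dict | None = field(default_factory=dict)  # SimConfig kwargs; None = read inputs
    inputs: dict | None = None     # {"snp_path", "snp_dialect", "pa_path", "sheet_path"}
    qc: dict = field(default_factory=dict)               # QcConfig kwargs
    scan: dict = field(default_factory=dict)             # ScanConfig kwargs
    mc: dict = field(default_factory=lambda: {"enabled": True, "reps": 100_000,
                                              "system": "XY"})
    mapping: dict = field(default_factory=dict)          # {"hits_path"?, "min_identity", "min_length"}
    repeats: dict = field(default_factory=dict)          # {"table_path"?, "dialect", "composition"?}
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _prepare_out_dir(out_dir, overwrite: bool) -> Path:
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out_dir} is not empty; pass overwrite=True / --overwrite")
    out_dir.mkdir(parents=True, exist_ok=True)
    return out_dir


def run_pipeline(config: PipelineConfig, out_dir, overwrite: bool = False) -> dict:
    """Run every configured stage; returns the summary dict it also writes."""
    out = _prepare_out_dir(out_dir, overwrite)
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger("sexlink").addHandler(handler)
    logging.getLogger("sexlink").setLevel(config.log_level)
    summary: dict = {"version": __version__, "seed": config.seed,
                     "config": asdict(config)}
    try:
        # -- inputs -----------------------------------------------------
        truth = None
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            sim = SimConfig(**sim_kwargs)
            snp, pa, sheet, truth = simulate_dataset(sim)
            write_matrix(snp, out / "snp_matrix.csv")
            write_matrix(pa, out / "pa_matrix.csv")
            write_sample_sheet(sheet, out / "sample_sheet.csv")
            truth.table.to_csv(out / "sim_truth.tsv", sep="\t", index=False)
        else:
            inp = config.inputs or {}
            for key in ("snp_path", "pa_path", "sheet_path"):
                if key in inp and not Path(inp[key]).exists():
                    raise FileNotFoundError(f"input not found: {inp[key]}")
            snp = (read_dart_snp(inp["snp_path"], inp.get("snp_dialect", "two_row"))
                   if "snp_path" in inp else None)
            pa = read_dart_pa(inp["pa_path"]) if "pa_path" in inp else None
            sheet = read_sample_sheet(inp["sheet_path"])

        # -- QC ---------------------------------------------------------
        qc_config = QcConfig(**config.qc)
        qc_summaries = {}
        matrices = {}
        for name, m in (("SNP", snp), ("PA", pa)):
            if m is None:
                continue
            filtered, report = apply_qc(m, qc_config)
            matrices[name] = filtered
            report.flags.to_csv(out / f"qc_{name.lower()}.tsv", sep="\t")
            qc_summaries[name] = report.summary()
        summary["qc"] = qc_summaries

        # -- scan -------------------------------------------------------
        scan_config = ScanConfig(**config.scan)
        scans = {}
        for name, m in matrices.items():
            result = run_scan(m, sheet, scan_config)
            result.per_locus.to_csv(out / f"scan_{name.lower()}.tsv",
                                    sep="\t", index=False)
            scans[name] = result
        summary["scan"] = {name: r.summary() for name, r in scans.items()}

        # -- spurious-linkage model -------------------------------------
        n_total_loci = sum(m.n_loci for m in matrices.values())
        n_ind = sheet.n_samples
        summary["spurious_model"] = {
            "n_individuals": n_ind,
            "n_loci": n_total_loci,
            "P_i": spurious_probability(n_ind),
            "expected_spurious": expected_spurious(n_total_loci, n_ind),
        }

        # -- Monte Carlo ------------------------------------------------
        mc_cfg = dict(config.mc)
        if mc_cfg.pop("enabled", True):
            system = mc_cfg.pop("system", "XY")
            mc_config = McConfig(seed=mc_cfg.pop("seed", config.seed), **mc_cfg)
            mc_summaries = {}
            for name, m in matrices.items():
                report = subsample_reproducibility(m, sheet, scan_config,
                                                   mc_config, system=system)
                report.table.to_csv(out / f"mc_{name.lower()}.tsv",
                                    sep="\t", index=False)
                mc_summaries[name] = report.summary()
            summary["monte_carlo"] = mc_summaries

        # -- chromosome mapping -----------------------------------------
        map_cfg = dict(config.mapping)
        hits = None
        if "hits_path" in map_cfg:
            hits = read_blast_tab(map_cfg["hits_path"])
        elif truth is not None:
            hits = simulate_alignment_hits(truth, seed=config.seed)
            write_blast_tab(hits, out / "hits.tsv")
        if hits is not None:
            assignment = filter_and_assign(
                hits, min_identity=map_cfg.get("min_identity", 95.0),
                min_length=map_cfg.get("min_length", 65))
            assignment.placed.to_csv(out / "assignments.tsv", sep="\t")
            write_karyotype_bed(assignment, out / "karyotype.bed")

            # classify every scanned locus by its pooled tier
            tier_col = f"tier_{scan_config.systems[0]}"
            frames = []
            for r in scans.values():
                t = r.per_locus
                frames.append(t[t["population"] == "pooled"][["locus_id", tier_col]])
            if frames:
                tiers = pd.concat(frames).set_index("locus_id")[tier_col]
                counts = chromosome_counts(assignment, tiers)
                counts.to_csv(out / "chromosome_counts.tsv", sep="\t", index=False)
                summary["chromosome_counts"] = counts.to_dict(orient="records")
                specific = tiers[tiers == "specific"].index.tolist()
                placed_specific = assignment.placed[
                    assignment.placed.index.isin(specific)]
                if len(placed_specific):
                    top_chrom = placed_specific["chromosome"].mode().iloc[0]
                    interval = sdr_interval(assignment, top_chrom, specific)
                    n_in, frac = loci_in_region(assignment, interval)
                    summary["sdr_interval"] = interval.to_dict()
                    summary["sdr_interval"]["loci_in_region"] = n_in
                    summary["sdr_interval"]["fraction_of_chromosome_loci"] = frac
                    with open(out / "sdr_interval.json", "w") as fh:
                        json.dump(summary["sdr_interval"], fh, indent=2)

        # -- repeats ----------------------------------------------------
        rep_cfg = dict(config.repeats)
        annotation = None
        if "table_path" in rep_cfg:
            annotation = read_repeat_table(rep_cfg["table_path"],
                                           rep_cfg.get("dialect", "simple_tsv"))
        elif "composition" in rep_cfg and "sdr_interval" in summary:
            si = summary["sdr_interval"]
            interval = SdrInterval(si["chromosome"], si["start"], si["end"],
                                   si["n_loci"])
            annotation = simulate_repeat_annotation(
                rep_cfg["composition"], interval, seed=config.seed)
        if annotation is not None and "sdr_interval" in summary:
            si = summary["sdr_interval"]
            interval = SdrInterval(si["chromosome"], si["start"], si["end"],
                                   si["n_loci"])
            comp = region_composition(annotation, interval)
            comp.table.to_csv(out / "repeat_composition.tsv", sep="\t", index=False)
            summary["repeat_composition"] = {
                "total_fragments": comp.total,
                "rows": comp.to_records(),
            }

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=_jsonable)
            fh.write("\n")
        return summary
    finally:
        logging.getLogger("sexlink").removeHandler(handler)
        handler.close()


def _jsonable(obj):
    import numpy as np
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
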