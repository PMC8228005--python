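"""Pipeline orchestration: simulate/load -> qc -> structure -> scan -> annotate.

One YAML config drives a full run.  Each breed dataset is QC'd and scanned
separately (the comparison is always group I vs group II within a breed);
the structure diagnostic is computed jointly across breeds on the variants
every breed retained.  Every output directory gets a ``manifest.json``
recording the config snapshot, input digests, per-stage counts, seed and
version, so a run is reproducible bit-for-bit apart from timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import AnnotationSet, enrichment_test, load_annotations, overlap_regions
from .fst import FstConfig, Region, regions_to_bed, regions_to_frame, scan, track_to_tsv
from .genotypes import GenotypeMatrix, attach_groups, read_genotypes
from .qc import QcConfig, grm, run_qc
from .simulate import PlantedWindow, SimConfig, evaluate_recovery, simulate
from .structure import cluster_report, svd_structure

logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _dataclass_from(section: dict | None, cls, name: str):
    section = dict(section or {})
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - fields
    if unknown:
        raise ValueError(f"[{name}] unknown option(s): {sorted(unknown)}")
    try:
        return cls(**section)
    except TypeError as e:
        raise ValueError(f"[{name}] {e}") from e


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sim_config(section: dict, seed: int | None) -> SimConfig:
    section = dict(section)
    windows = [
        PlantedWindow(**w) if isinstance(w, dict) else w
        for w in section.pop("planted_windows", [])
    ]
    if seed is not None:
        section["seed"] = seed
    if "seed" not in section:
        raise ValueError("[simulate] missing required field: seed")
    if "ancestral_maf_range" in section:
        section["ancestral_maf_range"] = tuple(section["ancestral_maf_range"])
    cfg = _dataclass_from(section, SimConfig, "simulate")
    cfg.planted_windows = windows
    return cfg


def run_pipeline(
    config: str | Path | dict,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> Path:
    """Execute the full pipeline described by a config; returns the output dir."""
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    out = Path(out_dir or cfg.get("out_dir", "driftscan_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else cfg.get("seed")

    manifest: dict = {
        "tool": "driftscan",
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in cfg.items() if k != "out_dir"},
        "inputs": {},
        "stages": {},
        "started_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    stage = "setup"
    try:
        qc_cfg = _dataclass_from(cfg.get("qc"), QcConfig, "qc")
        scan_cfg = _dataclass_from(cfg.get("scan"), FstConfig, "scan")
        k_structure = int(cfg.get("structure", {}).get("k", 10))

        stage = "input"
        sim_genes: AnnotationSet | None = None
        sim_truths: dict[str, object] = {}
        if "simulate" in cfg:
            sim_cfg = _sim_config(cfg["simulate"], seed)
            g, truth, sim_genes = simulate(sim_cfg)
            sim_truths[sim_cfg.breed] = truth
            logger.info("simulated %d samples x %d SNPs (breed %s)",
                        g.n_samples, g.n_variants, sim_cfg.breed)
        elif "input" in cfg:
            inp = cfg["input"]
            if "prefix" not in inp:
                raise ValueError("[input] missing required field: prefix")
            g = read_genotypes(inp["prefix"], inp.get("dialect", "binary"))
            for ext in {"binary": (".bed", ".bim", ".fam"), "text": (".ped", ".map")}[
                inp.get("dialect", "binary")
            ]:
                p = Path(str(inp["prefix"]) + ext)
                manifest["inputs"][p.name] = _sha256(p)
            if "groups" in inp:
                g = attach_groups(g, inp["groups"])
                manifest["inputs"][Path(inp["groups"]).name] = _sha256(Path(inp["groups"]))
        else:
            raise ValueError("config needs a [simulate] or [input] section")
        if cfg.get("autosomes_only", True):
            g = g.drop_nonautosomal()
        manifest["stages"]["input"] = {"n_samples": g.n_samples, "n_variants": g.n_variants}

        breeds = [b for b in pd.unique(g.samples["breed"]) if b is not None] or [None]
        qcd: dict[str, GenotypeMatrix] = {}
        for breed in breeds:
            label = breed or "all"
            stage = f"qc[{label}]"
            sub = (
                g.take_samples(np.flatnonzero((g.samples["breed"] == breed).to_numpy()))
                if breed is not None
                else g
            )
            bdir = out / label
            bdir.mkdir(exist_ok=True)
            sub_qc, report = run_qc(sub, qc_cfg)
            report.to_tsv(bdir / "qc_report.tsv")
            qcd[label] = sub_qc
            manifest["stages"][f"qc.{label}"] = {
                "n_samples": report.n_samples_out,
                "n_variants": report.n_variants_out,
                "removed": {s["step"]: s["n_removed"] for s in report.steps},
            }

        stage = "structure"
        common = set.intersection(*(set(m.variants["id"]) for m in qcd.values()))
        pieces = []
        for label, m in qcd.items():
            keep = [i for i, vid in enumerate(m.variants["id"]) if vid in common]
            pieces.append(m.take_variants(keep))
        joint = GenotypeMatrix(
            np.vstack([p.dosage for p in pieces]),
            pd.concat([p.samples for p in pieces], ignore_index=True),
            pieces[0].variants.copy(),
        )
        sres = svd_structure(grm(joint), k=min(k_structure, joint.n_samples))
        sres.to_frame(joint.samples["sample_id"]).to_csv(
            out / "structure_scores.tsv", sep="\t", index=False
        )
        crep = cluster_report(sres, joint.samples, plot_path=out / "structure.png")
        manifest["stages"]["structure"] = {
            "n_samples": joint.n_samples,
            "n_variants": joint.n_variants,
            "breed_separation": crep["breed_separation"],
            "group_separation": crep["group_separation"],
        }

        ann_cfg = cfg.get("annotate", {})
        genes: AnnotationSet | None = sim_genes
        if "genes" in ann_cfg:
            genes = load_annotations(ann_cfg["genes"], ann_cfg.get("genes_format", "bed"))
        qtl: AnnotationSet | None = None
        if "qtl" in ann_cfg:
            qtl = load_annotations(
                ann_cfg["qtl"], ann_cfg.get("qtl_format", "bed"), default_category="qtl"
            )

        for label, m in qcd.items():
            stage = f"scan[{label}]"
            bdir = out / label
            track, regions = scan(m, scan_cfg)
            track_to_tsv(track, bdir / "fst_track.tsv", scan_cfg)
            regions_to_bed(regions, bdir / "regions.bed", scan_cfg.region_merge_gap_bp)
            regions_to_frame(regions).to_csv(bdir / "regions.tsv", sep="\t", index=False)
            manifest["stages"][f"scan.{label}"] = {
                "n_flagged_snps": int(track["is_outlier"].sum()),
                "n_regions": len(regions),
                "outlier_threshold": track.attrs["outlier_threshold"],
            }
            if label in sim_truths:
                rec = evaluate_recovery(regions, sim_truths[label])
                (bdir / "recovery.json").write_text(json.dumps(dataclasses.asdict(rec), indent=1))
                manifest["stages"][f"recovery.{label}"] = dataclasses.asdict(rec)

            stage = f"annotate[{label}]"
            if genes is not None:
                hits = overlap_regions(regions, genes)
                hits.to_csv(bdir / "gene_hits.tsv", sep="\t", index=False)
                hit_names = sorted(set(hits["name"]))
                manifest["stages"][f"annotate.{label}"] = {"n_genes_hit": len(hit_names)}
                cat_map = genes.records.rename(columns={"name": "gene"})[["gene", "category"]]
                if len(hit_names):
                    enr = enrichment_test(hit_names, cat_map, genes.records["name"])
                    enr.to_csv(bdir / "enrichment.tsv", sep="\t", index=False)
            if qtl is not None:
                qhits = overlap_regions(regions, qtl)
                qhits.to_csv(bdir / "qtl_hits.tsv", sep="\t", index=False)
                manifest["stages"][f"qtl.{label}"] = {"n_qtl_hit": len(set(qhits["name"]))}
    except Exception:
        logger.exception("pipeline failed at stage %s", stage)
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.suffix != ".partial" and p.name != "run.log":
                p.rename(p.with_name(p.name + ".partial"))
        raise
    manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out
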