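"""Run orchestration: simulate -> scan -> AFS -> association from one config.

A run is driven by a single YAML configuration with flat key groups.  Exactly
one of an ``inputs`` block (paths to VCF/population map/genes/phenotypes) or a
``simulation`` block may be present.  Every output artifact carries a
provenance header (tool version, seed, config hash); partially written
outputs are removed if a stage fails.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .afs import HitchhikingScan
from .assoc import AssociationStudy, ConditionSpec
from .errors import ConfigurationError
from .scan import ScanThresholds, SelectionScan
from .synthetic import (
    CrossConfig,
    PhenotypeModel,
    PopulationModel,
    SweepConfig,
    cross_locus_names,
    simulate_phenotypes,
    truth_dict,
)

log = logging.getLogger("tbscan")


@dataclass
class RunConfig:
    """Validated run configuration (see the packaged demo config for keys)."""

    raw: dict
    seed: int
    out_dir: Path
    inputs: dict | None
    simulation: dict | None
    thresholds: ScanThresholds
    focal: dict | None
    association: dict | None

    @classmethod
    def from_dict(cls, cfg: dict, out_dir=None, seed=None) -> "RunConfig":
        cfg = dict(cfg)
        if seed is not None:
            cfg["seed"] = int(seed)
        if out_dir is not None:
            cfg["out_dir"] = str(out_dir)
        has_inputs = bool(cfg.get("inputs"))
        has_sim = bool(cfg.get("simulation"))
        if has_inputs == has_sim:
            raise ConfigurationError("exactly one of an 'inputs' or a 'simulation' block is required")
        if "out_dir" not in cfg:
            raise ConfigurationError("config needs an out_dir")
        thr = ScanThresholds(**cfg.get("thresholds", {}))
        return cls(
            raw=cfg,
            seed=int(cfg.get("seed", 0)),
            out_dir=Path(cfg["out_dir"]),
            inputs=cfg.get("inputs") or None,
            simulation=cfg.get("simulation") or None,
            thresholds=thr,
            focal=cfg.get("focal") or None,
            association=cfg.get("association") or None,
        )

    @classmethod
    def from_yaml(cls, path, out_dir=None, seed=None) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ConfigurationError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(cfg, out_dir=out_dir, seed=seed)

    def config_hash(self) -> str:
        # hash the scientific configuration only; the output location is
        # allowed to differ between otherwise identical runs
        canon = json.dumps({k: v for k, v in self.raw.items() if k != "out_dir"},
                           sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def provenance(self) -> str:
        return f"tbscan={__version__}\tseed={self.seed}\tconfig={self.config_hash()}"


def _setup_run_dir(config: RunConfig) -> Path:
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    return out


def _teardown_logging() -> None:
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            log.removeHandler(h)
            h.close()


def _simulate_inputs(config: RunConfig, out: Path):
    sim = dict(config.simulation)
    sweep_cfg = sim.pop("sweep", None)
    model = PopulationModel(seed=config.seed, **{
        k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()
    })
    sweep = SweepConfig(**sweep_cfg) if sweep_cfg else None
    matrix = model.simulate(sweep)
    io.write_vcf(matrix, out / "simulated.vcf")
    io.write_pop_map(matrix, out / "populations.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_dict(model, sweep), fh, indent=2)
    return matrix, model, sweep


def _tiled_genes(matrix, gene_length: int = 2_000, spacing: int = 10_000):
    """Deterministic gene tiling used when no annotation is supplied."""
    length = int(matrix.positions[-1])
    genes = []
    k = 0
    for start in range(1, length - gene_length, spacing):
        k += 1
        genes.append(io.GeneAnnotation(f"gene{k:05d}", matrix.chrom,
                                       [(start, start + gene_length - 1)]))
    return genes


def run_scan_pipeline(config: RunConfig) -> dict:
    """Simulate or load genotypes, run the window/gene scan and AFS stage.

    Returns a dict of output paths and headline numbers; writes windows.tsv,
    genes.tsv, candidates.tsv, afs.tsv (+ truth.json and the simulated VCF
    when simulating) under ``config.out_dir``.
    """
    out = _setup_run_dir(config)
    written: list[Path] = []
    try:
        if config.simulation is not None:
            matrix, _model, sweep = _simulate_inputs(config, out)
            genes = _tiled_genes(matrix)
            pops = list(matrix.populations)
        else:
            inp = config.inputs
            matrix = io.read_vcf(inp["vcf"], inp["pops"])
            genes = io.read_genes(inp["genes"]) if inp.get("genes") else _tiled_genes(matrix)
            pops = inp.get("pop_order") or list(matrix.populations)
            sweep = None
        if len(pops) != 3:
            raise ConfigurationError(f"scan needs exactly three populations, got {pops}")

        scan_model = SelectionScan(matrix, genes, tuple(pops))
        res = scan_model.fit(thresholds=config.thresholds,
                             chrom_length=(config.simulation or {}).get("chrom_length_bp"))
        header = config.provenance()
        io.write_window_stats(out / "windows.tsv", res.windows, extra_header=header)
        written.append(out / "windows.tsv")
        for name, df in (("genes.tsv", res.genes), ("candidates.tsv", res.candidates)):
            with open(out / name, "w") as fh:
                fh.write(f"#{header}\n")
                df.to_csv(fh, sep="\t", index=False, na_rep="NA")
            written.append(out / name)
        log.info("scan: %d windows, %d genes, %d candidates",
                 len(res.windows), len(res.genes), len(res.candidates))

        afs_summary = None
        focal = config.focal or ({} if sweep is None else {
            "position": sweep.focal_position_bp,
            "focal_pop": sweep.target_pop,
        })
        if focal:
            outgroup = focal.get("outgroup_pop", pops[2])
            hh = HitchhikingScan(matrix, focal["position"],
                                 focal.get("focal_pop", pops[0]), outgroup)
            hres = hh.fit(max_distance=focal.get("max_distance", 80_000),
                          bin_size=focal.get("bin_size", 10_000))
            with open(out / "afs.tsv", "w") as fh:
                fh.write(f"#{header}\n")
                hres.table.to_csv(fh, sep="\t", index=False, na_rep="NA")
            written.append(out / "afs.tsv")
            afs_summary = hres.decay
            log.info("afs: decay rho=%.3f p=%.3g", hres.decay["spearman_rho"], hres.decay["p"])

        return {
            "out_dir": str(out),
            "windows": str(out / "windows.tsv"),
            "genes": str(out / "genes.tsv"),
            "candidates": str(out / "candidates.tsv"),
            "n_candidates": len(res.candidates),
            "candidate_genes": list(res.candidates["gene_id"]),
            "afs_decay": afs_summary,
            "summary": res.summary(),
        }
    except Exception:
        for p in written:
            if p.exists():
                p.unlink()
        raise
    finally:
        _teardown_logging()


def run_association_pipeline(config: RunConfig) -> dict:
    """Cross/panel association stage: t-tests, conditional cells, segregation.

    Writes association.tsv and segregation.tsv under ``config.out_dir``.
    """
    out = _setup_run_dir(config)
    written: list[Path] = []
    try:
        assoc_cfg = config.association or {}
        if config.simulation is not None:
            sim = config.simulation
            cross = CrossConfig(**{k: (tuple(v) if k == "loci_positions" else v)
                                   for k, v in sim.get("cross", {}).items()})
            rng = np.random.default_rng(config.seed)
            matrix = cross.simulate(seed=rng)
            names = cross_locus_names(cross)
            geno = matrix.to_frame(site_ids=names)
            effects = {k: {int(t): float(e) for t, e in v.items()}
                       for k, v in sim.get("effects", {}).items()}
            model = PhenotypeModel(additive_effects=effects, seed=config.seed)
            pheno = simulate_phenotypes(geno, model, seed=rng)
            io.write_phenotypes(pheno, out / "phenotypes.tsv")
            with open(out / "genotypes.tsv", "w") as fh:
                fh.write(f"#{config.provenance()}\n")
                geno.rename_axis("line_id").to_csv(fh, sep="\t")
        else:
            inp = config.inputs
            pheno = io.read_phenotypes(inp["phenotypes"])
            geno = pd.read_csv(inp["genotypes"], sep="\t", comment="#", index_col=0)

        conditions = None
        if assoc_cfg.get("conditions"):
            conditions = [ConditionSpec(c["site"], c.get("condition_site"),
                                        c.get("required_dosage")) for c in assoc_cfg["conditions"]]
        study = AssociationStudy(pheno, geno)
        res = study.fit(sites=assoc_cfg.get("sites"),
                        timepoints=assoc_cfg.get("timepoints"),
                        conditions=conditions,
                        rare_cutoff=assoc_cfg.get("rare_cutoff", 0.05))
        header = config.provenance()
        with open(out / "association.tsv", "w") as fh:
            fh.write(f"#{header}\n")
            res.table.to_csv(fh, sep="\t", index=False, na_rep="NA")
        written.append(out / "association.tsv")

        seg_rows = []
        for site in geno.columns:
            seg = study.segregation(site, expected_ratio=(1, 2, 1))
            seg_rows.append({"locus": site, "observed": "/".join(map(str, seg.observed)),
                             "ratio": "1:2:1", "chi2": seg.chi2, "df": seg.df, "p": seg.p})
        seg_df = pd.DataFrame(seg_rows)
        with open(out / "segregation.tsv", "w") as fh:
            fh.write(f"#{header}\n")
            seg_df.to_csv(fh, sep="\t", index=False)
        written.append(out / "segregation.tsv")
        log.info("association: %d rows; segregation: %d loci", len(res.table), len(seg_df))

        return {
            "out_dir": str(out),
            "association": str(out / "association.tsv"),
            "segregation": str(out / "segregation.tsv"),
            "table": res.table,
            "segregation_table": seg_df,
            "summary": res.summary(),
        }
    except Exception:
        for p in written:
            if p.exists():
                p.unlink()
        raise
    finally:
        _teardown_logging()


__all__ = ["RunConfig", "run_scan_pipeline", "run_association_pipeline"]
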