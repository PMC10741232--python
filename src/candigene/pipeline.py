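"""Pipeline orchestration: one config, all stages, deterministic outputs.

``run_full_analysis`` executes the enabled stages in order — single-SNP
association, haplotype/LD, MDR, survival — on a panel loaded from
PED/MAP or CSV (or simulated on the fly), and writes one TSV per stage
plus a JSON bundle stamped with the config hash and seed.  Identical
config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as cg_io
from .association import genotype_counts_from_panel, allelic_association, genotypic_association, hwe_chi_square, pooled_maf
from .haplotypes import haplotype_association, ld_matrix
from .mdr import classify_cells, cell_counts, class_metrics, entropy_analysis, mdr_search
from .panel import GenotypePanel, summarize_panel
from .simulate import (
    HaplotypeBlock,
    PenetranceModel,
    SimulationConfig,
    default_study_config,
    simulate_cohort,
)
from .survival import survival_by_genotype

log = logging.getLogger("candigene")


@dataclass
class PipelineConfig:
    """Everything one analysis run needs.

    Exactly one input source: ``ped``+``map`` paths, a ``csv`` path, or
    ``simulate=True`` (optionally with a simulation YAML).  Stage toggles
    default to on; ``seed`` is mandatory whenever any stochastic stage
    (simulation, MDR) is enabled.
    """

    out_dir: str = "candigene_out"
    ped: str | None = None
    map: str | None = None
    csv: str | None = None
    simulate: bool = False
    blocks: list[dict] | None = None
    stages: tuple[str, ...] = ("assoc", "haplo", "ld", "mdr", "survival")
    alpha: float = 0.05
    folds: int = 10
    k_range: tuple[int, ...] = (1, 2, 3)
    n_perm: int = 1000
    seed: int | None = None
    censor_cap: float = 60.0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        if isinstance(cfg.k_range, list):
            cfg.k_range = tuple(cfg.k_range)
        return cfg

    def validate(self) -> None:
        sources = sum([self.ped is not None, self.csv is not None, self.simulate])
        if sources != 1:
            raise ValueError("exactly one input source (ped/map, csv, simulate) required")
        if self.ped is not None and self.map is None:
            raise ValueError("ped input requires a map path")
        for path in (self.ped, self.map, self.csv):
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(path)
        stochastic = self.simulate or "mdr" in self.stages
        if stochastic and self.seed is None:
            raise ValueError("seed is mandatory when simulation or MDR is enabled")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_panel(config: PipelineConfig) -> GenotypePanel:
    if config.ped:
        return cg_io.read_ped_map(config.ped, config.map)
    if config.csv:
        return cg_io.read_genotype_table(config.csv)
    sim = simulation_config_from(config)
    panel, _ = simulate_cohort(sim)
    return panel


def simulation_config_from(config: PipelineConfig) -> SimulationConfig:
    if not config.blocks:
        return dataclasses.replace(default_study_config(seed=config.seed or 0))
    blocks = [
        HaplotypeBlock(
            snp_ids=tuple(b["snp_ids"]),
            haplotypes=tuple(b["haplotypes"]),
            frequencies=tuple(b["frequencies"]),
        )
        for b in config.blocks
    ]
    return SimulationConfig(blocks=blocks, seed=config.seed or 0)


def _assoc_tables(panel: GenotypePanel) -> dict[str, pd.DataFrame]:
    hwe_rows, assoc_rows = [], []
    for meta in panel.snps:
        snp = meta.snp_id
        case_g, ctrl_g = genotype_counts_from_panel(panel, snp)
        for grp, counts in (("control", ctrl_g), ("case", case_g)):
            if counts.n == 0:
                continue
            r = hwe_chi_square(counts)
            hwe_rows.append(
                {"snp": snp, "group": grp, "n": counts.n, "chi2": r.chi2, "p": r.p, "maf": r.maf}
            )
        if case_g.n and ctrl_g.n:
            row = allelic_association(case_g.allele_counts(), ctrl_g.allele_counts(), snp_id=snp)
            assoc_rows.append(
                {
                    "snp": snp, "model": "allelic", "contrast": row.contrast,
                    "case_counts": "/".join(map(str, row.case_counts)),
                    "control_counts": "/".join(map(str, row.control_counts)),
                    "OR": row.or_estimate.oddsratio,
                    "CI_low": row.or_estimate.ci_low, "CI_high": row.or_estimate.ci_high,
                    "method": row.test.method if row.test else "NA",
                    "p": row.test.p if row.test else float("nan"),
                }
            )
            for model in ("genotype-pairwise", "dominant", "recessive"):
                for c in genotypic_association(case_g, ctrl_g, model=model, snp_id=snp):
                    assoc_rows.append(
                        {
                            "snp": snp, "model": model, "contrast": c.contrast,
                            "case_counts": "/".join(map(str, c.case_counts)),
                            "control_counts": "/".join(map(str, c.control_counts)),
                            "OR": c.or_estimate.oddsratio,
                            "CI_low": c.or_estimate.ci_low, "CI_high": c.or_estimate.ci_high,
                            "method": c.test.method if c.test else "NA",
                            "p": c.test.p if c.test else float("nan"),
                        }
                    )
    return {"hwe": pd.DataFrame(hwe_rows), "association": pd.DataFrame(assoc_rows)}


def _blocks_of(panel: GenotypePanel) -> list[tuple[str, ...]]:
    """Group panel SNPs into blocks by chromosome label, genomic order."""
    by_chrom: dict[str, list] = {}
    for meta in panel.snps:
        by_chrom.setdefault(meta.chromosome, []).append(meta)
    blocks = []
    for metas in by_chrom.values():
        metas = sorted(metas, key=lambda m: m.position)
        if len(metas) >= 2:
            blocks.append(tuple(m.snp_id for m in metas[:4]))
    return blocks


def run_full_analysis(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Execute the enabled stages and write the report bundle.

    Returns the tables also written to ``config.out_dir``.  A stage
    failure aborts the run with the failing stage named; tables produced
    before the failure are still written alongside a FAILED marker.
    """
    config.validate()
    panel = load_panel(config)
    summary = summarize_panel(panel)
    log.info(
        "panel: %d cases / %d controls, %d SNPs",
        summary.n_cases, summary.n_controls, panel.n_snps,
    )
    tables: dict[str, pd.DataFrame] = {}
    stage = "setup"
    try:
        if "assoc" in config.stages:
            stage = "assoc"
            tables.update(_assoc_tables(panel))
        if "haplo" in config.stages:
            stage = "haplo"
            rows = []
            for block in _blocks_of(panel):
                try:
                    for r in haplotype_association(panel, block):
                        rows.append(
                            {
                                "block": "|".join(block), "haplotype": r.haplotype,
                                "freq_pooled": r.freq_pooled, "freq_case": r.freq_case,
                                "freq_control": r.freq_control, "chi2": r.chi2, "p": r.p,
                            }
                        )
                except Exception as exc:  # monomorphic blocks etc.
                    log.warning("haplotype block %s skipped: %s", block, exc)
            tables["haplotypes"] = pd.DataFrame(rows)
        if "ld" in config.stages:
            stage = "ld"
            rows = []
            for r in ld_matrix(panel):
                rows.append(
                    {"snp_a": r.snp_a, "snp_b": r.snp_b, "D": r.d,
                     "D_prime": r.d_prime, "r2": r.r2,
                     "defined": "yes" if r.defined else "no"}
                )
            tables["ld"] = pd.DataFrame(rows)
        if "mdr" in config.stages:
            stage = "mdr"
            reports, best = mdr_search(
                panel, k_range=config.k_range, folds=config.folds,
                seed=config.seed or 0, n_perm=config.n_perm,
            )
            rows = [
                {
                    "k": len(r.combo), "combo": "|".join(r.combo),
                    "training_ba": r.training_ba, "testing_ba": r.testing_ba,
                    "cvc": f"{r.cvc}/{r.folds}",
                    "perm_p": r.perm_p if r.perm_p is not None else float("nan"),
                    "best_overall": "yes" if r.combo == best.combo else "no",
                }
                for r in reports
            ]
            tables["mdr_models"] = pd.DataFrame(rows)
            model = classify_cells(cell_counts(panel, best.combo))
            metrics = class_metrics(model, panel)
            tables["mdr_best_metrics"] = pd.DataFrame([{
                "combo": "|".join(best.combo), **dataclasses.asdict(metrics),
            }])
            ent = entropy_analysis(panel)
            ent_rows = [
                {"kind": "main", "markers": s, "ig_percent": v}
                for s, v in ent.main_ig.items()
            ] + [
                {"kind": "pair", "markers": f"{a}|{b}", "ig_percent": v}
                for (a, b), v in ent.pair_ig.items()
            ]
            tables["entropy"] = pd.DataFrame(ent_rows)
            os.makedirs(config.out_dir, exist_ok=True)
            with open(os.path.join(config.out_dir, "entropy_dendrogram.nwk"), "w") as fh:
                fh.write(ent.newick() + "\n")
        if "survival" in config.stages and panel.survival_time is not None:
            stage = "survival"
            rows = []
            for meta in panel.snps:
                res = survival_by_genotype(panel, meta.snp_id, censor_cap=config.censor_cap)
                for label, curve in res.curves.items():
                    for t, s, n_risk in zip(curve.times, curve.survival, curve.at_risk):
                        rows.append(
                            {"snp": meta.snp_id, "genotype": label, "time": t,
                             "survival": s, "at_risk": n_risk,
                             "logrank_chi2": res.test.chi2 if res.test else float("nan"),
                             "logrank_p": res.test.p if res.test else float("nan")}
                        )
            tables["survival"] = pd.DataFrame(rows)
    except Exception:
        os.makedirs(config.out_dir, exist_ok=True)
        cg_io.write_report(tables, config.out_dir)
        with open(os.path.join(config.out_dir, "FAILED"), "w") as fh:
            fh.write(f"stage: {stage}\n")
        log.error("stage %r failed; partial outputs retained", stage)
        raise

    cg_io.write_report(tables, config.out_dir)
    meta = {"config_hash": config.digest(), "seed": config.seed,
            "n_cases": summary.n_cases, "n_controls": summary.n_controls}
    with open(os.path.join(config.out_dir, "run_meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return tables
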