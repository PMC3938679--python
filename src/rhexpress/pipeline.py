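"""End-to-end orchestration: simulate -> filter -> DE -> overlap -> GSEA
-> recovery.

``PipelineConfig`` carries every path and threshold; ``run_pipeline``
executes the stages in order, writes each intermediate artifact as TSV
under the output directory, and finishes with a machine-readable
``run_summary.json`` mirroring the logged counts.  A ``MANIFEST`` file
marks the run in progress and is completed last, so an aborted run is
recognizable.

All randomness flows from the single config seed, fanned out per stage,
so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .de import ModeratedPairedTTest, filter_probes
from .exceptions import InvalidParameterError, RhexpressError
from .gsea import PrerankedGSEA, rank_genes
from .overlap import collapse_to_genes, restrict_to_platform, venn_partition
from .recovery import RecoveryModel
from .simulate import (
    CohortConfig,
    SimConfig,
    generate_cohort,
    random_gene_sets,
    simulate_rhe_dataset,
    truth_gene_sets,
)

logger = logging.getLogger("rhexpress")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs.

    When ``simulate`` is true the input paths are ignored and a seeded
    synthetic dataset (paired experiment + cohort + gene sets) is
    generated and written under ``outdir/inputs``.
    """

    outdir: str = "rhexpress_run"
    seed: int = 0
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    # input paths, used when simulate is false
    matrix_path: str | None = None
    samples_path: str | None = None
    annotation_path: str | None = None
    gmt_path: str | None = None
    cohort_path: str | None = None
    cohort_samples_path: str | None = None
    effects_path: str | None = None
    # thresholds
    min_expr: float = 3.0
    min_sd: float = 0.1
    fch_threshold: float = 1.5
    fdr_threshold: float = 0.1
    improvement_threshold: float = 75.0
    dysreg_floor: float = 0.1
    # GSEA
    gsea_weight: float = 1.0
    n_perm: int = 1000
    n_random_sets: int = 10
    # platform restriction for the cohort comparison
    restrict_platform: str = "A2"

    def validate(self) -> None:
        for name in ("min_expr", "min_sd", "fch_threshold", "fdr_threshold",
                     "improvement_threshold", "dysreg_floor"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not self.simulate:
            required = ["matrix_path", "samples_path", "annotation_path", "gmt_path"]
            for name in required:
                path = getattr(self, name)
                if path is None:
                    raise InvalidParameterError(f"{name} is required when not simulating")
                if not Path(path).exists():
                    raise InvalidParameterError(f"{name}: no such file {path!r}")
            for name in ("cohort_path", "cohort_samples_path", "effects_path"):
                path = getattr(self, name)
                if path is not None and not Path(path).exists():
                    raise InvalidParameterError(f"{name}: no such file {path!r}")
        self.sim.validate()

    # -- YAML round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["cohort"]["arms"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in d["sim"]["cohort"]["arms"].items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        cohort = dict(sim.pop("cohort", {})) if isinstance(sim, dict) else {}
        if "arms" in cohort:
            cohort["arms"] = {
                k: (tuple(v) if isinstance(v, (list, tuple)) else v)
                for k, v in cohort["arms"].items()
            }
        sim_cfg = SimConfig(**sim, cohort=CohortConfig(**cohort))
        return cls(sim=sim_cfg, **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _prepare_inputs(config: PipelineConfig, outdir: Path):
    """Simulate or load the pipeline inputs; always returns the tuple
    (matrix, annotation, gene sets, cohort, effects, truth-or-None)."""
    if config.simulate:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        matrix, annotation, truth = simulate_rhe_dataset(sim)
        sets = truth_gene_sets(truth, annotation)
        gene_universe = sorted(set(annotation.table["gene_id"]))
        for gs in random_gene_sets(
            gene_universe,
            config.n_random_sets,
            50,
            np.random.SeedSequence([sim.seed, 7]),
        ):
            sets.add(gs)
        # cohort over the genes measurable on the restricted platform,
        # planting the cytokine-responsive genes among the dysregulated
        platform_genes = sorted(
            set(annotation.table.loc[annotation.probes_on(config.restrict_platform), "gene_id"])
        )
        responsive_genes = sorted(
            set(annotation.table["gene_id"].reindex(list(truth.responsive_probes)))
            & set(platform_genes)
        )
        cohort_cfg = sim.cohort
        n_fill = max(cohort_cfg.n_dysreg_genes - len(responsive_genes), 0)
        rng_fill = np.random.default_rng(np.random.SeedSequence([sim.seed, 11]))
        others = sorted(set(platform_genes) - set(responsive_genes))
        fill = (
            list(rng_fill.choice(others, size=min(n_fill, len(others)), replace=False))
            if n_fill
            else []
        )
        cohort, cohort_truth = generate_cohort(
            cohort_cfg,
            np.random.SeedSequence([sim.seed, 13]),
            genes=platform_genes,
            dysreg_genes=responsive_genes + fill,
        )
        inputs = outdir / "inputs"
        inputs.mkdir(parents=True, exist_ok=True)
        rio.write_expression(matrix, inputs / "expression.tsv", inputs / "samples.tsv")
        rio.write_annotation(annotation, inputs / "annotation.tsv")
        rio.write_gmt(sets, inputs / "gene_sets.gmt")
        rio.write_expression(cohort, inputs / "cohort.tsv", inputs / "cohort_samples.tsv")
        truth.true_lfc.rename("true_lfc").to_frame().assign(
            responsive=truth.true_lfc.index.isin(truth.responsive_probes),
            true_sigma_sq=truth.true_sigma_sq,
        ).rename_axis("probe_id").to_csv(inputs / "truth_paired.tsv", sep="\t",
                                         float_format="%.6g")
        ct = cohort_truth.true_recovery_frac.copy()
        ct.insert(0, "true_dysreg", cohort_truth.true_dysreg)
        ct.rename_axis("gene_id").to_csv(inputs / "truth_cohort.tsv", sep="\t",
                                         float_format="%.6g")
        return matrix, annotation, sets, cohort, None, truth
    matrix = rio.read_expression(config.matrix_path, config.samples_path)
    annotation = rio.read_annotation(config.annotation_path)
    sets = rio.read_gmt(config.gmt_path)
    cohort = None
    if config.cohort_path is not None:
        cohort = rio.read_expression(
            config.cohort_path, config.cohort_samples_path, platform=config.restrict_platform
        )
    effects = None
    if config.effects_path is not None:
        effects = (
            pd.read_csv(config.effects_path, sep="\t", dtype={"gene_id": str})
            .set_index("gene_id")["log2_effect"]
            .astype(float)
        )
    return matrix, annotation, sets, cohort, effects, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the machine-readable run summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "MANIFEST"
    manifest.write_text("status: RUNNING\n")
    summary: dict = {"config": config.to_dict(), "stages": {}}
    t_start = time.time()
    stage = "inputs"
    try:
        matrix, annotation, sets, cohort, effects, truth = _prepare_inputs(
            config, outdir
        )
        summary["stages"]["inputs"] = {
            "n_probes": matrix.n_probes,
            "n_samples": matrix.n_samples,
            "n_gene_sets": len(sets),
        }

        stage = "filter"
        t0 = time.time()
        filtered = filter_probes(matrix, config.min_expr, config.min_sd)
        rio.write_expression(filtered, outdir / "filtered.tsv")
        summary["stages"]["filter"] = {
            "probes_in": matrix.n_probes,
            "probes_out": filtered.n_probes,
            "seconds": round(time.time() - t0, 3),
        }
        logger.info("filter: %d -> %d probes", matrix.n_probes, filtered.n_probes)

        stage = "de"
        t0 = time.time()
        de_res = ModeratedPairedTTest(filtered, annotation).fit()
        de_res.to_tsv(outdir / "de.tsv")
        degs = de_res.call_degs(config.fch_threshold, config.fdr_threshold)
        degs.to_csv(outdir / "degs.tsv", sep="\t", float_format="%.6g")
        n_up = int((degs["is_deg"] & (degs["direction"] == "up")).sum())
        n_down = int((degs["is_deg"] & (degs["direction"] == "down")).sum())
        summary["stages"]["de"] = {
            "prior_d0": float(de_res.prior.d0),
            "prior_s0_sq": float(de_res.prior.s0_sq),
            "n_deg_probes": n_up + n_down,
            "n_deg_up": n_up,
            "n_deg_down": n_down,
            "seconds": round(time.time() - t0, 3),
        }
        logger.info("de: %d up, %d down DEG probes", n_up, n_down)

        stage = "overlap"
        t0 = time.time()
        deg_set = collapse_to_genes(degs, annotation, label="treated_vs_control",
                                    platform=matrix.platform)
        restricted, n_excluded = restrict_to_platform(
            deg_set, config.restrict_platform, annotation
        )
        venn = venn_partition(
            [("deg_up", set(deg_set.genes_up)), ("deg_down", set(deg_set.genes_down))]
        )
        with open(outdir / "overlap.json", "w") as fh:
            json.dump(
                {
                    "full": deg_set.counts(),
                    "restricted": restricted.counts(),
                    "probes_excluded_by_restriction": n_excluded,
                    "venn_up_down": {"&".join(k): v for k, v in venn.items()},
                },
                fh,
                indent=2,
            )
        summary["stages"]["overlap"] = {
            "n_deg_genes": len(deg_set.genes),
            "n_deg_genes_restricted": len(restricted.genes),
            "probes_excluded_by_restriction": n_excluded,
            "seconds": round(time.time() - t0, 3),
        }

        stage = "gsea"
        t0 = time.time()
        ranked = rank_genes(de_res.table, annotation)
        ranked.to_tsv(outdir / "ranked_genes.tsv")
        gsea_res = PrerankedGSEA(ranked, sets, weight=config.gsea_weight).fit(
            n_perm=config.n_perm,
            seed=np.random.SeedSequence([config.seed, 17]),
        )
        gsea_res.to_tsv(outdir / "gsea.tsv")
        summary["stages"]["gsea"] = {
            "n_sets_scored": int(len(gsea_res.table)),
            "n_sets_skipped": len(gsea_res.skipped),
            "top_set": gsea_res.table.index[0] if len(gsea_res.table) else None,
            "seconds": round(time.time() - t0, 3),
        }

        stage = "recovery"
        if cohort is not None:
            t0 = time.time()
            score_genes = sorted(set(restricted.genes) & set(cohort.probe_ids))
            if score_genes:
                rec_res = RecoveryModel(cohort, score_genes, effects=effects).fit(
                    threshold=config.improvement_threshold, floor=config.dysreg_floor
                )
                rec_res.to_tsv(outdir / "recovery")
                summary["stages"]["recovery"] = {
                    "n_genes_scored": len(score_genes),
                    "per_arm": {
                        arm: {
                            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                            for k, v in row.items()
                        }
                        for arm, row in rec_res.summary_table.to_dict("index").items()
                    },
                    "seconds": round(time.time() - t0, 3),
                }
            else:
                summary["stages"]["recovery"] = {"n_genes_scored": 0}
    except RhexpressError as exc:
        manifest.write_text(f"status: FAILED\nstage: {stage}\nerror: {exc}\n")
        raise RhexpressError(f"[stage {stage}] {exc}") from exc

    summary["seconds_total"] = round(time.time() - t_start, 3)
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    manifest.write_text("status: COMPLETE\n")
    return summary
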