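"""Configuration-driven orchestration of the full analysis.

One declarative configuration (YAML or dict) drives simulate -> dm ->
aggregate -> enrich -> gsea -> exe-score -> cluster, writing every stage
table under the output directory together with a manifest of SHA-256
file hashes.  All randomness flows from a single root seed via named
substreams, so the same configuration and seed produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregate as agg
from . import enrichment as enr
from . import exe_score as exe
from . import io as rio
from . import simulate as sim
from . import structure as struct
from .containers import ValidationError
from .diffmeth import differential_expression, differential_methylation

logger = logging.getLogger("regmeth")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class Thresholds:
    delta_beta: float = 0.2
    fdr: float = 0.05
    gene_min_cpgs: int = 2
    promoter_min_cpgs: int = 1
    logor: float = 0.6
    enrichment_fdr: float = 0.05
    expression_logfc: float = 0.6
    expression_fdr: float = 0.2
    gsea_min_size: int = 15
    gsea_max_size: int = 2000
    gsea_permutations: int = 5000
    cpg_set_delta_min: float = 0.2
    cpg_set_max_size: int = 2999
    mds_top_cpgs: int = 1000

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValidationError(f"threshold {f.name} must be positive")


@dataclass
class PipelineConfig:
    seed: int
    outdir: str
    simulation: dict = field(default_factory=dict)
    input_beta: str | None = None
    input_annotation: str | None = None
    input_sheet: str | None = None
    contrast: tuple[str, str] | None = None
    secondary_contrast: tuple[str, str] | None = None
    paired: bool = False
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        thresholds = Thresholds(**raw.get("thresholds", {}))
        cfg = cls(
            seed=int(raw["seed"]),
            outdir=str(raw["outdir"]),
            simulation=raw.get("simulation", {}),
            input_beta=raw.get("input_beta"),
            input_annotation=raw.get("input_annotation"),
            input_sheet=raw.get("input_sheet"),
            contrast=tuple(raw["contrast"]) if raw.get("contrast") else None,
            secondary_contrast=(
                tuple(raw["secondary_contrast"]) if raw.get("secondary_contrast") else None
            ),
            paired=bool(raw.get("paired", False)),
            thresholds=thresholds,
        )
        cfg.thresholds.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=rio.FLOAT_FORMAT)


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every stage; return the manifest of output-file hashes."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    th.validate()

    # ---- simulate (or load) -------------------------------------------------
    stage = "simulate"
    try:
        if config.input_beta:
            stage = "dm"
            for name, p in (
                ("beta", config.input_beta),
                ("annotation", config.input_annotation),
                ("sheet", config.input_sheet),
            ):
                if p is None or not Path(p).exists():
                    raise PipelineError("dm", f"missing input {name} file: {p}")
            beta, annotation, sheet = rio.load_dataset(
                config.input_beta, config.input_annotation, config.input_sheet
            )
            expression = None
            regions = None
            truth = None
        else:
            sim_cfg = sim.SimulationConfig(seed=config.seed, **config.simulation)
            beta, annotation, sheet, truth = sim.generate_methylome(sim_cfg)
            expression = sim.generate_expression(beta, truth, annotation, sim_cfg)
            regions = sim.generate_region_sets(annotation, truth, sim_cfg)
            rio.write_matrix(beta, outdir / "beta.tsv", id_name="cpg_id")
            rio.write_annotation(annotation, outdir / "annotation.tsv")
            rio.write_sample_sheet(sheet, outdir / "samples.csv")
            rio.write_matrix(expression, outdir / "expression.tsv", id_name="gene_id")
            sim.write_truth(truth, outdir / "truth.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    groups = list(dict.fromkeys(sheet.frame["group"]))
    contrast = config.contrast or (groups[0], groups[1])
    secondary = config.secondary_contrast or (
        (groups[0], groups[2]) if len(groups) >= 3 else contrast
    )

    # ---- dm -----------------------------------------------------------------
    try:
        dm = differential_methylation(
            beta, sheet, contrast, paired=config.paired,
            delta_threshold=th.delta_beta, fdr_threshold=th.fdr,
        )
        _write(dm, outdir / "dm.tsv")
        dm2 = differential_methylation(
            beta, sheet, secondary, paired=config.paired,
            delta_threshold=th.delta_beta, fdr_threshold=th.fdr,
        )
        _write(dm2, outdir / "dm_secondary.tsv")
        logger.info(
            "dm: %d hyper, %d hypo of %d CpGs (%s vs %s)",
            (dm["call"] == "hyper").sum(), (dm["call"] == "hypo").sum(), len(dm),
            *contrast,
        )
    except Exception as exc:
        raise PipelineError("dm", str(exc)) from exc

    # ---- aggregate ----------------------------------------------------------
    try:
        genes = agg.call_dm_genes(dm["call"], annotation, min_cpgs=th.gene_min_cpgs)
        promoters = agg.call_dm_promoters(
            dm["call"], annotation, min_cpgs=th.promoter_min_cpgs
        )
        _write(genes, outdir / "dm_genes.tsv", index=False)
        _write(promoters, outdir / "dm_promoters.tsv", index=False)
        if expression is not None:
            de = differential_expression(
                expression, sheet, contrast, paired=config.paired,
                logfc_threshold=th.expression_logfc, fdr_threshold=th.expression_fdr,
            )
            _write(de, outdir / "de.tsv")
            prom_meth = agg.promoter_methylation_matrix(beta, annotation)
            dm_prom_genes = [
                g for g in promoters["gene"].unique() if g in prom_meth.index
            ]
            if dm_prom_genes:
                corr = agg.correlate_promoter_expression(
                    prom_meth.loc[dm_prom_genes], expression
                )
                _write(corr, outdir / "promoter_expression_corr.tsv")
    except Exception as exc:
        raise PipelineError("aggregate", str(exc)) from exc

    # ---- enrich -------------------------------------------------------------
    try:
        if regions is not None:
            query = list(dm.index[dm["call"] != "ns"])
            if query:
                overlap = enr.locus_overlap_enrichment(
                    query, list(dm.index), annotation, regions,
                    logor_threshold=th.logor, fdr_threshold=th.enrichment_fdr,
                )
                _write(overlap, outdir / "enrichment.tsv", index=False)
                residuals = enr.feature_distribution_residuals(dm["call"], annotation)
                _write(residuals, outdir / "feature_residuals.tsv", index=False)
    except Exception as exc:
        raise PipelineError("enrich", str(exc)) from exc

    # ---- gsea ---------------------------------------------------------------
    try:
        cpg_sets = enr.build_direction_cpg_sets(
            dm2, delta_min=th.cpg_set_delta_min, max_size=th.cpg_set_max_size
        )
        cpg_sets = {k: v for k, v in cpg_sets.items() if v}
        if cpg_sets:
            gsea = enr.preranked_gsea(
                dm["t"], cpg_sets, n_perm=th.gsea_permutations, seed=config.seed,
            )
            _write(gsea, outdir / "gsea.tsv", index=False)
    except Exception as exc:
        raise PipelineError("gsea", str(exc)) from exc

    # ---- exe-score ----------------------------------------------------------
    try:
        cgis = sim.cgi_regions_from_annotation(annotation)
        if len(cgis):
            exe_intervals = sim.RegionSet(
                "exe", cgis.intervals.iloc[::5].reset_index(drop=True)
            )
            mapping = exe.assign_closest_cgi(exe_intervals, cgis)
            scores = exe.compute_exe_scores(beta, annotation, cgis, mapping["cgi"])
            normal_samples = [
                s for s in sheet.sample_ids
                if sheet.frame.set_index("sample_id").loc[s, "group"] != contrast[0]
            ]
            tau = exe.normal_upper_limit(scores.loc[normal_samples])
            table = exe.classify_scores(scores, tau)
            test = exe.wilcoxon_rank_sum(
                scores.loc[[s for s in sheet.sample_ids if s not in normal_samples]],
                scores.loc[normal_samples],
            )
            table["tau"] = tau
            _write(table, outdir / "exe_scores.tsv")
            pd.DataFrame(
                [{"W": test.W, "p": test.p, "tau": tau}]
            ).to_csv(outdir / "exe_test.tsv", sep="\t", index=False,
                     float_format=rio.FLOAT_FORMAT)
    except Exception as exc:
        raise PipelineError("exe-score", str(exc)) from exc

    # ---- cluster ------------------------------------------------------------
    try:
        embedding = struct.mds_top_variable(beta, n_top=th.mds_top_cpgs)
        _write(embedding.coordinates, outdir / "mds.tsv")
        high = struct.select_high_methylation_cluster(beta, k=2)
        pd.DataFrame(
            {
                "sample_id": sheet.sample_ids,
                "high_methylation_cluster": [
                    s in set(high) for s in sheet.sample_ids
                ],
            }
        ).to_csv(outdir / "cluster.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("cluster", str(exc)) from exc

    manifest = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
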