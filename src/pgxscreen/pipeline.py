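"""Config-driven end-to-end run: filter -> screen -> model comparison -> index.

Every stochastic stage derives its stream from the single config seed, so a
rerun with the same inputs and config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core_data import (
    SampleTable,
    read_annotations,
    read_genotype_tsv,
    read_phenotypes,
    split_datasets,
)
from .index import compute_index, dichotomize, index_contingency
from .models import compare_models, ten_model_preset
from .qc import FilterConfig, apply_filters
from .screen import PermutationConfig, screen

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("pgxscreen")


@dataclass
class PipelineConfig:
    genotype_tsv: str
    phenotype_tsv: str
    annotation_tsv: str
    out_dir: str
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    n_perm: int = 1000
    screen_model: str = "allele"
    alpha1: float = 0.05
    alpha2: float = 0.05
    perm_alpha: float = 0.05
    model_snps: list[str] | None = None  # default: top two screening candidates
    index_snps: list[str] | None = None
    index_threshold: int = 2

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "filter" in raw:
            raw["filter"] = FilterConfig(**raw["filter"])
        return cls(**raw)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, writing per-stage TSVs plus a JSON summary.

    Returns the summary dict.  A stage failure aborts with the stage name;
    outputs of completed stages are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed, "config": _echo(config)}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("load")
        genotypes = read_genotype_tsv(config.genotype_tsv)
        samples = read_phenotypes(config.phenotype_tsv)
        annotations = read_annotations(config.annotation_tsv)
        first_ids, second_ids = split_datasets(samples)
        summary["n_samples"] = len(samples)
        summary["n_first_dataset"] = len(first_ids)
        summary["n_snps_input"] = genotypes.n_snps
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("load", exc) from exc

    try:
        stage("filter")
        report = apply_filters(genotypes, annotations, config.filter)
        report.per_snp.to_csv(out / "filter_report.tsv", sep="\t", index=False)
        retained = sorted(report.retained)
        summary["n_snps_retained"] = len(retained)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("filter", exc) from exc

    try:
        stage("screen")
        perm = PermutationConfig(config.n_perm, config.seed, config.screen_model)
        screened = screen(
            genotypes, samples, retained, first_ids, second_ids, perm,
            config.alpha1, config.alpha2, config.perm_alpha,
        )
        screened.to_csv(out / "screening.tsv", sep="\t")
        candidates = screened.index[screened.get("candidate", pd.Series(dtype=bool))].tolist()
        summary["candidates"] = candidates
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("screen", exc) from exc

    model_snps = config.model_snps
    if model_snps is None:
        ranked = screened.sort_values("combined_T").index.tolist()
        model_snps = ranked[:2]
    summary["model_snps"] = list(model_snps)

    try:
        stage("model")
        if len(model_snps) >= 2:
            data = samples.frame.set_index("sample_id").join(
                genotypes.dose_frame(list(model_snps[:2]))
            ).dropna(subset=list(model_snps[:2]))
            comparison = compare_models(
                ten_model_preset(model_snps[0], model_snps[1]), data
            )
            comparison.to_csv(out / "model_comparison.tsv", sep="\t", index=False)
            summary["best_model"] = comparison.iloc[0]["model"]
            summary["model_table"] = comparison.to_dict(orient="records")
        else:
            summary["best_model"] = None
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("model", exc) from exc

    try:
        stage("index")
        index_snps = config.index_snps or list(model_snps[:2])
        if len(index_snps) >= 2:
            idx = compute_index(genotypes, index_snps)
            result = index_contingency(idx, samples.response_series())
            result.levels.to_csv(out / "index_levels.tsv", sep="\t", index=False)
            table, p_dichot = dichotomize(result, config.index_threshold)
            summary["index"] = {
                "snps": index_snps,
                "p_levels": result.p_levels,
                "p_dichotomized": p_dichot,
                "dichotomized_table": table.tolist(),
                "threshold": config.index_threshold,
            }
        else:
            summary["index"] = None
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("index", exc) from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    return summary


def _echo(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d
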