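"""Pipeline orchestration: simulate -> count -> de -> concord -> validate.

Stages communicate through files in the output directory so any suffix of
the pipeline can be re-run from persisted intermediates. The consolidated
report (JSON + Markdown) carries the parameter echo, the DE tally, the
concordance summary table and the validation tallies; with a fixed seed
and config the report is byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import concordance as conc
from . import counting, de, sim, validation

__all__ = ["PipelineConfig", "PipelineError", "MissingInputError", "run_pipeline", "write_report"]

logger = logging.getLogger("crossde")

STAGE_ORDER = ("simulate", "count", "de", "concord", "validate")


class PipelineError(ValueError):
    """Invalid pipeline configuration."""


class MissingInputError(FileNotFoundError):
    """A requested stage lacks its upstream input."""


@dataclass
class PipelineConfig:
    outdir: str
    # the count stage needs external GTF/read inputs, so the default chain
    # runs the fully synthetic path
    stages: tuple[str, ...] = ("simulate", "de", "concord", "validate")
    seed: int = 0
    simulation: Mapping[str, Any] = field(default_factory=dict)
    alpha: float = 0.05
    min_fold: float = 1.5
    adjust: str = "bh"
    # optional external inputs overriding simulate-stage outputs
    counts_tsv: str | None = None
    conditions_tsv: str | None = None
    refsets_tsv: str | None = None
    orthologs_tsv: str | None = None
    panel_tsv: str | None = None
    gtf: str | None = None
    reads: Mapping[str, str] = field(default_factory=dict)  # sample id -> BED path
    heatmap: bool = False

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise PipelineError(f"unknown stages {sorted(unknown)}")
        if not self.stages:
            raise PipelineError("at least one stage must be requested")
        order = [STAGE_ORDER.index(s) for s in self.stages]
        if order != sorted(order):
            raise PipelineError("stages must follow the pipeline order")
        if self.adjust not in ("bh", "bonferroni"):
            raise PipelineError(f"unknown adjustment method {self.adjust!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise PipelineError(str(exc)) from exc


def _sim_config(config: PipelineConfig) -> sim.SimulationConfig:
    kwargs = dict(config.simulation)
    kwargs["seed"] = config.seed
    for key in ("mean_log10_range", "dispersion_model", "library_size_factors"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    try:
        return sim.SimulationConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise PipelineError(f"invalid simulation config: {exc}") from exc


def _require(path: Path | None, stage: str, what: str) -> Path:
    if path is None or not Path(path).exists():
        raise MissingInputError(
            f"stage {stage!r} is missing its {what} input"
            + (f" ({path})" if path is not None else "")
        )
    return Path(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages and return the consolidated report dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "alpha": config.alpha,
            "min_fold": config.min_fold,
            "adjust": config.adjust,
            "simulation": dict(config.simulation),
        },
    }

    counts_path = Path(config.counts_tsv) if config.counts_tsv else None
    conditions_path = Path(config.conditions_tsv) if config.conditions_tsv else None
    refsets_path = Path(config.refsets_tsv) if config.refsets_tsv else None
    orthologs_path = Path(config.orthologs_tsv) if config.orthologs_tsv else None
    panel_path = Path(config.panel_tsv) if config.panel_tsv else None
    truth: pd.DataFrame | None = None

    if "simulate" in config.stages:
        logger.info("simulate: generating synthetic experiment (seed=%d)", config.seed)
        sim_cfg = _sim_config(config)
        matrix, truth = sim.simulate_count_experiment(sim_cfg)
        refsets = sim.simulate_reference_sets(truth, sim_cfg)
        orthologs = sim.simulate_ortholog_map(
            matrix.gene_ids, sim_cfg.ortholog_dropout_rate, seed=sim_cfg.seed
        )
        counts_path = outdir / "counts.tsv"
        conditions_path = outdir / "conditions.tsv"
        matrix.to_tsv(counts_path, conditions_path)
        truth.to_csv(outdir / "truth.tsv", sep="\t")
        refsets_path = outdir / "reference_sets.tsv"
        refsets.to_tsv(refsets_path)
        orthologs_path = outdir / "orthologs.tsv"
        orthologs.to_tsv(orthologs_path)
        report["simulate"] = {
            "n_genes": sim_cfg.n_genes,
            "n_per_group": sim_cfg.n_per_group,
            "n_true_de": int(truth["true_de"].sum()),
        }
        logger.info("simulate: %d genes, %d true DE", sim_cfg.n_genes, int(truth["true_de"].sum()))

    if "count" in config.stages:
        gtf_path = _require(Path(config.gtf) if config.gtf else None, "count", "GTF")
        if not config.reads:
            raise MissingInputError("stage 'count' is missing its reads input")
        model = counting.union_exon_model(counting.read_gtf_exons(gtf_path))
        reads_by_sample = {
            s: counting.read_bed_reads(_require(Path(p), "count", f"reads[{s}]"))
            for s, p in config.reads.items()
        }
        matrix, stats = counting.count_reads(reads_by_sample, model)
        counts_path = outdir / "counted.tsv"
        matrix.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
        report["count"] = {
            s: {"assigned": st.assigned, "no_feature": st.no_feature, "ambiguous": st.ambiguous}
            for s, st in stats.items()
        }

    results: pd.DataFrame | None = None
    if "de" in config.stages:
        counts_path = _require(counts_path, "de", "counts")
        conditions_path = _require(conditions_path, "de", "conditions")
        matrix = counting.CountMatrix.from_tsv(counts_path, conditions_path)
        logger.info("de: testing %d genes", len(matrix.gene_ids))
        results = de.run_de(
            matrix,
            alpha=config.alpha,
            min_fold=config.min_fold,
            adjust=config.adjust,
        )
        results.to_csv(outdir / "de_results.tsv", sep="\t")
        called = results[results["significant"]]
        called.to_csv(outdir / "de_called.tsv", sep="\t")
        report["de"] = {
            "n_tested": int(len(results)),
            "n_called": int(len(called)),
            "n_up": int((called["direction"] == "up").sum()),
            "n_down": int((called["direction"] == "down").sum()),
        }
        if config.heatmap and len(called) >= 2:
            _write_heatmap(matrix, called.index, outdir / "heatmap.png")

    classified: list[conc.ClassifiedGene] | None = None
    if "concord" in config.stages:
        if results is None:
            called_path = _require(outdir / "de_called.tsv", "concord", "called-DE")
            results = pd.read_csv(called_path, sep="\t", index_col=0)
            called = results
        else:
            called = results[results["significant"]]
        refsets = conc.ReferenceSets.from_tsv(_require(refsets_path, "concord", "reference-set"))
        orthologs = conc.OrthologMap.from_tsv(
            _require(orthologs_path, "concord", "ortholog")
        )
        rat_de = dict(zip(called.index, called["direction"]))
        classified, unmapped = conc.classify_genes(rat_de, refsets, orthologs)
        pd.DataFrame([vars(c) for c in classified]).to_csv(
            outdir / "classified.tsv", sep="\t", index=False
        )
        summary = conc.summarize_concordance(classified)
        summary.rename_axis("row").to_csv(outdir / "concordance_summary.tsv", sep="\t")
        report["concord"] = {
            "summary": {r: summary.loc[r].to_dict() for r in summary.index},
            "n_unmapped_orthologs": len(unmapped),
        }

    if "validate" in config.stages:
        if panel_path is not None:
            records = validation.frame_to_records(pd.read_csv(panel_path, sep="\t"))
            planted = None
        else:
            if classified is None:
                raise MissingInputError(
                    "stage 'validate' is missing its panel input (no panel_tsv and "
                    "no concord stage output)"
                )
            candidates = [
                (
                    c.gene,
                    "common_rat_mouse" if c.primary_category == "shared_hyp" else "unique_rat",
                    c.rat_direction,
                )
                for c in classified
                if c.primary_category in ("shared_hyp", "unique_rat")
            ]
            records, planted = sim.simulate_validation_panel(candidates, _sim_config(config))
        frame = validation.records_to_frame(records)
        frame["label"] = [validation.classify_validation_record(r) for r in records]
        if planted is not None:
            frame["planted_label"] = planted
        frame.to_csv(outdir / "validation_labelled.tsv", sep="\t", index=False)
        report["validate"] = validation.summarize_validation(records)

    write_report(report, outdir)
    return report


def _write_heatmap(matrix: counting.CountMatrix, genes, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sf = de.estimate_size_factors(matrix)
    norm = matrix.counts.loc[genes] / sf.factors
    z = de.zscore_rows(norm)
    row_order, col_order = de.hierarchical_cluster(z)
    fig, ax = plt.subplots(figsize=(6, 8))
    ax.imshow(z.iloc[row_order, col_order], aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(col_order)))
    ax.set_xticklabels([z.columns[i] for i in col_order], rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_xlabel("sample")
    ax.set_ylabel(f"{len(genes)} DE genes (row z-scores)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_report(report: dict, outdir) -> tuple[Path, Path]:
    """Serialize the consolidated report deterministically (JSON + Markdown)."""
    outdir = Path(outdir)
    json_path = outdir / "report.json"
    md_path = outdir / "report.md"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    lines = ["# Pipeline report", "", f"Seed: {report.get('seed')}", ""]
    if "de" in report:
        d = report["de"]
        lines += [
            "## Differential expression",
            "",
            f"{d['n_called']} of {d['n_tested']} genes called "
            f"({d['n_down']} down, {d['n_up']} up).",
            "",
        ]
    if "concord" in report:
        summary = report["concord"]["summary"]
        cols = list(next(iter(summary.values())))
        lines += ["## Concordance", "", "| row | " + " | ".join(cols) + " |"]
        lines.append("|" + "---|" * (len(cols) + 1))
        for row, cells in summary.items():
            formatted = [
                f"{cells[c]:.2f}" if row == "percent_of_total" else f"{int(cells[c])}"
                for c in cols
            ]
            lines.append(f"| {row} | " + " | ".join(formatted) + " |")
        lines.append("")
    if "validate" in report:
        v = report["validate"]
        lines += ["## Validation", ""]
        for label, count in v["counts"].items():
            lines.append(f"- {label}: {count} ({v['percent'][label]}%)")
        lines.append(
            f"- altered or undetectable: {v['altered_or_undetectable']} "
            f"({v['percent_altered_or_undetectable']}% of {v['panel_size']})"
        )
        lines.append("")
    md_path.write_text("\n".join(lines))
    return json_path, md_path
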