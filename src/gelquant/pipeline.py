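"""End-to-end orchestration: simulate/load -> preprocess -> diff -> effects -> PCA -> report.

The pipeline is a thin composition of the stage functions; every
intermediate is written to the output directory as plain CSV, and all
randomness flows from one configured seed, so a run is reproducible
byte-for-byte from its config.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .bootstrap import pairwise_significance, results_to_frame
from .datatypes import AnalysisConfig, BootstrapSettings
from .effects import compute_effects, format_effects
from .errors import ConfigError
from .io import read_design, read_spot_table, write_design, write_spot_table
from .ordination import run_pca
from .preprocess import preprocess
from .reporting import AnalysisReport, render_report, summarize
from .simulate import GeneratorConfig, generate_dataset

log = logging.getLogger("gelquant")


@dataclass
class PipelineConfig:
    """Either a generator config (simulate stage) or input file paths."""

    generator: GeneratorConfig | None = None
    spot_table: Path | None = None
    design: Path | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    outdir: Path = Path("gelquant_out")
    seed: int | None = None
    pca_scale: bool = False

    def __post_init__(self) -> None:
        if self.generator is None and (self.spot_table is None or self.design is None):
            raise ConfigError(
                "either a generator config or spot_table+design files are required"
            )
        if self.generator is None:
            for p in (self.spot_table, self.design):
                if not Path(p).exists():
                    raise ConfigError(f"input file not found: {p}")
        if self.seed is not None:
            # one master seed drives both simulation and resampling
            if self.generator is not None:
                self.generator = dataclasses.replace(self.generator, seed=self.seed)
            self.analysis.bootstrap = dataclasses.replace(
                self.analysis.bootstrap, seed=self.seed
            )


def _config_echo(config: PipelineConfig) -> dict:
    echo = {
        "analysis": dataclasses.asdict(config.analysis),
        "seed": config.seed,
        "pca_scale": config.pca_scale,
    }
    if config.generator is not None:
        gen = dataclasses.asdict(config.generator)
        gen["groups"] = list(gen["groups"])
        gen["effect_log2_range"] = list(gen["effect_log2_range"])
        echo["generator"] = gen
    return echo


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Run every stage in order, writing intermediates to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    if config.generator is not None:
        table, design, truth = generate_dataset(config.generator)
        write_spot_table(table, outdir / "table.csv")
        write_design(design, outdir / "design.csv")
        truth.to_frame().to_csv(outdir / "truth.csv")
        log.info("simulate: %d spots x %d gels", table.n_spots, table.n_gels)
    else:
        table = read_spot_table(config.spot_table)
        design = read_design(config.design)
        log.info("load: %d spots x %d gels", table.n_spots, table.n_gels)

    normalized, presence = preprocess(table, design, config.analysis)
    write_spot_table(normalized, outdir / "filtered_normalized.csv")
    presence.counts.to_csv(outdir / "presence_counts.csv")
    log.info("preprocess: %d validated spots", normalized.n_spots)

    results = pairwise_significance(
        normalized, design, presence, config.analysis.bootstrap
    )
    results_to_frame(results).to_csv(outdir / "results.csv", index=False)
    n_sig = sum(r.significant for r in results)
    log.info("diff: %d significant spot-pair results", n_sig)

    effects = compute_effects(results)
    effects.table.to_csv(outdir / "effects.csv", index=False)
    format_effects(
        effects, config.analysis.round_fc, config.analysis.round_rc
    ).to_csv(outdir / "effects_formatted.csv")

    sig_spots = sorted({r.spot_id for r in results if r.significant})
    pca = None
    if len(sig_spots) >= 1:
        pca = run_pca(
            normalized.subset_spots(sig_spots), design, scale=config.pca_scale
        )
        pca.scores.to_csv(outdir / "pca_scores.csv", index_label="gel_id")
        pca.loadings.to_csv(outdir / "pca_loadings.csv", index_label="spot_id")
        import pandas as pd

        pd.DataFrame(
            {"variance_fraction": pca.variance_fraction},
            index=[f"PC{i + 1}" for i in range(len(pca.variance_fraction))],
        ).to_csv(outdir / "pca_variance.csv", index_label="component")

    report = summarize(presence, results, effects, pca, _config_echo(config))
    render_report(report, outdir)
    log.info("pipeline done in %.1fs", time.perf_counter() - t0)
    return report


def load_pipeline_config(path, seed: int | None = None,
                         outdir: str | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a TOML document.

    Recognised sections: ``[generator]``, ``[analysis]``,
    ``[analysis.bootstrap]``; top-level keys ``spot_table``, ``design``,
    ``outdir``, ``seed``, ``pca_scale``.  CLI ``seed``/``outdir`` override
    the file.
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    gen = None
    if "generator" in doc:
        g = dict(doc["generator"])
        if "groups" in g:
            g["groups"] = tuple(g["groups"])
        if "effect_log2_range" in g:
            g["effect_log2_range"] = tuple(g["effect_log2_range"])
        gen = GeneratorConfig(**g)
    analysis_kwargs = dict(doc.get("analysis", {}))
    boot = BootstrapSettings(**analysis_kwargs.pop("bootstrap", {}))
    analysis = AnalysisConfig(bootstrap=boot, **analysis_kwargs)
    return PipelineConfig(
        generator=gen,
        spot_table=doc.get("spot_table"),
        design=doc.get("design"),
        analysis=analysis,
        outdir=Path(outdir or doc.get("outdir", "gelquant_out")),
        seed=seed if seed is not None else doc.get("seed"),
        pca_scale=bool(doc.get("pca_scale", False)),
    )
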