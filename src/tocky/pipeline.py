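"""End-to-end pipeline orchestration and the run manifest.

``run_pipeline`` executes preprocess -> locus -> stats -> plots on an
experiment described by a :class:`RunConfig`, writing every table as CSV,
every figure as PNG, and a JSON manifest (config echo, seeds, package
versions) sufficient to reproduce the CSV outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import tocky
from tocky.io import Experiment, read_experiment_csvs
from tocky.locus import LocusScheme, locus_dynamics, locus_table, percent_matrix
from tocky.preprocess import preprocess_experiment, transformed_to_frame
from tocky.stats import chisq_global, parametric_locuswise, wilcoxon_locuswise

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one analysis run (CLI flags mirror these fields)."""

    sample_paths: list[str] = field(default_factory=list)
    negative_control_path: str = ""
    output_dir: str = "tocky_out"
    quantile: float = 1.0
    k: int = 5
    denominator: str = "parent"
    stats_method: str = "wilcoxon"  # wilcoxon | t_asr | t_logit
    adjust: str = "BH"
    logit_c: float = 0.001
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _versions() -> dict[str, str]:
    import matplotlib
    import numpy
    import scipy
    import statsmodels

    return {
        "tocky": tocky.__version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "matplotlib": matplotlib.__version__,
        "python": platform.python_version(),
    }


def run_pipeline(config: RunConfig, experiment: Experiment | None = None) -> Path:
    """Execute the full analysis and return the output directory.

    The experiment is loaded from ``config`` CSV paths unless given
    directly.  Any stage failure raises with the stage name; outputs
    written before the failure persist.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if experiment is None:
            if not config.sample_paths or not config.negative_control_path:
                raise ValueError("config must list sample_paths and negative_control_path")
            experiment = read_experiment_csvs(
                config.sample_paths, config.negative_control_path
            )

        stage = "preprocess"
        transformed = preprocess_experiment(experiment, quantile=config.quantile)
        transformed_to_frame(transformed).to_csv(out / "transformed.csv", index=False)

        stage = "locus"
        scheme = LocusScheme(k=config.k)
        tables = [locus_table(ts, scheme, denominator=config.denominator)
                  for ts in transformed]
        pd.concat([t.to_frame() for t in tables], ignore_index=True).to_csv(
            out / "locus_tables.csv", index=False
        )
        summary = locus_dynamics(tables)
        summary.to_csv(out / "locus_summary.csv", index=False)

        stage = "stats"
        groups = sorted({t.group_id for t in tables})
        comparison = None
        if len(groups) == 2:
            a = percent_matrix(tables, groups[0])
            b = percent_matrix(tables, groups[1])
            if config.stats_method == "wilcoxon":
                comparison = wilcoxon_locuswise(a, b, adjust=config.adjust,
                                                alpha=config.alpha)
            else:
                transform = config.stats_method.removeprefix("t_")
                comparison = parametric_locuswise(
                    a, b, transform=transform, adjust=config.adjust,
                    c=config.logit_c, alpha=config.alpha,
                )
            comparison.table.to_csv(out / "stats_locuswise.csv", index=False)
            counts_a = sum(t.counts for t in tables if t.group_id == groups[0])
            counts_b = sum(t.counts for t in tables if t.group_id == groups[1])
            chisq = chisq_global(counts_a.to_numpy(), counts_b.to_numpy(),
                                 labels=list(scheme.labels))
            chisq.table.to_csv(out / "stats_global.csv", index=False)
        else:
            logger.info("stats stage skipped: %d group(s) present", len(groups))

        stage = "plots"
        from tocky.plotting import plot_angle_density, plot_locus_dynamics, plot_timer_qc

        figures = plot_timer_qc(transformed, scheme, denominator=config.denominator,
                                seed=config.seed)
        for sid, fig in figures.items():
            fig.savefig(out / f"qc_{sid}.png", dpi=120)
        density_fig, _ = plot_angle_density(transformed)
        density_fig.savefig(out / "angle_density.png", dpi=120)
        dyn_fig = plot_locus_dynamics(summary, comparison)
        dyn_fig.savefig(out / "locus_dynamics.png", dpi=120)
        import matplotlib.pyplot as plt

        plt.close("all")

        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "versions": _versions(),
            "seeds": {"run": config.seed},
            "samples": experiment.groups.to_dict(orient="records"),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e
    return out
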