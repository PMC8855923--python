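"""Run configuration, end-to-end orchestration and figure generation.

A run is fully determined by its :class:`RunConfig` (paths, comparisons,
module settings, seed): running twice with the same resolved config yields
byte-identical result tables.  Figures are rendered from the emitted TSV
artifacts — never from in-memory state — so regeneration is a pure function
of the output directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from phoskin import io as pio  # noqa: E402
from phoskin.differential import heatmap_matrix, peptide_stats, select_top_peptides  # noqa: E402
from phoskin.kinetics import build_signal_matrix, qc_filter  # noqa: E402
from phoskin.mapping import build_map  # noqa: E402
from phoskin.uka import run_uka  # noqa: E402

logger = logging.getLogger("phoskin.pipeline")

DEFAULTS: dict = {
    "inputs": {
        "kinetic": None,
        "design": None,
        "scores": None,
        "invitro": None,
        "delimiter": "\t",
    },
    "comparisons": [],
    "signal": {"slope_scale": 100.0},
    "qc": {"min_r2": 0.8, "min_max_intensity": 5.0},
    "mapping": {"score_threshold": 300.0, "top_k": 12},
    "differential": {"n_top": 75, "rank_by": "t_stat"},
    "uka": {
        "B": 1000,
        "min_peptides": 3,
        "report_threshold": 1.5,
        "subsample_iters": 0,
    },
    "seed": 0,
    "outdir": "phoskin_out",
}


class ConfigError(ValueError):
    """Invalid or unknown run configuration."""


def _merge(defaults: dict, given: dict, path: str = "") -> dict:
    out = {}
    for key, default in defaults.items():
        here = f"{path}.{key}" if path else key
        if key in given:
            value = given[key]
            if isinstance(default, dict) and value is not None:
                if not isinstance(value, dict):
                    raise ConfigError(f"config key {here!r} must be a mapping")
                value = _merge(default, value, here)
            out[key] = value
        else:
            out[key] = default
    unknown = set(given) - set(defaults)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(f'{path}.{k}' if path else k for k in unknown)}"
        )
    return out


@dataclass
class RunConfig:
    """Validated, fully-resolved run configuration."""

    settings: dict = field(default_factory=lambda: _merge(DEFAULTS, {}))

    @classmethod
    def from_dict(cls, given: dict) -> "RunConfig":
        cfg = cls(_merge(DEFAULTS, given))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            given = yaml.safe_load(fh) or {}
        return cls.from_dict(given)

    def validate(self) -> None:
        s = self.settings
        comparisons = s["comparisons"]
        if not comparisons:
            raise ConfigError("at least one comparison is required")
        s["comparisons"] = [tuple(c) for c in comparisons]
        for c in s["comparisons"]:
            if len(c) != 2:
                raise ConfigError(f"comparison {c!r} must name exactly two groups")
        for key in ("kinetic", "design", "scores"):
            if s["inputs"][key] is None:
                raise ConfigError(f"inputs.{key} is required")

    def to_yaml(self, path) -> None:
        resolved = dict(self.settings)
        resolved["comparisons"] = [list(c) for c in resolved["comparisons"]]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(resolved, fh, sort_keys=True)

    def __getitem__(self, key):
        return self.settings[key]


def _comparison_tag(comparison: tuple[str, str]) -> str:
    return f"{comparison[0]}_vs_{comparison[1]}"


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Execute the full chip→kinases pipeline and write all artifacts.

    Per comparison this produces ``kinases_<g1>_vs_<g2>.tsv``,
    ``peptides_<g1>_vs_<g2>.tsv``, ``heatmap_matrix_<g1>_vs_<g2>.tsv`` and
    the figures; plus the resolved config and a run log.  Returns a dict of
    the in-memory tables keyed by comparison.
    """
    s = config.settings
    outdir = Path(outdir if outdir is not None else s["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("phoskin")
    prior_level = root.level
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        import phoskin

        logger.info("phoskin %s, seed %s", phoskin.__version__, s["seed"])
        sep = s["inputs"]["delimiter"]
        kinetic = pio.read_kinetic_table(s["inputs"]["kinetic"], sep=sep)
        design = pio.read_design(s["inputs"]["design"], s["comparisons"], sep=sep)
        scores = pio.read_score_table(s["inputs"]["scores"], sep=sep)
        invitro = (
            pio.read_invitro_targets(s["inputs"]["invitro"], sep=sep)
            if s["inputs"]["invitro"]
            else None
        )
        logger.info(
            "read %d kinetic rows, %d samples, %d peptides",
            len(kinetic.frame), len(kinetic.samples), len(kinetic.peptides),
        )

        base = build_signal_matrix(kinetic, slope_scale=s["signal"]["slope_scale"])
        results: dict[tuple[str, str], pd.DataFrame] = {}
        for comparison in s["comparisons"]:
            tag = _comparison_tag(comparison)
            samples = design.group_samples(comparison[0]) + design.group_samples(
                comparison[1]
            )
            matrix = qc_filter(
                base,
                samples=samples,
                min_r2=s["qc"]["min_r2"],
                min_max_intensity=s["qc"]["min_max_intensity"],
            )
            kmap = build_map(
                scores,
                invitro,
                chip_peptides=matrix.peptides,
                score_threshold=s["mapping"]["score_threshold"],
                top_k=s["mapping"]["top_k"],
            )
            kmap.to_tsv(outdir / f"kinase_map_{tag}.tsv")

            peptable = peptide_stats(matrix, design, comparison)
            peptable.to_csv(
                outdir / f"peptides_{tag}.tsv", sep="\t", index=False,
                float_format=pio.FLOAT_FORMAT,
            )
            selection = select_top_peptides(
                peptable, n=s["differential"]["n_top"], by=s["differential"]["rank_by"]
            )
            z, row_order, col_order = heatmap_matrix(matrix, selection)
            z.to_csv(
                outdir / f"heatmap_matrix_{tag}.tsv", sep="\t",
                index_label="peptide_id", float_format=pio.FLOAT_FORMAT,
            )

            table = run_uka(
                matrix,
                design,
                kmap,
                B=s["uka"]["B"],
                seed=s["seed"],
                min_peptides=s["uka"]["min_peptides"],
                report_threshold=s["uka"]["report_threshold"],
                subsample_iters=s["uka"]["subsample_iters"],
                comparisons=[comparison],
            )[tuple(comparison)]
            pio.write_results(table, outdir / f"kinases_{tag}.tsv")
            results[tuple(comparison)] = table

        config.to_yaml(outdir / "resolved_config.yaml")
        render_figures(outdir, comparisons=s["comparisons"])
    finally:
        root.removeHandler(handler)
        root.setLevel(prior_level)
        handler.close()
    return results


def _render_heatmap(z: pd.DataFrame, out_base: Path) -> None:
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * z.shape[1] + 2), max(4, 0.11 * z.shape[0] + 1))
    )
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_xticks(range(z.shape[1]), z.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(z.shape[0]), z.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="row z-score")
    ax.set_title("Top differentially regulated peptides")
    fig.tight_layout()
    for ext in ("png", "svg"):
        fig.savefig(f"{out_base}.{ext}", dpi=150)
    plt.close(fig)


def _render_kinase_bars(table: pd.DataFrame, out_base: Path) -> None:
    """Report-flagged kinases: kinase statistic (left axis) + specificity (right)."""
    flagged = table[table["report"]]
    if flagged.empty:
        flagged = table.head(10)
    fig, ax = plt.subplots(figsize=(max(5, 0.5 * len(flagged) + 2), 4))
    xs = range(len(flagged))
    ax.bar(xs, flagged["tau"], width=0.4, color="tab:blue", label="kinase statistic")
    ax.set_ylabel("mean kinase statistic (tau)", color="tab:blue")
    ax.axhline(0.0, color="black", lw=0.8)
    ax2 = ax.twinx()
    ax2.bar(
        [x + 0.4 for x in xs], flagged["specificity"], width=0.4,
        color="tab:orange", label="specificity",
    )
    ax2.set_ylabel("mean specificity score", color="tab:orange")
    ax.set_xticks([x + 0.2 for x in xs], flagged["kinase"], rotation=90, fontsize=8)
    ax.set_title("Report-flagged upstream kinases")
    fig.tight_layout()
    for ext in ("png", "svg"):
        fig.savefig(f"{out_base}.{ext}", dpi=150)
    plt.close(fig)


def render_figures(outdir, comparisons: list[tuple[str, str]] | None = None) -> list[Path]:
    """(Re)draw all figures from the TSV artifacts in ``outdir``."""
    outdir = Path(outdir)
    if comparisons is None:
        tags = [
            p.stem.removeprefix("kinases_") for p in sorted(outdir.glob("kinases_*.tsv"))
        ]
    else:
        tags = [_comparison_tag(tuple(c)) for c in comparisons]
    written = []
    for tag in tags:
        z = pd.read_csv(outdir / f"heatmap_matrix_{tag}.tsv", sep="\t", index_col=0)
        _render_heatmap(z, outdir / f"heatmap_{tag}")
        table = pio.read_results(outdir / f"kinases_{tag}.tsv")
        _render_kinase_bars(table, outdir / f"kinases_{tag}")
        written += [outdir / f"heatmap_{tag}.png", outdir / f"kinases_{tag}.png"]
    return written
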