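"""Reproducible report bundles for a full dyadic analysis.

``run_study_pipeline`` drives the whole analysis of one study from a single
config: descriptives and paired male-female comparisons, the correlation
matrix with significance stars, one APIM per outcome, and the four equality
constraint tests — every table written as TSV (human-readable formatting)
plus JSON (raw values) with a deterministic run manifest, so the bundle is
fully determined by (inputs, config, seed).

Numeric display follows the field's reporting style: 3 decimals for
correlations and standardized coefficients, 2 for t/z/chi-square, and p
rendered "<0.001" below threshold while the raw p survives in the JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .apim import APIMSpec, fit_apim
from .constraints import equality_tests_table, run_all_equality_tests
from .dyad_data import DyadTable, MomentSummary, moments_from_table, read_dyad_table
from .preliminary_stats import (
    correlation_report,
    correlation_report_from_summary,
    paired_t_from_summary,
    paired_t_raw,
)
from .simulate import SimulationConfig, simulate_dyads

__all__ = [
    "AnalysisConfig",
    "StageError",
    "run_study_pipeline",
    "render_tables",
    "format_table",
]

MODES = ("table", "summary", "simulate")
FORMATS = ("tsv", "json", "markdown")


class StageError(RuntimeError):
    """Failure in a named pipeline stage (stage name in ``.stage``)."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class AnalysisConfig:
    """Configuration of a full study analysis.

    Exactly one input mode is used: ``table`` (wide CSV path), ``summary``
    (moments JSON path) or ``simulate`` (a SimulationConfig dict).
    ``outcomes`` lists the outcome constructs to fit an APIM for (first one
    also gets the constraint tests).
    """

    mode: str
    data_path: str | None = None
    summary_path: str | None = None
    sim_config: dict | None = None
    x_var: str = "depression"
    y_var: str = "qol"
    outcomes: Sequence[str] = ("qol",)
    roles: tuple[str, str] = ("male", "female")
    chi_square_multiplier: str = "n_minus_1"
    constraint_scale: str = "unstandardized"
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "dyadkit_report"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        sources = {
            "table": self.data_path,
            "summary": self.summary_path,
            "simulate": self.sim_config,
        }
        if sources[self.mode] is None:
            raise ValueError(f"mode {self.mode!r} requires its input to be set")
        self.roles = tuple(self.roles)
        self.outcomes = list(self.outcomes)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "data_path": self.data_path,
            "summary_path": self.summary_path,
            "sim_config": self.sim_config,
            "x_var": self.x_var,
            "y_var": self.y_var,
            "outcomes": list(self.outcomes),
            "roles": list(self.roles),
            "chi_square_multiplier": self.chi_square_multiplier,
            "constraint_scale": self.constraint_scale,
            "alpha": self.alpha,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        return cls(**{k: v for k, v in d.items()})

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_FMT_3DP = ("beta", "se_beta", "r", "estimate", "se", "mean_se", "bias",
            "empirical_sd", "coverage", "truth", "mean_estimate")
_FMT_2DP = ("t", "z", "chi_sq_diff", "chi_square", "mean", "sd")
_P_COLS = ("p", "p_value")


def _fmt_p(p: float, threshold: float = 0.001) -> str:
    if pd.isna(p):
        return ""
    return f"<{threshold:g}" if p < threshold else f"{p:.3f}"


def format_table(df: pd.DataFrame) -> pd.DataFrame:
    """Display-formatted copy of a results table (strings)."""
    out = df.copy()
    for col in out.columns:
        base = col.lower()
        if base in _P_COLS or base.startswith("p_"):
            out[col] = df[col].map(_fmt_p)
        elif base in _FMT_2DP or any(base.startswith(x) for x in ("t_", "z_", "chi")):
            out[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
        elif base in _FMT_3DP or base.startswith(("beta", "r_", "se", "mean_", "sd_")):
            out[col] = df[col].map(
                lambda v: "" if pd.isna(v) else (f"{v:.3f}" if isinstance(v, float) else v)
            )
    return out


def _markdown(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def render_tables(
    results: Mapping[str, pd.DataFrame],
    fmt: str,
    out_dir: str | Path,
) -> list[Path]:
    """Write each named table in ``results`` to ``out_dir``.

    ``tsv`` and ``markdown`` apply the display formatting; ``json`` keeps
    raw values (records orientation) so the output re-parses to the
    in-memory results exactly.
    """
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {FORMATS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in results.items():
        if fmt == "json":
            path = out / f"{name}.json"
            path.write_text(df.to_json(orient="records", indent=1))
        elif fmt == "tsv":
            path = out / f"{name}.tsv"
            format_table(df).to_csv(path, sep="\t", index=False)
        else:
            path = out / f"{name}.md"
            path.write_text(_markdown(format_table(df)))
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _load_input(config: AnalysisConfig):
    """Returns (table | None, summary | None)."""
    if config.mode == "table":
        return read_dyad_table(config.data_path, role_labels=config.roles), None
    if config.mode == "summary":
        return None, MomentSummary.from_json(config.summary_path)
    sim = SimulationConfig.from_dict({**config.sim_config, "seed": config.seed,
                                      "roles": tuple(config.roles)})
    return simulate_dyads(sim), None


def _paired_rows(config, table, summary) -> pd.DataFrame:
    rows = []
    r0, r1 = config.roles
    for var in [config.x_var, *config.outcomes]:
        cols = (f"{var}_{r0}", f"{var}_{r1}")
        if table is not None:
            pc = paired_t_raw(table.data[cols[0]], table.data[cols[1]])
        else:
            sub = summary.subset(cols)
            pc = paired_t_from_summary(
                sub.means[0], sub.sds[0], sub.means[1], sub.sds[1],
                sub.correlations[0, 1], sub.n,
            )
        rows.append({
            "variable": var,
            f"mean_{r0}": pc.mean_a, f"sd_{r0}": pc.sd_a,
            f"mean_{r1}": pc.mean_b, f"sd_{r1}": pc.sd_b,
            "r_pair": pc.r_ab, "t": pc.t, "df": pc.df, "p": pc.p,
        })
    return pd.DataFrame(rows)


def _all_variables(config) -> list[str]:
    r0, r1 = config.roles
    return [f"{v}_{r}" for v in [config.x_var, *config.outcomes] for r in (r0, r1)]


def run_study_pipeline(config: AnalysisConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis and write the report bundle.

    Returns the result tables in memory (keys ``paired_comparisons``,
    ``correlations``, ``correlation_p``, ``apim_effects``,
    ``constraint_tests``) and writes each as TSV + JSON to
    ``config.out_dir`` along with ``manifest.json``.  Any stage failure is
    re-raised as :class:`StageError` carrying the stage name.
    """
    results: dict[str, pd.DataFrame] = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as e:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, e) from e

    table, summary = stage("load_input", lambda: _load_input(config))

    results["paired_comparisons"] = stage(
        "paired_comparisons", lambda: _paired_rows(config, table, summary))

    def _corr():
        if table is not None:
            rep = correlation_report(table, _all_variables(config))
        else:
            rep = correlation_report_from_summary(summary.subset(_all_variables(config)))
        r = rep.r.copy()
        r.insert(0, "variable", r.index)
        p = rep.p.copy()
        p.insert(0, "variable", p.index)
        stars = rep.stars.copy()
        stars.insert(0, "variable", stars.index)
        return r.reset_index(drop=True), p.reset_index(drop=True), stars.reset_index(drop=True)

    results["correlations"], results["correlation_p"], results["correlation_stars"] = (
        stage("correlation_report", _corr))

    def _apim():
        rows = []
        fits = {}
        for outcome in config.outcomes:
            spec = APIMSpec(x_var=config.x_var, y_var=outcome,
                            roles=config.roles,
                            chi_square_multiplier=config.chi_square_multiplier)
            fit = fit_apim(table if table is not None else summary, spec)
            fits[outcome] = fit
            tab = fit.path_table()
            tab.insert(0, "outcome", outcome)
            rows.append(tab)
        return pd.concat(rows, ignore_index=True), fits

    results["apim_effects"], fits = stage("apim_fits", _apim)

    def _constraints():
        tests = run_all_equality_tests(
            table if table is not None else summary,
            APIMSpec(x_var=config.x_var, y_var=config.outcomes[0],
                     roles=config.roles,
                     chi_square_multiplier=config.chi_square_multiplier),
            scale=config.constraint_scale, seed=config.seed,
        )
        return equality_tests_table(tests, alpha=config.alpha)

    results["constraint_tests"] = stage("constraint_tests", _constraints)

    def _write():
        out = Path(config.out_dir)
        render_tables(results, "tsv", out)
        render_tables(results, "json", out)
        n = fits[config.outcomes[0]].n
        # out_dir is where the bundle lands, not part of the analysis identity
        cfg_dict = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
        cfg_json = json.dumps(cfg_dict, sort_keys=True)
        manifest = {
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": config.seed,
            "dyadkit_version": __version__,
            "n_dyads_after_listwise": int(n),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    stage("write_bundle", _write)
    return results
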