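"""Reading trial streams, writing result tables, configuration, pipeline.

Trial-stream CSV dialect: comma-delimited UTF-8 with header
``participant,trial,stimulus,response,correct,rt_ms``; stimulus/response in
{R, L}; correct in {0, 1}.  Correctness is recomputed from stimulus and
response on ingest and cross-checked against the file's column; mismatches
are logged with their row numbers and the recomputed value wins.

All output tables are tab-separated with a header row and 6-decimal
numeric formatting, and each table gets a provenance JSON sidecar (resolved
config, seed, package version, config hash) so a run can be reproduced from
its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import (
    DEFAULT_A,
    DEFAULT_K,
    DEFAULT_N_AVG,
    DEFAULT_N_ITER,
    DEFAULT_N_KEEP,
    BifurcationSurface,
    Staircase,
    bifurcation_surface,
    devils_staircase,
)
from .farey import FareyTree, build_tree
from .scan import DEFAULT_BOUNDS, analyze_streams
from .stats import denominator_regression, spearman_farey_test, staircase_test
from .synth import GeneratorConfig, generate_streams

__all__ = [
    "RunConfig",
    "read_trials",
    "write_trials",
    "write_staircase",
    "write_tree",
    "write_surface",
    "write_history_stats",
    "write_reports",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6f"


def _float_fmt(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
    return out


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    _float_fmt(df).to_csv(path, sep="\t", index=False)


def _provenance(path: Path, config: dict, seed: int | None) -> None:
    blob = json.dumps(config, sort_keys=True, default=str)
    sidecar = {
        "config": config,
        "seed": seed,
        "version": __version__,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    path.with_suffix(path.suffix + ".provenance.json").write_text(
        json.dumps(sidecar, indent=2, default=str) + "\n"
    )


def read_trials(path, drop_first_n: int = 0) -> pd.DataFrame:
    """Read and validate a trial-stream CSV.

    ``drop_first_n`` removes that many leading (buffer) trials from each
    participant before analysis.  Trial indices are re-based to 0..n-1 per
    participant after dropping.
    """
    df = pd.read_csv(path)
    required = ["participant", "trial", "stimulus", "response", "correct", "rt_ms"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trial stream {path}: missing columns {missing}")
    for col in ("stimulus", "response"):
        bad = df.loc[~df[col].isin(["R", "L"])]
        if not bad.empty:
            rows = (bad.index + 2).tolist()[:10]  # header is line 1
            raise ValueError(
                f"trial stream {path}: non-R/L codes in {col!r} at lines {rows}"
            )
    if (df["rt_ms"] <= 0).any():
        raise ValueError(f"trial stream {path}: non-positive response times")
    recomputed = (df["stimulus"] == df["response"]).astype(int)
    mismatch = df.index[recomputed != df["correct"].astype(int)]
    if len(mismatch):
        logger.warning(
            "correct column disagrees with stimulus/response at lines %s; "
            "recomputed values used",
            (mismatch + 2).tolist()[:20],
        )
    df = df.assign(correct=recomputed)
    parts = []
    for pid, grp in df.groupby("participant", sort=True):
        grp = grp.sort_values("trial").iloc[drop_first_n:].reset_index(drop=True)
        grp["trial"] = np.arange(len(grp))
        parts.append(grp)
    return pd.concat(parts, ignore_index=True)


def write_trials(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_staircase(staircase: Staircase, path) -> None:
    _write_tsv(
        pd.DataFrame({"omega": staircase.omegas, "rho": staircase.rhos}), Path(path)
    )


def write_surface(surface: BifurcationSurface, path) -> None:
    n_keep = surface.phases.shape[1]
    df = pd.DataFrame(
        {
            "omega": np.repeat(surface.omegas, n_keep),
            "phase_index": np.tile(np.arange(n_keep), surface.omegas.size),
            "phase": surface.phases.ravel(),
            "circular_mean": np.repeat(surface.circular_means, n_keep),
        }
    )
    _write_tsv(df, Path(path))


def write_tree(tree: FareyTree, path) -> None:
    df = pd.DataFrame(
        {
            "level": [n.level for n in tree.nodes],
            "history": [n.history for n in tree.nodes],
            "numerator": [n.ratio.numerator for n in tree.nodes],
            "denominator": [n.ratio.denominator for n in tree.nodes],
            "omega": [n.omega for n in tree.nodes],
            "binary_rank": [n.binary_rank for n in tree.nodes],
        }
    )
    _write_tsv(df, Path(path))


def write_history_stats(df: pd.DataFrame, path) -> None:
    _write_tsv(df, Path(path))


def write_reports(reports: list, path) -> None:
    rows = [r.as_dict() for r in reports]
    _write_tsv(pd.DataFrame(rows), Path(path))


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration for a full pipeline run."""

    # circle map
    K: float = DEFAULT_K
    A: float = DEFAULT_A
    omega_min: float = 0.0
    omega_max: float = 1.0
    omega_step: float = 0.001
    n_iter: int = DEFAULT_N_ITER
    n_avg: int = DEFAULT_N_AVG
    n_keep: int = DEFAULT_N_KEEP
    n_omega: int = 1000
    # scan
    depth: int = 5
    rt_min: float = DEFAULT_BOUNDS[0]
    rt_max: float = DEFAULT_BOUNDS[1]
    mode: str = "terminal"
    l_leading: bool = False
    drop_first_n: int = 0
    # input: path to a trial CSV, or None to simulate
    trials: str | None = None
    synth: dict = dataclasses.field(default_factory=dict)
    seed: int = 0
    outdir: str = "fareyrt_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def __post_init__(self) -> None:
        if self.mode not in ("terminal", "all"):
            raise ValueError(f"mode must be 'terminal' or 'all', got {self.mode!r}")
        if not self.rt_min < self.rt_max:
            raise ValueError("rt_min must be < rt_max")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_avg > self.n_iter or self.n_keep > self.n_iter:
            raise ValueError("n_avg and n_keep must not exceed n_iter")


def run_pipeline(config: RunConfig) -> Path:
    """Run staircase -> tree -> scan -> stats, writing all artifacts.

    Deterministic given ``config.seed``.  Returns the output directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    rng = np.random.default_rng(config.seed)

    n_steps = int(round((config.omega_max - config.omega_min) / config.omega_step))
    grid = np.linspace(config.omega_min, config.omega_max, n_steps + 1)
    staircase = devils_staircase(
        config.K, config.A, omega_grid=grid,
        n_iter=config.n_iter, n_avg=config.n_avg, rng=rng,
    )
    write_staircase(staircase, outdir / "staircase.tsv")
    _provenance(outdir / "staircase.tsv", cfg_dict, config.seed)

    tree = build_tree(config.depth)
    write_tree(tree, outdir / "farey_tree.tsv")
    _provenance(outdir / "farey_tree.tsv", cfg_dict, config.seed)

    if config.trials is not None:
        streams = read_trials(config.trials, drop_first_n=config.drop_first_n)
    else:
        synth_cfg = GeneratorConfig(**{"seed": config.seed, **config.synth})
        streams = generate_streams(synth_cfg, staircase=staircase, tree=tree)
        write_trials(streams, outdir / "trials.csv")
        _provenance(outdir / "trials.csv", cfg_dict, config.seed)

    per_part, grand = analyze_streams(
        streams, depth=config.depth, bounds=(config.rt_min, config.rt_max),
        mode=config.mode, l_leading=config.l_leading, tree=tree,
    )
    write_history_stats(per_part, outdir / "history_stats_per_participant.tsv")
    write_history_stats(grand, outdir / "history_stats_grand.tsv")
    _provenance(outdir / "history_stats_grand.tsv", cfg_dict, config.seed)

    r_grand = grand.loc[~grand["history"].str.startswith("L")]
    norm_means = r_grand.set_index("history")["norm_mean"]
    error_rates = r_grand.set_index("history")["error_rate"]
    reports = [staircase_test(norm_means, staircase, tree)]
    try:
        reports.append(spearman_farey_test(error_rates, tree))
        slope, dr = denominator_regression(error_rates, tree)
        reports.append(dr)
        logger.info("denominator regression slope: %.6g per denominator unit", slope)
    except ValueError as exc:  # e.g. all-zero error rates
        logger.warning("error-rate tests skipped: %s", exc)
    write_reports(reports, outdir / "reports.tsv")
    _provenance(outdir / "reports.tsv", cfg_dict, config.seed)
    logger.info("pipeline outputs written to %s", outdir)
    return outdir
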