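"""CSV/JSON formats, run configuration, and the pipeline orchestrator.

Counts travel as wide CSV: a ``year`` column plus one integer column per
species. Site metadata (continent, per-species guild) lives in a YAML
config. Every artifact written by the pipeline records the seed it was
generated from, so outputs are regenerable from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import CommunityCounts
from .first_stage import McmcConfig, fit_community, summarize
from .second_stage import build_design, fit_mixed_model
from .variability import population_variability

__all__ = [
    "RunConfig",
    "read_counts_csv",
    "read_counts_csv_long",
    "write_counts_csv",
    "pv_table",
    "run_pipeline",
]

logger = logging.getLogger("commvar")

try:
    __version__ = version("commvar")
except PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"


def read_counts_csv(
    path: str | Path,
    guild: dict[str, str] | list[str] | None = None,
    site: str | None = None,
    continent: str = "Europe",
) -> CommunityCounts:
    """Read a wide counts CSV (year column + one column per species)."""
    path = Path(path)
    df = pd.read_csv(path)
    if "year" not in df.columns:
        raise ValueError(f"{path}: missing required 'year' column")
    species = [c for c in df.columns if c != "year"]
    if not species:
        raise ValueError(f"{path}: no species columns")
    years = df["year"].to_numpy()
    dup = pd.Series(years)[pd.Series(years).duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate year {int(dup.iloc[0])}")
    if np.any(np.diff(years) != 1):
        gap = int(years[np.flatnonzero(np.diff(years) != 1)[0]])
        raise ValueError(f"{path}: years not contiguous after {gap}")
    for row, (_, rec) in enumerate(df.iterrows(), start=2):
        for sp in species:
            v = rec[sp]
            if pd.isna(v):
                raise ValueError(f"{path}: missing cell for {sp} at line {row}")
            if v < 0:
                raise ValueError(f"{path}: negative count for {sp} at line {row}")
            if float(v) != int(v):
                raise ValueError(f"{path}: non-integer count for {sp} at line {row}")
    counts = df[species].to_numpy(dtype=np.int64)
    if isinstance(guild, dict):
        guild_list = [guild.get(sp, "dabbling") for sp in species]
    elif guild is not None:
        guild_list = list(guild)
    else:
        guild_list = ["dabbling"] * len(species)
    return CommunityCounts(
        counts=counts,
        years=years.astype(np.int64),
        species=species,
        guild=guild_list,
        site=site if site is not None else path.stem,
        continent=continent,
    )


def read_counts_csv_long(
    path: str | Path,
    guild: dict[str, str] | None = None,
    site: str | None = None,
    continent: str = "Europe",
) -> CommunityCounts:
    """Convenience alias for long format (year, species, count columns)."""
    df = pd.read_csv(path)
    need = {"year", "species", "count"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: long format needs columns {sorted(need)}")
    wide = df.pivot(index="year", columns="species", values="count").reset_index()
    tmp = Path(path).with_suffix(".wide.tmp.csv")
    try:
        wide.to_csv(tmp, index=False)
        return read_counts_csv(tmp, guild=guild, site=site or Path(path).stem, continent=continent)
    finally:
        tmp.unlink(missing_ok=True)


def write_counts_csv(counts: CommunityCounts, path: str | Path) -> Path:
    """Write a CommunityCounts to wide CSV; round-trips losslessly."""
    path = Path(path)
    df = pd.DataFrame(counts.counts, columns=counts.species)
    df.insert(0, "year", counts.years)
    df.to_csv(path, index=False)
    return path


def pv_table(communities: list[CommunityCounts]) -> pd.DataFrame:
    """Per-species PV plus guild x continent group means and standard errors."""
    rows = []
    for comm in communities:
        for i, sp in enumerate(comm.species):
            rows.append(
                {
                    "site": comm.site,
                    "continent": comm.continent,
                    "species": sp,
                    "guild": comm.guild[i],
                    "pv": population_variability(comm.counts[:, i].astype(float)),
                }
            )
    return pd.DataFrame(rows)


def pv_group_means(table: pd.DataFrame) -> pd.DataFrame:
    g = table.groupby(["continent", "guild"])["pv"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    out["se"] = out["std"] / np.sqrt(out["count"])
    return out.drop(columns="std")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    input_paths: list[str] = field(default_factory=list)
    continent_by_site: dict[str, str] = field(default_factory=dict)
    guild_by_species: dict[str, str] = field(default_factory=dict)
    stages: list[str] = field(default_factory=lambda: ["fit", "pv", "compare"])
    factor: str = "continent"
    parameter: str = "C_ii"
    mode: str | None = None
    output_dir: str = "out"
    seed: int = 0
    chains: int = 4
    iterations: int = 20000
    burn_in: int = 10000
    thin: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def mcmc(self) -> McmcConfig:
        return McmcConfig(
            chains=self.chains,
            iterations=self.iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
        )


def run_pipeline(config: RunConfig) -> Path:
    """Filter -> fit per site -> summarize -> compare; artifacts on disk.

    Returns the output directory. Every file records the seed and package
    version; non-convergence flags propagate into the final report.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("commvar %s seed=%d", __version__, config.seed)
        communities = []
        for path in config.input_paths:
            comm = read_counts_csv(
                path,
                guild=config.guild_by_species,
                continent=config.continent_by_site.get(Path(path).stem, "Europe"),
            )
            communities.append(comm)
        if not communities:
            raise ValueError("pipeline: no input files configured")

        if "pv" in config.stages:
            table = pv_table(communities)
            table.to_csv(outdir / "pv_by_species.csv", index=False)
            pv_group_means(table).to_csv(outdir / "pv_group_means.csv", index=False)

        summaries = []
        posteriors = []
        if "fit" in config.stages:
            for comm in communities:
                try:
                    post = fit_community(comm, config.mcmc())
                except Exception as exc:
                    raise RuntimeError(f"stage 'fit' failed at site {comm.site}: {exc}") from exc
                posteriors.append(post)
                post.save_draws(outdir / f"draws_{comm.site}.npz")
                for pname in ("C_ii", "I", "Prop(I)"):
                    summaries.extend(summarize(post, pname))
            rows = [
                {
                    "site": s.site,
                    "species": s.species,
                    "guild": s.guild,
                    "continent": s.continent,
                    "parameter": s.parameter,
                    "mean": s.posterior_mean,
                    "sd": s.posterior_sd,
                }
                for s in summaries
            ]
            pd.DataFrame(rows).to_csv(outdir / "stage1_summaries.csv", index=False)
            diag = [
                {
                    "site": post.site,
                    "converged": post.converged,
                    "max_rhat": max(post.rhat.values()) if post.rhat else 1.0,
                }
                for post in posteriors
            ]
            pd.DataFrame(diag).to_csv(outdir / "stage1_convergence.csv", index=False)

        if "compare" in config.stages:
            if not summaries:
                raise RuntimeError("stage 'compare' requires stage 'fit' results")
            rows = []
            sel = [s for s in summaries if s.parameter == config.parameter]
            try:
                design = build_design(sel, factor=config.factor, mode=config.mode)
                result = fit_mixed_model(design, config.mcmc())
            except Exception as exc:
                raise RuntimeError(f"stage 'compare' failed: {exc}") from exc
            rows.append(
                {
                    "parameter": config.parameter,
                    "factor": config.factor,
                    "mean": result.beta_mean,
                    "sd": result.beta_sd,
                    "rhat": max(result.rhat.values()),
                    "p": result.p,
                    "seed": config.seed,
                }
            )
            pd.DataFrame(rows).to_csv(outdir / "comparison.csv", index=False)

        meta = dataclasses.asdict(config)
        meta["commvar_version"] = __version__
        (outdir / "run_meta.json").write_text(json.dumps(meta, indent=2))
        logger.info("pipeline complete")
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outdir
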