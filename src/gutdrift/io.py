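"""File I/O, run configuration, and the end-to-end analysis pipeline.

The pipeline stitches the stages together the way the experimental analysis
runs them: family aggregation (optional) -> focal subsetting -> relativizing
-> per-sample diversity -> copy-number scaling -> Bray-Curtis -> group
dispersion -> null-model beta-deviation.  Outputs are plain CSV/JSON with
'.' decimals, UTF-8 and LF line endings so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import gutdrift
from gutdrift.community import (
    CountTable,
    aggregate_taxa,
    bray_curtis,
    copy_scale,
    diversity_table,
    relativize,
    subset_focal,
    validate_metadata,
)
from gutdrift.dispersion import group_dispersion
from gutdrift.nullmodel import TaxonPool, beta_deviation, deviation_frame
from gutdrift.simulate import AssemblyParams, simulate_study

_CSV_KW = dict(lineterminator="\n", index=False)


def read_count_table(path: str | Path, unit_tag: str = "reads") -> CountTable:
    """Read a TSV count table (first column ``sample_id``, one column per
    taxon) into a validated :class:`CountTable`.

    Errors name the offending cell: non-numeric values, negative values and
    duplicate labels are all rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise ValueError(
            f"first column must be 'sample_id', got {df.columns[0]!r}"
        )
    df = df.set_index("sample_id")
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(
                f"non-numeric value in column {col!r}, sample {bad!r}"
            ) from None
        neg = out.index[out[col] < 0]
        if len(neg):
            raise ValueError(
                f"negative value in column {col!r}, sample {neg[0]!r}"
            )
    return CountTable(out, unit_tag=unit_tag)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-sample metadata TSV."""
    return validate_metadata(pd.read_csv(path, sep="\t"))


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of (``counts_path`` + ``metadata_path``) or ``sim_params``
    must be set; a seed is mandatory because the null model is stochastic.
    """

    counts_path: str | None = None
    metadata_path: str | None = None
    sim_params: dict | None = None
    focal: list | None = None
    aggregation: dict | None = None
    group_keys: tuple = ("immigration_level", "instar")
    sqrt_dist: bool = True
    bias_adjust: bool = True
    center: str = "spatial_median"
    n_reps: int = 1000
    seed: int = 0
    outdir: str = "gutdrift_run"

    def __post_init__(self) -> None:
        has_files = self.counts_path is not None and self.metadata_path is not None
        has_sim = self.sim_params is not None
        if has_files == has_sim:
            raise ValueError(
                "exactly one of (counts_path + metadata_path) or sim_params "
                "must be provided"
            )
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "group_keys" in raw:
            raw["group_keys"] = tuple(raw["group_keys"])
        return cls(**raw)


def _group_label(row: pd.Series, keys: tuple) -> str:
    return "|".join(f"{row[k]:g}" if isinstance(row[k], float) else str(row[k]) for k in keys)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis chain and write the run directory.

    Writes ``diversity.csv``, ``dispersion.csv``, ``deviation.csv``,
    ``taxon_stage_means.csv``, ``model_input.csv``, ``exclusions.log`` and
    ``run_manifest.json``; returns the tables as DataFrames.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exclusions: list[tuple[str, str]] = []

    if config.sim_params is not None:
        params = AssemblyParams(**{**config.sim_params, "seed": config.seed})
        study = simulate_study(params)
        table, meta = study.counts, study.metadata
        study.write(outdir / "simulated")
    else:
        table = read_count_table(config.counts_path)
        meta = read_metadata(config.metadata_path)
    meta = validate_metadata(meta.reset_index(), table)

    if config.aggregation:
        table = aggregate_taxa(table, config.aggregation)
    focal = config.focal or [t for t in table.taxon_ids if t != "unassigned"]
    table, excluded = subset_focal(table, focal)
    exclusions += [(s, "zero focal abundance") for s in excluded]
    meta = meta.loc[table.sample_ids]

    rel = relativize(table)
    diversity = diversity_table(rel, meta["copy_number"]).reset_index()
    scaled = copy_scale(rel, meta["copy_number"])
    zero_cn = [s for s in scaled.sample_ids if meta.loc[s, "copy_number"] == 0]
    if zero_cn:
        exclusions += [(s, "zero copy_number") for s in zero_cn]
        keep = [s for s in scaled.sample_ids if s not in zero_cn]
        rel = CountTable(rel.data.loc[keep], unit_tag="relative")
        scaled = CountTable(scaled.data.loc[keep], unit_tag="copy_scaled")
    groups = {
        str(s): _group_label(meta.loc[s], config.group_keys)
        for s in rel.sample_ids
    }

    dm = bray_curtis(rel)
    disp = group_dispersion(
        dm,
        groups,
        sqrt_dist=config.sqrt_dist,
        bias=config.bias_adjust,
        center=config.center,
    )
    disp_frame = disp.to_frame()
    group_meta = (
        pd.DataFrame(
            {
                "group": list(groups.values()),
                **{
                    k: [meta.loc[s, k] for s in rel.sample_ids]
                    for k in config.group_keys
                },
            }
        )
        .drop_duplicates("group")
        .reset_index(drop=True)
    )
    disp_frame = group_meta.merge(disp_frame, on="group", how="right")

    pools = {
        g: TaxonPool.equal(rel.taxon_ids, total_density=0.0)
        for g in set(groups.values())
    }
    dev = beta_deviation(
        scaled,
        groups,
        pools,
        n_reps=config.n_reps,
        seed=config.seed,
        sqrt_dist=config.sqrt_dist,
        bias=config.bias_adjust,
    )
    dev_frame = group_meta.merge(deviation_frame(dev), on="group", how="right")

    stage_means = (
        rel.data.assign(instar=[meta.loc[s, "instar"] for s in rel.sample_ids])
        .groupby("instar")
        .mean()
        .mul(100)  # percent relative abundance
        .reset_index()
    )

    sample_dist = disp.sample_frame()
    model_input = (
        diversity.merge(
            meta.reset_index()[
                ["sample_id", *config.group_keys, "plant_id", "lineage_id"]
            ],
            on="sample_id",
        )
        .assign(group=lambda d: d["sample_id"].map(groups))
        .merge(sample_dist[["sample_id", "distance"]], on="sample_id", how="left")
        .merge(
            dev_frame[["group", "observed_beta", "ses"]], on="group", how="left"
        )
    )

    diversity.to_csv(outdir / "diversity.csv", **_CSV_KW)
    disp_frame.to_csv(outdir / "dispersion.csv", **_CSV_KW)
    dev_frame.to_csv(outdir / "deviation.csv", **_CSV_KW)
    stage_means.to_csv(outdir / "taxon_stage_means.csv", **_CSV_KW)
    model_input.to_csv(outdir / "model_input.csv", **_CSV_KW)
    with open(outdir / "exclusions.log", "w") as fh:
        for sid, reason in exclusions:
            fh.write(f"{sid}\t{reason}\n")
    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "versions": {
            "gutdrift": gutdrift.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return {
        "diversity": diversity,
        "dispersion": disp_frame,
        "deviation": dev_frame,
        "stage_means": stage_means,
        "model_input": model_input,
        "exclusions": exclusions,
    }


def relative_change(a: float, b: float) -> float:
    """Percent change from ``a`` to ``b``: 100 * (b - a) / a.

    Both arguments are on the percent scale (mean relative abundances);
    reports round to the nearest integer percent.
    """
    if a <= 0:
        raise ValueError("baseline value must be > 0")
    return 100.0 * (b - a) / a
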