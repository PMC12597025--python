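"""Count-table transformations, Hill diversity, and Bray-Curtis dissimilarity.

The analysis universe is a samples x taxa abundance table.  Samples are
individual hosts (caterpillar midguts); taxa are bacterial families after
aggregation.  Abundances may be sequencing reads, relative proportions, or
qPCR-scaled absolute abundances; the ``unit_tag`` tracks which.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)

#: allowed states for CountTable.unit_tag
UNIT_TAGS = ("reads", "relative", "copy_scaled")

_REL_TOL = 1e-9


@dataclass
class CountTable:
    """Samples x taxa abundance matrix with a unit tag.

    Parameters
    ----------
    data :
        DataFrame with sample ids as the index and taxon/family labels as
        columns.  Values must be nonnegative.
    unit_tag :
        One of ``reads`` (raw counts or CFU-equivalents), ``relative``
        (rows sum to 1), or ``copy_scaled`` (relative abundances multiplied
        by per-sample 16S copy number, i.e. absolute abundance estimates).
    """

    data: pd.DataFrame
    unit_tag: str = "reads"

    def __post_init__(self) -> None:
        if self.unit_tag not in UNIT_TAGS:
            raise ValueError(
                f"unit_tag must be one of {UNIT_TAGS}, got {self.unit_tag!r}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.data.index[i]!r}, "
                f"taxon {self.data.columns[j]!r}"
            )
        if np.isnan(values).any():
            raise ValueError("abundance table contains missing values")
        if self.unit_tag == "relative":
            sums = values.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > _REL_TOL)
            if bad.size:
                raise ValueError(
                    f"relative table rows must sum to 1 within {_REL_TOL}; "
                    f"offending sample {self.data.index[bad[0]]!r} sums to "
                    f"{sums[bad[0]]!r}"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]


def validate_metadata(meta: pd.DataFrame, table: CountTable | None = None) -> pd.DataFrame:
    """Validate a per-sample metadata frame.

    Expects the index (or a ``sample_id`` column) to hold sample ids and the
    columns ``immigration_level``, ``instar``, ``plant_id``, ``lineage_id``,
    ``copy_number``.  Copy numbers and immigration levels must be >= 0.
    When a :class:`CountTable` is supplied, every sample in it must have
    exactly one metadata record.
    """
    meta = meta.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate metadata records for samples: {dups}")
    required = ["immigration_level", "instar", "plant_id", "lineage_id", "copy_number"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing columns: {missing}")
    for col in ("immigration_level", "copy_number"):
        vals = pd.to_numeric(meta[col], errors="raise")
        if (vals < 0).any():
            bad = meta.index[vals < 0][0]
            raise ValueError(f"{col} must be >= 0 (sample {bad!r})")
        meta[col] = vals
    if table is not None:
        absent = [s for s in table.sample_ids if s not in meta.index]
        if absent:
            raise ValueError(f"samples without metadata: {absent}")
    return meta


def aggregate_taxa(
    table: CountTable,
    mapping: Mapping[str, str],
    policy: str = "bucket",
    bucket_label: str = "unassigned",
) -> CountTable:
    """Aggregate taxa into higher-level groups (e.g. ASVs to families).

    Each output column is the per-sample sum over its member taxa, so
    per-sample totals are conserved.  Taxa absent from ``mapping`` go to the
    ``bucket_label`` group under ``policy='bucket'`` (the default) or raise
    under ``policy='strict'``.
    """
    if policy not in ("bucket", "strict"):
        raise ValueError(f"policy must be 'bucket' or 'strict', got {policy!r}")
    unmapped = [t for t in table.taxon_ids if t not in mapping]
    if unmapped and policy == "strict":
        raise ValueError(f"unmapped taxon {unmapped[0]!r} under strict policy")
    groups = [mapping.get(t, bucket_label) for t in table.taxon_ids]
    out = table.data.T.groupby(pd.Index(groups, name="group"), sort=False).sum().T
    return CountTable(out, unit_tag=table.unit_tag)


def subset_focal(
    table: CountTable, focal: Iterable[str]
) -> tuple[CountTable, list]:
    """Restrict the table to the focal taxa.

    Samples whose focal counts are all zero cannot enter relative-abundance
    analyses; they are dropped and their ids returned (and logged) so the
    exclusion is auditable.

    Returns
    -------
    (subset, excluded) :
        The focal-only table and the list of excluded sample ids.
    """
    focal = list(focal)
    if not focal:
        raise ValueError("focal taxon set is empty")
    absent = [t for t in focal if t not in table.data.columns]
    if absent:
        raise ValueError(f"focal taxa absent from table: {absent}")
    sub = table.data.loc[:, focal]
    zero = sub.sum(axis=1) == 0
    excluded = list(sub.index[zero])
    if excluded:
        logger.warning(
            "excluding %d sample(s) with zero focal abundance: %s",
            len(excluded),
            excluded,
        )
        sub = sub.loc[~zero]
    return CountTable(sub, unit_tag=table.unit_tag), excluded


def relativize(table: CountTable) -> CountTable:
    """Convert each row to relative abundances (rows sum to 1).

    All-zero rows are an error: route them through :func:`subset_focal`,
    whose exclusion policy removes them with a logged reason.
    """
    sums = table.data.sum(axis=1)
    if (sums == 0).any():
        bad = sums.index[sums == 0][0]
        raise ValueError(
            f"sample {bad!r} has zero total abundance; exclude it via "
            "subset_focal before relativizing"
        )
    rel = table.data.div(sums, axis=0)
    return CountTable(rel, unit_tag="relative")


def copy_scale(table: CountTable, copy_number: pd.Series | pd.DataFrame) -> CountTable:
    """Scale relative abundances to absolute abundances via qPCR copy number.

    Each relative-abundance row is multiplied by that sample's total 16S
    rRNA copy number, so the per-sample total equals the qPCR estimate of
    community size.
    """
    if table.unit_tag != "relative":
        raise ValueError("copy_scale expects a relative-abundance table")
    if isinstance(copy_number, pd.DataFrame):
        if "copy_number" not in copy_number.columns:
            raise ValueError("metadata frame lacks a copy_number column")
        copy_number = copy_number["copy_number"]
    missing = [s for s in table.sample_ids if s not in copy_number.index]
    if missing:
        raise ValueError(f"missing copy_number for sample {missing[0]!r}")
    cn = copy_number.reindex(table.data.index).astype(float)
    if (cn < 0).any():
        bad = cn.index[cn < 0][0]
        raise ValueError(f"copy_number must be >= 0 (sample {bad!r})")
    if (cn == 0).any():
        logger.warning(
            "copy_number is 0 for sample(s) %s; scaled rows will be all zero",
            list(cn.index[cn == 0]),
        )
    return CountTable(table.data.mul(cn, axis=0), unit_tag="copy_scaled")


def hill_diversity(p: np.ndarray, q: float) -> float:
    """Hill number (effective number of taxa) of order ``q``.

    ``q=0`` is richness (count of taxa with p_i > 0, no pseudo-count floor);
    ``q=2`` is the inverse Simpson concentration ``1 / sum(p_i^2)``.  General
    ``q >= 0`` is supported via ``(sum p_i^q)^(1/(1-q))`` with the Shannon
    limit at ``q=1``.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D relative-abundance vector")
    if (p < 0).any():
        raise ValueError("relative abundances must be nonnegative")
    if abs(p.sum() - 1.0) > _REL_TOL:
        raise ValueError(f"p must sum to 1 within {_REL_TOL}, got {p.sum()!r}")
    if q < 0:
        raise ValueError("q must be >= 0")
    pos = p[p > 0]
    if q == 0:
        return float(pos.size)
    if q == 1:
        return float(np.exp(-np.sum(pos * np.log(pos))))
    return float(np.sum(pos**q) ** (1.0 / (1.0 - q)))


def diversity_table(table: CountTable, copy_number: pd.Series | None = None) -> pd.DataFrame:
    """Per-sample alpha diversity: richness (q=0), inverse Simpson (q=2).

    ``community_size`` is taken from ``copy_number`` when given (qPCR proxy
    for total abundance), otherwise from the row totals.
    """
    rel = table if table.unit_tag == "relative" else relativize(table)
    rows = []
    for sid in rel.sample_ids:
        p = rel.data.loc[sid].to_numpy(dtype=float)
        rows.append(
            {
                "sample_id": sid,
                "richness_q0": hill_diversity(p, 0),
                "inv_simpson_q2": hill_diversity(p, 2),
            }
        )
    out = pd.DataFrame(rows).set_index("sample_id")
    if copy_number is not None:
        out["community_size"] = copy_number.reindex(out.index).astype(float)
    else:
        out["community_size"] = table.data.sum(axis=1)
    return out


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity among samples.

    d(x, y) = 1 - 2 * sum_i min(x_i, y_i) / (sum x + sum y); on rows that
    each sum to 1 this equals half the L1 distance.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples for a dissimilarity matrix")
    totals = table.values.sum(axis=1)
    n_zero = int((totals == 0).sum())
    if n_zero >= 2:
        zero_ids = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(
            f"Bray-Curtis undefined for a pair of all-zero samples: {zero_ids}"
        )
    condensed = pdist(table.values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(s) for s in table.sample_ids])
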