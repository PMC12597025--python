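"""Abundance-constrained null model and standardized beta-deviation (SES).

For every host the null model resamples its community from the treatment
species pool while preserving two observed quantities exactly: the host's
focal-taxon richness S and its community size N (total bacterial count,
estimated by qPCR).  Repeating the randomization gives a null distribution
of group beta-dispersion; the standardized effect size

    SES = (observed beta - mean null beta) / SD(null beta)

is ~0 when composition reflects stochastic sampling from the pool (drift),
negative under homogenizing selection, positive under divergence.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Hashable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from gutdrift.community import CountTable
from gutdrift.dispersion import group_dispersion

logger = logging.getLogger(__name__)

_REL_TOL = 1e-9


@dataclass
class TaxonPool:
    """The regional / treatment species pool available to colonize hosts."""

    taxon_ids: list
    rel_proportions: np.ndarray
    total_density: float = 0.0

    def __post_init__(self) -> None:
        self.rel_proportions = np.asarray(self.rel_proportions, dtype=float)
        if len(self.taxon_ids) != self.rel_proportions.size:
            raise ValueError("taxon_ids and rel_proportions length mismatch")
        if (self.rel_proportions < 0).any():
            raise ValueError("pool proportions must be >= 0")
        if abs(self.rel_proportions.sum() - 1.0) > _REL_TOL:
            raise ValueError(
                f"pool proportions must sum to 1, got {self.rel_proportions.sum()!r}"
            )
        if self.total_density < 0:
            raise ValueError("total_density must be >= 0")

    @classmethod
    def equal(cls, taxon_ids, total_density: float = 0.0) -> "TaxonPool":
        """Equal-proportion pool (1/k per taxon), the experimental design."""
        k = len(taxon_ids)
        return cls(list(taxon_ids), np.full(k, 1.0 / k), total_density)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)


def integerize(row: np.ndarray) -> np.ndarray:
    """Round a copy-scaled abundance row to integer bacterial counts.

    Rounds to the nearest integer, but any taxon with positive real
    abundance keeps at least one individual so observed richness is
    preserved by the rounding.
    """
    row = np.asarray(row, dtype=float)
    if (row < 0).any():
        raise ValueError("abundances must be nonnegative")
    counts = np.rint(row).astype(np.int64)
    counts[(row > 0) & (counts == 0)] = 1
    return counts


def build_null_community(
    pool: TaxonPool,
    richness: int,
    size: int,
    rng: np.random.Generator,
    method: str = "founders",
) -> np.ndarray:
    """Draw one null community with exactly ``richness`` taxa and ``size``
    individuals.

    With ``method='founders'`` (default) the S occupying taxa are drawn
    without replacement with probability proportional to the pool
    proportions; each receives one founding individual and the remaining
    N - S individuals are assigned multinomially with the selected taxa's
    pool proportions renormalized.  Both constraints hold exactly in every
    draw, with no rejection step.  ``method='rejection'`` instead draws N
    individuals multinomially from the full pool and rejects draws whose
    realized richness differs from S — a sensitivity check, slower and
    impractical when S is improbable under the pool.
    """
    k = pool.n_taxa
    if not 1 <= richness <= k:
        raise ValueError(f"richness must be in [1, {k}], got {richness}")
    if size < richness:
        raise ValueError(f"size ({size}) must be >= richness ({richness})")
    if method == "rejection":
        for _ in range(100_000):
            counts = rng.multinomial(size, pool.rel_proportions)
            if int((counts > 0).sum()) == richness:
                return counts
        raise RuntimeError(
            f"rejection sampling failed to hit richness {richness} at size "
            f"{size}; use method='founders'"
        )
    if method != "founders":
        raise ValueError(f"unknown method {method!r}")
    chosen = rng.choice(k, size=richness, replace=False, p=pool.rel_proportions)
    counts = np.zeros(k, dtype=np.int64)
    counts[chosen] = 1
    remaining = size - richness
    if remaining > 0:
        probs = pool.rel_proportions[chosen]
        probs = probs / probs.sum()
        counts[chosen] += rng.multinomial(remaining, probs)
    return counts


@dataclass
class DeviationResult:
    """Observed beta, null distribution moments, and SES for one group."""

    group: Hashable
    n: int
    observed_beta: float
    null_mean: float
    null_sd: float
    ses: float  # NaN when degenerate
    n_reps: int
    degenerate: bool


def _group_rng(seed: int, label: Hashable) -> np.random.Generator:
    """Independent, label-keyed substream: adding or reordering groups does
    not perturb another group's draws."""
    key = zlib.crc32(str(label).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _group_beta(counts: np.ndarray, ids: list, sqrt_dist: bool, bias: bool) -> float:
    """Beta-dispersion of one group of integer count rows.

    Rows are relativized before Bray-Curtis so the dissimilarity is
    relative-abundance weighted; the dispersion pipeline (sqrt transform,
    PCoA with imaginary axes, spatial median, bias adjustment) is identical
    for observed and null communities.
    """
    rel = counts / counts.sum(axis=1, keepdims=True)
    dm = DistanceMatrix(squareform(pdist(rel, metric="braycurtis")), ids=ids)
    disp = group_dispersion(
        dm, {i: "g" for i in ids}, sqrt_dist=sqrt_dist, bias=bias
    )
    return disp.results["g"].beta


def beta_deviation(
    table: CountTable,
    groups: Mapping[str, Hashable] | pd.Series,
    pools: Mapping[Hashable, TaxonPool] | TaxonPool,
    n_reps: int = 1000,
    seed: int = 0,
    sqrt_dist: bool = True,
    bias: bool = True,
) -> list[DeviationResult]:
    """Standardized beta-deviation (SES) per group.

    Parameters
    ----------
    table :
        Copy-scaled (absolute-abundance) table; each row is integerized to
        (S, N) constraints.  A plain count table works equally.
    groups :
        sample id -> group label (immigration level x instar cell).
    pools :
        One :class:`TaxonPool` per group label, or a single pool shared by
        all groups.  Pool taxa must match the table's columns.
    n_reps :
        Null randomizations per group (1000 by default).
    seed :
        Master seed; each group consumes an independent substream keyed by
        its label.

    Notes
    -----
    Null mean and SD are the sample moments (SD with denominator
    ``n_reps - 1``) of the replicate beta values.  A group whose null SD is
    zero is flagged degenerate and its SES reported as NaN, not +/-inf.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    by_group: dict = {}
    for sid in table.sample_ids:
        by_group.setdefault(groups[sid], []).append(sid)

    results = []
    for label in by_group:
        members = by_group[label]
        n = len(members)
        if n < 2:
            logger.warning("group %r has n=%d < 2; skipped", label, n)
            continue
        pool = pools[label] if isinstance(pools, Mapping) else pools
        if list(pool.taxon_ids) != table.taxon_ids:
            raise ValueError(
                f"pool taxa for group {label!r} do not match table columns"
            )
        obs = np.vstack(
            [integerize(table.data.loc[s].to_numpy()) for s in members]
        )
        richness = (obs > 0).sum(axis=1)
        sizes = obs.sum(axis=1)
        if (richness < 1).any():
            bad = members[int(np.argmin(richness))]
            raise ValueError(
                f"sample {bad!r} has zero focal abundance; exclude it via "
                "subset_focal before the null model"
            )
        ids = [str(s) for s in members]
        observed_beta = _group_beta(obs, ids, sqrt_dist, bias)
        rng = _group_rng(seed, label)
        null_betas = np.empty(n_reps)
        for rep in range(n_reps):
            null_counts = np.vstack(
                [
                    build_null_community(pool, int(s), int(nn), rng)
                    for s, nn in zip(richness, sizes)
                ]
            )
            null_betas[rep] = _group_beta(null_counts, ids, sqrt_dist, bias)
        null_mean = float(null_betas.mean())
        null_sd = float(null_betas.std(ddof=1))
        degenerate = null_sd == 0.0
        if degenerate:
            logger.warning("group %r: null SD is zero; SES undefined", label)
        ses = float("nan") if degenerate else (observed_beta - null_mean) / null_sd
        results.append(
            DeviationResult(
                group=label,
                n=n,
                observed_beta=observed_beta,
                null_mean=null_mean,
                null_sd=null_sd,
                ses=ses,
                n_reps=n_reps,
                degenerate=degenerate,
            )
        )
    return results


def deviation_frame(results: list[DeviationResult]) -> pd.DataFrame:
    """Tidy per-group deviation table."""
    return pd.DataFrame(
        [
            {
                "group": str(r.group),
                "n": r.n,
                "observed_beta": r.observed_beta,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "ses": r.ses,
                "n_reps": r.n_reps,
                "degenerate_flag": r.degenerate,
            }
            for r in results
        ]
    )
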