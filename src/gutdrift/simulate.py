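"""Synthetic immigration-gradient experiment generator.

Emulates the statistical structure of a gnotobiotic caterpillar study: a
five-family bacterial pool at equal relative proportions is serially diluted
over five orders of magnitude to form six immigration treatments; replicate
hosts are inoculated, bacteria colonize probabilistically, and within-host
dynamics (deterministic fitness differences + demographic drift) run until a
second developmental stage.  Hosts are sampled destructively, so the 3rd-
and 5th-instar samples of a treatment come from different individuals.
Per-host totals carry multiplicative qPCR-like measurement noise.

Every downstream stage of the package is testable on this generator without
external data, and the generating truth is retained for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gutdrift.community import CountTable
from gutdrift.nullmodel import TaxonPool

#: the five focal bacterial families of the experimental pool
DEFAULT_TAXA = (
    "Enterobacteriaceae",
    "Comamonadaceae",
    "Bacillaceae",
    "Xanthomonadaceae",
    "Pseudomonadaceae",
)


@dataclass
class AssemblyParams:
    """Parameters of the synthetic assembly experiment.

    Attributes
    ----------
    n_taxa :
        Focal taxa in the pool (default 5).
    dilution_exponents :
        Log10 dilution of each immigration treatment relative to the top
        mix; the default 0 .. -5 spans six orders of magnitude.
    base_density :
        Density of the undiluted mix, CFU/uL (default 1.69e5).
    replicates_per_cell :
        Hosts per treatment x stage cell (default 7; the experimental
        design had 5-9).
    colonization_scale :
        Converts pool density to expected ingested propagules; defaults to
        2.0, the uL volume of an inoculum dose.
    establishment_prob :
        Per-propagule probability of establishing in the gut.
    growth_rate :
        Per-generation multiplicative growth factor shared by all taxa.
    selection_s :
        Fitness advantage of the advantaged taxon: its growth factor is
        growth_rate * (1 + s).  s = 0 gives pure drift (all taxa
        exchangeable).
    advantaged_taxon :
        Index of the taxon receiving the advantage (default 0, the
        Enterobacteriaceae-like dominant).
    fitness :
        Optional explicit per-taxon growth factors overriding
        growth_rate/selection_s.
    carrying_capacity :
        Within-host community ceiling, in effective individuals — the
        population size governing drift strength, far below the census of
        16S copies (default 2000, small enough that rare taxa face real
        extinction risk over an ontogeny).
    drift_size :
        Maximum number of individuals multinomially resampled each
        generation; resampling size is min(current total, drift_size), so
        the default (= carrying capacity) is plain Wright-Fisher drift at
        the current community size and smaller values impose a recurring
        bottleneck.
    n_generations_between_stages :
        Generations of within-host dynamics between the two sampled stages.
    molt_bottleneck :
        Optional extra bottleneck size applied once mid-ontogeny (gut
        lining shed at molt); None disables it.
    n_background_taxa / background_scale :
        Non-focal colonists: number of background taxa and the log-normal
        abundance scale of each (0 disables).  They exercise the focal
        subsetting path downstream.
    measurement_noise_sd :
        Sigma of log-normal multiplicative noise on qPCR-like totals.
    n_lineages / n_plants :
        Host lineages and rearing plants cycled over hosts (random-effect
        structure for downstream mixed models).
    seed :
        Master seed for the whole study.
    """

    n_taxa: int = 5
    taxon_ids: tuple = DEFAULT_TAXA
    dilution_exponents: tuple = (0, -1, -2, -3, -4, -5)
    base_density: float = 1.69e5
    replicates_per_cell: int = 7
    colonization_scale: float = 2.0
    establishment_prob: float = 0.1
    growth_rate: float = 3.0
    selection_s: float = 0.0
    advantaged_taxon: int = 0
    fitness: tuple | None = None
    carrying_capacity: int = 2_000
    drift_size: int = 2_000
    n_generations_between_stages: int = 10
    molt_bottleneck: int | None = None
    n_background_taxa: int = 0
    background_scale: float = 100.0
    measurement_noise_sd: float = 0.1
    n_lineages: int = 4
    n_plants: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        self.taxon_ids = tuple(self.taxon_ids)[: self.n_taxa]
        if len(self.taxon_ids) < self.n_taxa:
            self.taxon_ids = self.taxon_ids + tuple(
                f"taxon_{i}" for i in range(len(self.taxon_ids), self.n_taxa)
            )
        if any(np.diff(self.dilution_exponents) >= 0):
            raise ValueError("dilution_exponents must be strictly decreasing")
        if self.carrying_capacity < 1:
            raise ValueError("carrying_capacity must be >= 1")
        if self.fitness is not None and any(f <= 0 for f in self.fitness):
            raise ValueError("fitness factors must be > 0")
        if self.selection_s < 0:
            raise ValueError("selection_s must be >= 0")

    def fitness_vector(self) -> np.ndarray:
        if self.fitness is not None:
            f = np.asarray(self.fitness, dtype=float)
            if f.size != self.n_taxa:
                raise ValueError("fitness length must equal n_taxa")
            return f
        f = np.full(self.n_taxa, self.growth_rate, dtype=float)
        f[self.advantaged_taxon] *= 1.0 + self.selection_s
        return f


@dataclass
class SimulatedStudy:
    """A realized synthetic study: counts, metadata, and generating truth."""

    counts: CountTable
    metadata: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> None:
        """Write counts.tsv, metadata.tsv and truth.json to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.data.rename_axis("sample_id").to_csv(
            outdir / "counts.tsv", sep="\t", lineterminator="\n"
        )
        self.metadata.rename_axis("sample_id").to_csv(
            outdir / "metadata.tsv", sep="\t", lineterminator="\n"
        )
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True, default=str)


def make_pools(params: AssemblyParams) -> dict[int, TaxonPool]:
    """One equal-proportion pool per dilution exponent.

    Pool density is base_density * 10^e, so adjacent treatments differ by
    exactly a factor of 10.
    """
    return {
        e: TaxonPool.equal(
            list(params.taxon_ids), params.base_density * 10.0**e
        )
        for e in params.dilution_exponents
    }


def simulate_colonization(
    pool: TaxonPool, params: AssemblyParams, rng: np.random.Generator
) -> np.ndarray:
    """Established founder counts for one host.

    Ingested propagules per taxon are Poisson with mean
    colonization_scale * density * proportion; each propagule establishes
    independently with establishment_prob.  At strong dilutions the result
    is often all-zero — the colonization bottleneck of low immigration.
    """
    lam = params.colonization_scale * pool.total_density * pool.rel_proportions
    propagules = rng.poisson(lam)
    return rng.binomial(propagules, params.establishment_prob)


def _one_generation(
    counts: np.ndarray, fitness: np.ndarray, params: AssemblyParams, rng
) -> np.ndarray:
    grown = counts * fitness
    total = grown.sum()
    if total == 0:
        return counts
    if total > params.carrying_capacity:
        grown = grown * (params.carrying_capacity / total)
        total = params.carrying_capacity
    resample_n = int(min(round(total), params.drift_size))
    return rng.multinomial(resample_n, grown / grown.sum())


def simulate_ontogeny(
    initial: np.ndarray, params: AssemblyParams, rng: np.random.Generator
) -> np.ndarray:
    """Within-host dynamics between the two sampled stages.

    Each generation applies deterministic growth (counts x fitness, capped
    at the carrying capacity by proportional rescaling) followed by
    multinomial resampling — Wright-Fisher drift with selection.  With
    equal fitness the expected composition is unchanged (martingale);
    extinct taxa stay extinct.  An optional molt bottleneck resamples a
    reduced population once, halfway through.
    """
    counts = np.asarray(initial, dtype=np.int64).copy()
    fitness = params.fitness_vector()
    half = params.n_generations_between_stages // 2
    for gen in range(params.n_generations_between_stages):
        if counts.sum() == 0:
            break
        counts = _one_generation(counts, fitness, params, rng)
        if (
            params.molt_bottleneck is not None
            and gen == half
            and counts.sum() > params.molt_bottleneck
        ):
            counts = rng.multinomial(
                params.molt_bottleneck, counts / counts.sum()
            )
    return counts


def _measure_total(total: float, params: AssemblyParams, rng) -> float:
    """qPCR-like total: log-normal multiplicative noise, zero stays zero."""
    if total <= 0:
        return 0.0
    return float(total * rng.lognormal(0.0, params.measurement_noise_sd))


def simulate_study(params: AssemblyParams) -> SimulatedStudy:
    """Run the full design: treatments x stages x replicate hosts.

    Stage-3 hosts are sampled right after colonization (24 h post
    inoculation); stage-5 hosts are independent individuals of the same
    treatment carried through ontogeny (destructive sampling).  Output rows
    are one per host; metadata carries immigration level (pool density),
    instar, plant, lineage, and the noisy copy-number total.
    """
    rng = np.random.default_rng(params.seed)
    pools = make_pools(params)
    bg_ids = [f"nonfocal_{i + 1}" for i in range(params.n_background_taxa)]
    rows, meta_rows = [], []
    host_counter = 0
    for e in params.dilution_exponents:
        pool = pools[e]
        for instar in (3, 5):
            for rep in range(params.replicates_per_cell):
                host_counter += 1
                sid = f"host{host_counter:03d}_e{e}_i{instar}"
                founders = simulate_colonization(pool, params, rng)
                focal = (
                    founders
                    if instar == 3
                    else simulate_ontogeny(founders, params, rng)
                )
                row = dict(zip(params.taxon_ids, focal.astype(float)))
                if bg_ids:
                    row.update(
                        dict(
                            zip(
                                bg_ids,
                                np.floor(
                                    rng.lognormal(
                                        np.log(params.background_scale),
                                        1.0,
                                        size=len(bg_ids),
                                    )
                                ),
                            )
                        )
                    )
                rows.append(pd.Series(row, name=sid))
                total = focal.sum() + (sum(row[b] for b in bg_ids) if bg_ids else 0)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "immigration_level": pool.total_density,
                        "instar": instar,
                        "plant_id": f"plant{host_counter % params.n_plants + 1}",
                        "lineage_id": f"lineage{host_counter % params.n_lineages + 1}",
                        "copy_number": _measure_total(total, params, rng),
                    }
                )
    if rows:
        counts = pd.DataFrame(rows).fillna(0.0)
    else:
        counts = pd.DataFrame(columns=list(params.taxon_ids))
    metadata = pd.DataFrame(
        meta_rows,
        columns=[
            "sample_id",
            "immigration_level",
            "instar",
            "plant_id",
            "lineage_id",
            "copy_number",
        ],
    ).set_index("sample_id")
    truth = dataclasses.asdict(params)
    return SimulatedStudy(
        counts=CountTable(counts, unit_tag="reads"),
        metadata=metadata,
        truth=truth,
    )
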