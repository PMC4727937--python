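"""Forward simulation of pooled-segregant sequencing experiments.

Builds surviving seedling populations under a cross design (rejection
sampling of simulated paternal gametes against the viability model, with
optional gametic transmission distortion) and turns the pooled chromosomes
into per-SNP biallelic read counts under a coverage + error model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cross_model import (
    CrossDesign,
    GeneticMap,
    Locus,
    ViabilityModel,
    simulate_gametes,
)
from .errors import DesignError, NoSurvivorsError
from .snp_filter import SnpTable

_BASES = np.array(list("ACGT"))

#: Panel flag names understood by the filter stage.
FLAG_AMBIGUOUS = "ambiguous_reference"
FLAG_MISMATCH = "mismatch"
KNOWN_FLAGS = frozenset({FLAG_AMBIGUOUS, FLAG_MISMATCH})


@dataclass
class SnpPanel:
    """Informative SNP positions discriminating accession A from accession B.

    ``df`` columns: ``chrom`` (str), ``pos`` (1-based int), ``allele_a``,
    ``allele_b`` (single bases, distinct), ``flags`` (frozenset of quality
    flags, possibly empty).
    """

    df: pd.DataFrame

    def __post_init__(self):
        required = ["chrom", "pos", "allele_a", "allele_b", "flags"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"panel missing columns: {missing}")
        df = self.df
        for chrom, grp in df.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"panel positions not strictly increasing on {chrom}")
        if (df["allele_a"] == df["allele_b"]).any():
            raise ValueError("panel contains rows with identical alleles")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_snps(self) -> int:
        return len(self.df)


def random_panel(
    gmap: GeneticMap,
    n_snps: int,
    rng: np.random.Generator,
    flagged_fraction: float = 0.0,
) -> SnpPanel:
    """Draw a synthetic panel of ``n_snps`` positions across the map.

    SNPs are placed uniformly, allocated to chromosomes proportionally to
    physical length; a ``flagged_fraction`` of rows receives a random
    quality flag (for exercising the filter cascade).
    """
    lengths = np.array([c.length_bp for c in gmap.chromosomes], dtype=float)
    alloc = np.floor(n_snps * lengths / lengths.sum()).astype(int)
    # distribute the remainder to the largest chromosomes
    for i in np.argsort(-lengths)[: n_snps - alloc.sum()]:
        alloc[i] += 1
    frames = []
    for chrom, k in zip(gmap.chromosomes, alloc):
        if k == 0:
            continue
        pos = np.sort(rng.choice(np.arange(1, chrom.length_bp + 1), size=k, replace=False))
        a_idx = rng.integers(0, 4, size=k)
        b_idx = (a_idx + rng.integers(1, 4, size=k)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom.name,
                    "pos": pos,
                    "allele_a": _BASES[a_idx],
                    "allele_b": _BASES[b_idx],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    flags = [frozenset()] * len(df)
    if flagged_fraction > 0:
        n_flag = int(round(flagged_fraction * len(df)))
        which = rng.choice(len(df), size=n_flag, replace=False)
        names = sorted(KNOWN_FLAGS)
        for i in which:
            flags[i] = frozenset({names[rng.integers(0, len(names))]})
    df["flags"] = flags
    return SnpPanel(df)


@dataclass(frozen=True)
class CoverageModel:
    """Per-SNP sequencing depth and base-error model."""

    distribution: str = "poisson"
    mean: float = 22.0
    dispersion: float = 10.0
    error_rate: float = 0.002

    def __post_init__(self):
        if self.distribution not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown coverage distribution {self.distribution!r}")
        if self.mean <= 0:
            raise ValueError("mean coverage must be > 0")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error rate must be in [0, 0.5)")
        if self.distribution == "negative_binomial" and self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    def sample_depths(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.distribution == "poisson":
            return rng.poisson(self.mean, size=n)
        k = self.dispersion
        return rng.negative_binomial(k, k / (k + self.mean), size=n)


@dataclass(frozen=True)
class DistortionLocus:
    """Gametic transmission bias independent of seed viability.

    ``bias`` is the probability that an F1 pollen grain carries allele B at
    this locus (0.5 = Mendelian).
    """

    locus: Locus
    bias: float

    def __post_init__(self):
        if not (0.0 < self.bias < 1.0):
            raise ValueError("transmission bias must be in (0, 1)")


@dataclass
class Population:
    """Surviving diploid seedlings over the panel positions.

    ``maternal_b`` / ``paternal_b`` are ``(n_survivors, n_snps)`` 0/1
    arrays of B-allele dosage per inherited chromosome set.
    """

    panel: SnpPanel
    maternal_b: np.ndarray
    paternal_b: np.ndarray

    @property
    def n_survivors(self) -> int:
        return self.paternal_b.shape[0]

    def pooled_b_frequency(self) -> np.ndarray:
        """Per-SNP B-allele frequency among all pooled chromosomes."""
        n = self.n_survivors
        return (self.maternal_b.sum(axis=0) + self.paternal_b.sum(axis=0)) / (2.0 * n)


def _merged_positions(
    panel: SnpPanel,
    gmap: GeneticMap,
    extra: Sequence[Locus],
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Merge panel SNPs with extra loci into one sorted position list.

    Returns (chroms, cm, panel_columns, extra_columns): the index arrays
    recover panel rows / extra loci from the merged gamete matrix.
    """
    chrom_order = {name: i for i, name in enumerate(gmap.names)}
    recs: list[tuple[int, float, int, int]] = []  # (chrom_code, cm, kind, idx)
    for i, (chrom, pos) in enumerate(zip(panel.df["chrom"], panel.df["pos"])):
        cm = gmap.chromosome(chrom).bp_to_cm(float(pos))
        recs.append((chrom_order[chrom], cm, 0, i))
    for j, loc in enumerate(extra):
        loc = loc.resolved(gmap)
        recs.append((chrom_order[loc.chromosome], loc.position_cm, 1, j))
    recs.sort(key=lambda t: (t[0], t[1], t[2]))
    names = gmap.names
    chroms = [names[r[0]] for r in recs]
    cm = np.array([r[1] for r in recs])
    panel_cols = np.empty(len(panel.df), dtype=int)
    extra_cols = np.empty(len(extra), dtype=int)
    for col, (_, _, kind, idx) in enumerate(recs):
        (panel_cols if kind == 0 else extra_cols)[idx] = col
    return chroms, cm, panel_cols, extra_cols


def simulate_cross_population(
    design: CrossDesign,
    viability: ViabilityModel,
    n_target_survivors: int,
    panel: SnpPanel,
    gmap: GeneticMap,
    rng: np.random.Generator,
    distortions: Sequence[DistortionLocus] = (),
    max_attempts: int | None = None,
) -> Population:
    """Accumulate surviving seeds by rejection sampling of simulated gametes.

    Each candidate seed draws a paternal gamete across the panel, rescue and
    distortion positions; it is accepted with probability
    ``survival(genotype) * w(distortion) / max(w)``, so accepted gametes
    follow the distortion-tilted, survival-conditioned distribution while
    preserving linkage.
    """
    if n_target_survivors < 1:
        raise ValueError("n_target_survivors must be >= 1")
    if max_attempts is None:
        max_attempts = max(100_000, 500 * n_target_survivors)

    rescue = [rl.locus for rl in viability.rescue_loci]
    dist_loci = [d.locus for d in distortions]
    chroms, cm, panel_cols, extra_cols = _merged_positions(
        panel, gmap, list(rescue) + list(dist_loci)
    )
    rescue_cols = extra_cols[: len(rescue)]
    dist_cols = extra_cols[len(rescue) :]
    bias = np.array([d.bias for d in distortions], dtype=float)
    w_hi = (np.maximum(bias, 1.0 - bias) / 0.5).prod() if len(bias) else 1.0

    selfing = design.design_label == "f2_selfing"
    pat_rows: list[np.ndarray] = []
    mat_rows: list[np.ndarray] = []
    accepted = 0
    attempts = 0
    batch = min(max(256, n_target_survivors), 2048)
    while accepted < n_target_survivors:
        if attempts >= max_attempts:
            raise NoSurvivorsError(
                f"accepted {accepted}/{n_target_survivors} seeds after "
                f"{attempts} attempts; design may yield no survivors"
            )
        n = min(batch, max_attempts - attempts)
        gam = simulate_gametes(n, chroms, cm, rng)
        surv = viability.survival_array(gam[:, rescue_cols])
        pm = design.maternally_mutant_probability
        if pm < 1.0:
            mut = rng.random(n) < pm
            surv = np.where(mut, surv, viability.wildtype_viability)
        if len(bias):
            b_alleles = gam[:, dist_cols]
            w = np.where(b_alleles, bias / 0.5, (1.0 - bias) / 0.5).prod(axis=1)
            surv = surv * (w / w_hi)
        keep = rng.random(n) < surv
        attempts += n
        if keep.any():
            pat_rows.append(gam[keep][:, panel_cols])
            if selfing:
                mg = simulate_gametes(int(keep.sum()), chroms, cm, rng)
                mat_rows.append(mg[:, panel_cols])
            accepted += int(keep.sum())

    paternal = np.concatenate(pat_rows)[:n_target_survivors].astype(np.uint8)
    if selfing:
        maternal = np.concatenate(mat_rows)[:n_target_survivors].astype(np.uint8)
    else:
        maternal = np.zeros_like(paternal)
    return Population(panel=panel, maternal_b=maternal, paternal_b=paternal)


def simulate_pool_reads(
    population: Population,
    coverage: CoverageModel,
    rng: np.random.Generator,
    pool: str | None = None,
    replicate: str | None = None,
) -> SnpTable:
    """Sequence a pooled population into one replicate count table.

    Per SNP the total depth is drawn from the coverage distribution; each
    read samples one of the 2N pooled chromosomes uniformly and reports its
    allele, flipped with the error rate.
    """
    if population.n_survivors == 0:
        raise ValueError("cannot sequence an empty survivor pool")
    f = population.pooled_b_frequency()
    eps = coverage.error_rate
    p_b = f * (1.0 - eps) + (1.0 - f) * eps
    depth = coverage.sample_depths(len(f), rng)
    count_b = rng.binomial(depth, p_b)
    df = pd.DataFrame(
        {
            "chrom": population.panel.df["chrom"].to_numpy(),
            "pos": population.panel.df["pos"].to_numpy(),
            "count_a": depth - count_b,
            "count_b": count_b,
        }
    )
    return SnpTable(df, pool=pool, replicate=replicate)


def simulate_replicates(
    design: CrossDesign,
    viability: ViabilityModel,
    survivor_counts: Sequence[int],
    panel: SnpPanel,
    gmap: GeneticMap,
    coverage: CoverageModel,
    rng: np.random.Generator,
    distortions: Sequence[DistortionLocus] = (),
    pool: str | None = None,
) -> list[SnpTable]:
    """Simulate one pool: an independent population + read table per replicate."""
    tables = []
    for i, n in enumerate(survivor_counts, start=1):
        popn = simulate_cross_population(
            design, viability, n, panel, gmap, rng, distortions=distortions
        )
        tables.append(simulate_pool_reads(popn, coverage, rng, pool=pool, replicate=str(i)))
    return tables
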