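"""Cross designs with imprinted maternal-effect lethality and paternal rescue.

The genetic model: a mother (accession background ``A``) carrying a
maternal-effect lethal mutation is pollinated by an F1 hybrid father that is
heterozygous ``A/B`` genome-wide.  Seeds that maternally inherit the mutant
allele die unless the paternal gamete carries rescuing ``B`` alleles at one
or more modifier loci; survival is multiplicative across rescue loci.

Expectations (viable-seed fraction, pooled allele fraction at a query
position) are computed two independent ways: exact enumeration of gamete
classes under the Haldane map function, and forward Monte Carlo simulation
of gametes.  Both routes are exposed so each can check the other.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import CapacityError, DesignError, MapError

#: Hard bound on the number of loci enumerated exactly (2**N gamete classes).
MAX_ENUM_LOCI = 20

DesignLabel = Literal["mea_pool", "wt_pool", "f2_selfing"]


def haldane_recomb(distance_cm: float) -> float:
    """Recombination fraction for a genetic distance under the Haldane model.

    ``r = 0.5 * (1 - exp(-2 d / 100))`` for *d* in centimorgans: no
    crossover interference, monotone in *d*, bounded by 0.5.

    Raises
    ------
    ValueError
        If ``distance_cm`` is negative.
    """
    if distance_cm < 0:
        raise ValueError(f"genetic distance must be >= 0, got {distance_cm}")
    return 0.5 * (1.0 - math.exp(-2.0 * distance_cm / 100.0))


# ---------------------------------------------------------------------------
# Maps and loci
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChromosomeMap:
    """One chromosome with genetic (cM) and physical (bp) coordinates.

    ``anchors`` are ordered ``(position_cM, position_bp)`` pairs; positions
    between anchors interpolate linearly in both directions.
    """

    name: str
    length_cm: float
    length_bp: int
    anchors: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if self.length_cm <= 0 or self.length_bp <= 0:
            raise MapError(f"chromosome {self.name}: lengths must be positive")
        cm = [a[0] for a in self.anchors]
        bp = [a[1] for a in self.anchors]
        if len(self.anchors) < 2:
            raise MapError(f"chromosome {self.name}: need >= 2 anchors")
        if any(b <= a for a, b in zip(cm, cm[1:])) or any(
            b <= a for a, b in zip(bp, bp[1:])
        ):
            raise MapError(
                f"chromosome {self.name}: anchors must be strictly increasing "
                "in both coordinates"
            )
        if cm[0] < 0 or bp[0] < 0 or cm[-1] > self.length_cm or bp[-1] > self.length_bp:
            raise MapError(f"chromosome {self.name}: anchors outside chromosome bounds")

    def bp_to_cm(self, pos_bp) -> np.ndarray | float:
        pos = np.asarray(pos_bp, dtype=float)
        if np.any(pos < 0) or np.any(pos > self.length_bp):
            raise MapError(f"position outside chromosome {self.name} (bp)")
        bp = np.array([a[1] for a in self.anchors], dtype=float)
        cm = np.array([a[0] for a in self.anchors], dtype=float)
        # extend anchors to the chromosome ends so interpolation covers [0, L]
        if bp[0] > 0:
            bp, cm = np.concatenate([[0.0], bp]), np.concatenate([[0.0], cm])
        if bp[-1] < self.length_bp:
            bp = np.concatenate([bp, [float(self.length_bp)]])
            cm = np.concatenate([cm, [self.length_cm]])
        out = np.interp(pos, bp, cm)
        return float(out) if np.isscalar(pos_bp) or out.ndim == 0 else out

    def cm_to_bp(self, pos_cm) -> np.ndarray | float:
        pos = np.asarray(pos_cm, dtype=float)
        if np.any(pos < 0) or np.any(pos > self.length_cm):
            raise MapError(f"position outside chromosome {self.name} (cM)")
        bp = np.array([a[1] for a in self.anchors], dtype=float)
        cm = np.array([a[0] for a in self.anchors], dtype=float)
        if cm[0] > 0:
            bp, cm = np.concatenate([[0.0], bp]), np.concatenate([[0.0], cm])
        if cm[-1] < self.length_cm:
            bp = np.concatenate([bp, [float(self.length_bp)]])
            cm = np.concatenate([cm, [self.length_cm]])
        out = np.interp(pos, cm, bp)
        return float(out) if np.isscalar(pos_cm) or out.ndim == 0 else out


@dataclass(frozen=True)
class GeneticMap:
    """An ordered collection of :class:`ChromosomeMap`."""

    chromosomes: tuple[ChromosomeMap, ...]

    def __post_init__(self):
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise MapError("duplicate chromosome names")

    @classmethod
    def uniform(cls, spec: Iterable[tuple[str, float, int]]) -> "GeneticMap":
        """Build a map with constant cM/bp rate per chromosome.

        ``spec`` is an iterable of ``(name, length_cM, length_bp)``.
        """
        return cls(
            tuple(
                ChromosomeMap(
                    name=n,
                    length_cm=lcm,
                    length_bp=lbp,
                    anchors=((0.0, 0.0), (lcm, float(lbp))),
                )
                for n, lcm, lbp in spec
            )
        )

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> ChromosomeMap:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise MapError(f"unknown chromosome {name!r}")

    def __contains__(self, name: str) -> bool:
        return name in self.names


def arabidopsis_like_map() -> GeneticMap:
    """A five-chromosome map with sizes typical of *A. thaliana*.

    Constant recombination rate (~4 cM/Mb); used for simulations and
    examples when no empirical map is supplied.
    """
    return GeneticMap.uniform(
        [
            ("1", 121.7, 30_427_671),
            ("2", 78.8, 19_698_289),
            ("3", 93.8, 23_459_830),
            ("4", 74.3, 18_585_056),
            ("5", 107.9, 26_975_502),
        ]
    )


@dataclass(frozen=True)
class Locus:
    """A genomic location with genetic and/or physical coordinates."""

    chromosome: str
    position_cm: float | None = None
    position_bp: float | None = None

    def __post_init__(self):
        if self.position_cm is None and self.position_bp is None:
            raise MapError("locus needs at least one of position_cm, position_bp")

    def resolved(self, gmap: GeneticMap | None) -> "Locus":
        """Return a copy with both coordinates filled in via the map."""
        if self.position_cm is not None and self.position_bp is not None:
            return self
        if gmap is None:
            if self.position_cm is not None:
                return self
            raise MapError(
                f"locus on {self.chromosome} has only a physical position; "
                "a GeneticMap is required to derive cM"
            )
        chrom = gmap.chromosome(self.chromosome)
        if self.position_cm is None:
            return Locus(self.chromosome, chrom.bp_to_cm(self.position_bp), self.position_bp)
        return Locus(self.chromosome, self.position_cm, chrom.cm_to_bp(self.position_cm))


# ---------------------------------------------------------------------------
# Cross design and viability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossDesign:
    """Which parent carries the maternal-effect mutation and how.

    - ``mea_pool``: homozygous mutant mother (all-``A`` genome) x ``A/B``
      F1 father; every seed is maternally mutant.
    - ``wt_pool``: wild-type ``A`` mother x ``A/B`` F1 father; no
      maternal-effect lethality (the control cross).
    - ``f2_selfing``: selfed ``A/B`` F1 heterozygous for the mutation;
      the mutant allele segregates through both gametes but only the
      maternally inherited copy matters.
    """

    design_label: DesignLabel
    maternal_background: str = "A"

    def __post_init__(self):
        if self.design_label not in ("mea_pool", "wt_pool", "f2_selfing"):
            raise DesignError(f"unknown design label {self.design_label!r}")

    @property
    def maternal_genome_is_fixed(self) -> bool:
        """True when every maternal gamete is all-``A`` (pool designs)."""
        return self.design_label in ("mea_pool", "wt_pool")

    @property
    def maternally_mutant_probability(self) -> float:
        """Probability a seed inherits the mutant allele from its mother."""
        return {"mea_pool": 1.0, "wt_pool": 0.0, "f2_selfing": 0.5}[self.design_label]

    @classmethod
    def mea_pool(cls) -> "CrossDesign":
        return cls("mea_pool")

    @classmethod
    def wt_pool(cls) -> "CrossDesign":
        return cls("wt_pool")

    @classmethod
    def f2_selfing(cls) -> "CrossDesign":
        return cls("f2_selfing")


@dataclass(frozen=True)
class RescueLocus:
    """A modifier locus whose paternal ``B`` allele multiplies seed survival.

    ``multiplier`` may be ``math.inf`` to express a fully required locus:
    survival is 1 (after capping) whenever the paternal ``B`` allele is
    present, regardless of baseline viability.
    """

    locus: Locus
    multiplier: float

    def __post_init__(self):
        if not (self.multiplier >= 1.0):
            raise DesignError(f"rescue multiplier must be >= 1, got {self.multiplier}")


@dataclass(frozen=True)
class ViabilityModel:
    """Seed survival given the paternally inherited alleles at rescue loci.

    ``survival(x) = min(1, v0 * prod(r_i ** x_i))`` where ``x_i`` is 1 iff
    the paternal gamete carries ``B`` at rescue locus ``i``; infinite
    multipliers short-circuit to the cap.  Maternally wild-type seeds
    survive with ``wildtype_viability``.
    """

    baseline_viability: float
    rescue_loci: tuple[RescueLocus, ...] = ()
    wildtype_viability: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.baseline_viability <= 1.0):
            raise DesignError("baseline_viability must be in [0, 1]")
        if not (0.0 <= self.wildtype_viability <= 1.0):
            raise DesignError("wildtype_viability must be in [0, 1]")

    def survival(self, paternal_b: Sequence[int]) -> float:
        """Survival probability of one maternally-mutant seed."""
        if len(paternal_b) != len(self.rescue_loci):
            raise DesignError("paternal allele vector length != number of rescue loci")
        s = self.baseline_viability
        for x, rl in zip(paternal_b, self.rescue_loci):
            if x:
                if math.isinf(rl.multiplier):
                    return 1.0
                s *= rl.multiplier
        return min(1.0, s)

    def survival_array(self, paternal_b: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`survival` for an ``(n, n_loci)`` 0/1 array."""
        X = np.asarray(paternal_b)
        if X.ndim != 2 or X.shape[1] != len(self.rescue_loci):
            raise DesignError("paternal allele matrix must be (n, n_rescue_loci)")
        mult = np.array([rl.multiplier for rl in self.rescue_loci], dtype=float)
        finite = np.isfinite(mult)
        factors = np.where(X[:, finite].astype(bool), mult[finite], 1.0)
        s = self.baseline_viability * factors.prod(axis=1)
        if (~finite).any():
            s = np.where(X[:, ~finite].astype(bool).any(axis=1), 1.0, s)
        return np.minimum(1.0, s)


# ---------------------------------------------------------------------------
# Exact enumeration
# ---------------------------------------------------------------------------


def _gamete_class_distribution(
    loci: Sequence[Locus], gmap: GeneticMap | None
) -> list[tuple[tuple[int, ...], float]]:
    """Joint distribution of a gamete's alleles (0=A, 1=B) at ``loci``.

    Loci on the same chromosome are chained with Haldane recombination
    between cM-adjacent pairs; chromosomes segregate independently with a
    fair starting allele.  Returns ``(bits_in_input_order, probability)``
    pairs for all ``2**len(loci)`` classes.
    """
    if len(loci) > MAX_ENUM_LOCI:
        raise CapacityError(
            f"exact enumeration supports <= {MAX_ENUM_LOCI} loci, got {len(loci)}"
        )
    resolved = [loc.resolved(gmap) for loc in loci]
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for i, loc in enumerate(resolved):
        by_chrom.setdefault(loc.chromosome, []).append((i, loc.position_cm))
    chrom_dists = []
    for _, members in by_chrom.items():
        members = sorted(members, key=lambda t: t[1])
        idxs = [i for i, _ in members]
        cms = [cm for _, cm in members]
        rs = [haldane_recomb(b - a) for a, b in zip(cms, cms[1:])]
        dist = []
        for bits in itertools.product((0, 1), repeat=len(idxs)):
            p = 0.5
            for j, r in enumerate(rs):
                p *= r if bits[j] != bits[j + 1] else 1.0 - r
            dist.append((idxs, bits, p))
        chrom_dists.append(dist)
    out: list[tuple[tuple[int, ...], float]] = []
    for combo in itertools.product(*chrom_dists):
        bits_all = [0] * len(loci)
        p = 1.0
        for idxs, bits, pc in combo:
            p *= pc
            for i, b in zip(idxs, bits):
                bits_all[i] = b
        out.append((tuple(bits_all), p))
    return out


def expected_viable_fraction(
    design: CrossDesign, viability: ViabilityModel, gmap: GeneticMap | None = None
) -> float:
    """Exact expected fraction of viable seeds for a cross design.

    Enumerates paternal gamete classes at the rescue loci (with pairwise
    Haldane linkage for loci sharing a chromosome) and averages survival;
    maternally wild-type seeds contribute ``wildtype_viability``.
    """
    loci = [rl.locus for rl in viability.rescue_loci]
    dist = _gamete_class_distribution(loci, gmap)
    e_mut = sum(p * viability.survival(bits) for bits, p in dist)
    pm = design.maternally_mutant_probability
    return pm * e_mut + (1.0 - pm) * viability.wildtype_viability


def expected_pool_allele_fraction(
    design: CrossDesign,
    viability: ViabilityModel,
    query: Locus,
    gmap: GeneticMap | None = None,
) -> float:
    """Expected ``B``-allele fraction among pooled survivor genomes at ``query``.

    Conditions the paternal gamete distribution on seed survival; the
    maternal contribution is all-``A`` for the pool designs and an unbiased
    coin for ``f2_selfing`` (the maternal-effect locus is treated as
    unlinked to the query).
    """
    if gmap is not None and query.chromosome not in gmap:
        raise MapError(f"query chromosome {query.chromosome!r} not on the map")
    query = query.resolved(gmap)
    loci = [rl.locus for rl in viability.rescue_loci] + [query]
    dist = _gamete_class_distribution(loci, gmap)
    # weighted paternal B probability at the query, given survival
    num_mut = sum(p * viability.survival(bits[:-1]) * bits[-1] for bits, p in dist)
    den_mut = sum(p * viability.survival(bits[:-1]) for bits, p in dist)
    pm = design.maternally_mutant_probability
    v_wt = viability.wildtype_viability
    num = pm * num_mut + (1.0 - pm) * v_wt * 0.5
    den = pm * den_mut + (1.0 - pm) * v_wt
    if den == 0.0:
        raise DesignError("design yields no surviving seeds; allele fraction undefined")
    paternal_b = num / den
    maternal_b = 0.5 if design.design_label == "f2_selfing" else 0.0
    return (maternal_b + paternal_b) / 2.0


# ---------------------------------------------------------------------------
# Gamete simulation (Monte Carlo twin of the enumeration)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gamete:
    """Alleles (False=A, True=B) of one gamete at ordered tracked positions."""

    chromosomes: tuple[str, ...]
    alleles: tuple[bool, ...]


def _check_positions(chroms: np.ndarray, cm: np.ndarray) -> list[tuple[int, int]]:
    """Validate grouped chromosomes / sorted cM; return (start, stop) blocks."""
    if len(chroms) != len(cm):
        raise ValueError("chromosome and position arrays differ in length")
    blocks: list[tuple[int, int]] = []
    seen: set[str] = set()
    i = 0
    n = len(chroms)
    while i < n:
        name = chroms[i]
        if name in seen:
            raise ValueError(f"chromosome {name!r} appears in non-contiguous blocks")
        seen.add(name)
        j = i
        while j < n and chroms[j] == name:
            j += 1
        if np.any(np.diff(cm[i:j]) < 0):
            raise ValueError(f"positions not sorted within chromosome {name!r}")
        blocks.append((i, j))
        i = j
    return blocks


def simulate_gametes(
    n: int,
    chroms: Sequence[str],
    positions_cm: Sequence[float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate ``n`` F1 gametes; returns a boolean ``(n, m)`` matrix (True=B).

    Per chromosome the starting allele is a fair coin and the allele
    switches between consecutive positions with the Haldane recombination
    fraction of their cM distance; chromosomes are independent.
    """
    chroms = np.asarray(chroms, dtype=object)
    cm = np.asarray(positions_cm, dtype=float)
    blocks = _check_positions(chroms, cm)
    out = np.empty((n, len(cm)), dtype=bool)
    for i, j in blocks:
        k = j - i
        start = rng.random(n) < 0.5
        out[:, i] = start
        if k > 1:
            d = np.diff(cm[i:j])
            r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
            switches = rng.random((n, k - 1)) < r
            parity = np.cumsum(switches, axis=1, dtype=np.int32) & 1
            out[:, i + 1 : j] = start[:, None] ^ parity.astype(bool)
    return out


def simulate_gamete(
    chroms: Sequence[str],
    positions_cm: Sequence[float],
    rng: np.random.Generator,
) -> Gamete:
    """Simulate a single gamete over ordered positions (see simulate_gametes)."""
    row = simulate_gametes(1, chroms, positions_cm, rng)[0]
    return Gamete(tuple(chroms), tuple(bool(b) for b in row))


def _simulate_seed_batch(
    design: CrossDesign,
    viability: ViabilityModel,
    n: int,
    rng: np.random.Generator,
    gmap: GeneticMap | None,
    extra_locus: Locus | None = None,
):
    """Simulate n seeds: returns (paternal bits matrix, survived mask)."""
    loci = [rl.locus.resolved(gmap) for rl in viability.rescue_loci]
    if extra_locus is not None:
        loci = loci + [extra_locus.resolved(gmap)]
    if loci:
        order = sorted(range(len(loci)), key=lambda i: (loci[i].chromosome, loci[i].position_cm))
        chroms = [loci[i].chromosome for i in order]
        cms = [loci[i].position_cm for i in order]
        gam_sorted = simulate_gametes(n, chroms, cms, rng)
        gam = np.empty_like(gam_sorted)
        gam[:, order] = gam_sorted
    else:
        gam = np.zeros((n, 0), dtype=bool)
    n_rescue = len(viability.rescue_loci)
    surv_p = viability.survival_array(gam[:, :n_rescue])
    pm = design.maternally_mutant_probability
    if pm < 1.0:
        mut = rng.random(n) < pm
        surv_p = np.where(mut, surv_p, viability.wildtype_viability)
    survived = rng.random(n) < surv_p
    return gam, survived


def monte_carlo_viable_fraction(
    design: CrossDesign,
    viability: ViabilityModel,
    n_seeds: int,
    rng: np.random.Generator,
    gmap: GeneticMap | None = None,
) -> float:
    """Forward-simulated viable-seed fraction (check of the enumeration)."""
    _, survived = _simulate_seed_batch(design, viability, n_seeds, rng, gmap)
    return survived.mean()


def monte_carlo_pool_allele_fraction(
    design: CrossDesign,
    viability: ViabilityModel,
    query: Locus,
    n_seeds: int,
    rng: np.random.Generator,
    gmap: GeneticMap | None = None,
) -> float:
    """Forward-simulated pooled B-allele fraction at ``query`` among survivors."""
    gam, survived = _simulate_seed_batch(design, viability, n_seeds, rng, gmap, query)
    if not survived.any():
        raise DesignError("no surviving seeds in the simulation")
    paternal_b = gam[survived, -1].mean()
    if design.design_label == "f2_selfing":
        maternal_b = (rng.random(int(survived.sum())) < 0.5).mean()
    else:
        maternal_b = 0.0
    return (maternal_b + paternal_b) / 2.0
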