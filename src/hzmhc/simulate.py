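"""Forward simulation of MHC haplotypes and parametric hybrid-zone generators.

The individual-based model: a Wright-Fisher diploid population in which the
MHC region is a block of completely linked multiallelic loci, each evolving
under the infinite-alleles model (every mutation creates a brand-new allele
identity, per-locus rate mu = theta / 4N) and negative frequency-dependent
selection.  The fitness of an allele at frequency f is

    w = 1 + s/2 - f * s,

bounded in [1 - s/2, 1 + s/2]; an individual's fitness is the arithmetic
mean of the fitnesses of its 2 * n_loci allele copies.  An ancestral
population evolves for a burn-in, splits into two descendant species of the
same size that evolve in isolation, and snapshots are taken at chosen times
after the split.

The transect builder does not simulate the formation of a cline: it samples
haplotypes from the two parental pools against a fixed sigmoid expected-
admixture curve, recording each haplotype's true species of origin, so that
hybrid-index estimators can be benchmarked against known ancestry.

A separate parametric generator draws binary genotype matrices with
controlled interspecific allele sharing in "near" and "far" categories, for
calibrating the allele-sharing permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import BinaryGenotypeMatrix, IndividualRecord, ZoneCategory

__all__ = [
    "SimParams",
    "SimState",
    "Population",
    "TransectSample",
    "allele_fitness",
    "wf_generation",
    "run_split_simulation",
    "build_transect",
    "binarize",
    "generate_parametric_zone",
]


@dataclass
class SimParams:
    """Forward-simulation parameters.

    Defaults follow the standard scenario: N = 500 diploids, five linked
    loci with equal theta = 0.6, strong negative frequency dependence
    s = 0.5, burn-in of 20N generations, snapshots at 0.5N, 1N and 4N
    generations after the species split.
    """

    N: int = 500
    n_loci: int = 5
    theta: tuple[float, ...] = (0.6, 0.6, 0.6, 0.6, 0.6)
    s: float = 0.5
    burn_in_gens: int | None = None  # default 20N
    split_gens: tuple[float, ...] = (0.5, 1.0, 4.0)  # in units of N
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if isinstance(self.theta, (int, float)):
            self.theta = (float(self.theta),) * self.n_loci
        self.theta = tuple(float(t) for t in self.theta)
        if len(self.theta) != self.n_loci:
            raise ValueError(f"need {self.n_loci} theta values, got {len(self.theta)}")
        if any(t < 0 for t in self.theta):
            raise ValueError("theta must be >= 0")
        if not (0.0 <= self.s <= 1.0):
            raise ValueError("s must be in [0, 1]")
        if self.burn_in_gens is None:
            self.burn_in_gens = 20 * self.N

    @property
    def mu(self) -> np.ndarray:
        """Per-locus mutation rate mu = theta / (4N)."""
        return np.asarray(self.theta) / (4.0 * self.N)


@dataclass
class SimState:
    """Haplotype pool of one population at one generation.

    ``haplotypes`` has shape (2N, n_loci) of integer allele identifiers;
    haplotypes 2i and 2i+1 belong to diploid individual i.  Allele
    identifiers are never reused (infinite alleles): ``next_allele_id`` is
    the lowest unused identifier.
    """

    generation: int
    haplotypes: np.ndarray
    next_allele_id: int
    species: str = "ancestral"

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if self.haplotypes.shape[0] % 2 != 0:
            raise ValueError("haplotype pool must contain an even number of haplotypes")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def copy(self, species: str | None = None) -> "SimState":
        return SimState(
            self.generation,
            self.haplotypes.copy(),
            self.next_allele_id,
            species or self.species,
        )


def allele_fitness(f: float | np.ndarray, s: float) -> float | np.ndarray:
    """Fitness of an allele at frequency ``f``: w = 1 + s/2 - f*s."""
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    w = 1.0 + s / 2.0 - f * s
    return float(w) if w.ndim == 0 else w


def _individual_fitness(haplotypes: np.ndarray, s: float) -> np.ndarray:
    """Mean allele-copy fitness per diploid individual.

    Allele frequencies are computed per locus among the 2N gene copies of
    the parental generation.
    """
    two_n, n_loci = haplotypes.shape
    w_copies = np.empty_like(haplotypes, dtype=float)
    for locus in range(n_loci):
        alleles, inverse, counts = np.unique(
            haplotypes[:, locus], return_inverse=True, return_counts=True
        )
        freqs = counts / two_n
        w_copies[:, locus] = allele_fitness(freqs, s)[inverse]
    # individual i owns haplotype rows 2i and 2i+1
    per_hap = w_copies.mean(axis=1)
    return 0.5 * (per_hap[0::2] + per_hap[1::2])


def wf_generation(state: SimState, params: SimParams, rng: np.random.Generator) -> SimState:
    """Advance one Wright-Fisher generation.

    Each offspring draws two parents with probability proportional to
    individual fitness; each parent transmits one of its two haplotypes
    intact (loci completely linked, no recombination).  Transmitted copies
    then mutate per locus with probability mu = theta/(4N), each mutation
    introducing a brand-new allele identifier.
    """
    two_n = state.n_haplotypes
    n_ind = two_n // 2
    fit = _individual_fitness(state.haplotypes, params.s)
    probs = fit / fit.sum()
    parents = rng.choice(n_ind, size=two_n, p=probs)
    which = rng.integers(0, 2, size=two_n)
    offspring = state.haplotypes[2 * parents + which].copy()

    mut = rng.random(offspring.shape) < params.mu[None, :]
    n_mut = int(mut.sum())
    next_id = state.next_allele_id
    if n_mut:
        offspring[mut] = np.arange(next_id, next_id + n_mut)
        next_id += n_mut
    return SimState(state.generation + 1, offspring, next_id, state.species)


def run_split_simulation(
    params: SimParams, rng: np.random.Generator | None = None
) -> dict[float, tuple[SimState, SimState]]:
    """Burn-in, split into two isolated species, snapshot at the requested
    times after the split.

    Returns a mapping from each split time (in units of N generations) to the
    pair of species states at that time.  The ancestral population has size
    N; the split duplicates its final pool into two independent copies that
    each continue at size N.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    two_n = 2 * params.N
    # start monomorphic per locus; burn-in reaches mutation-selection-drift balance
    init = np.tile(np.arange(params.n_loci, dtype=np.int64), (two_n, 1))
    state = SimState(0, init, params.n_loci, "ancestral")
    for _ in range(params.burn_in_gens):
        state = wf_generation(state, params, rng)

    species_a = state.copy("A")
    species_b = state.copy("B")
    checkpoints = sorted(params.split_gens)
    snapshots: dict[float, tuple[SimState, SimState]] = {}
    gens_done = 0
    for t in checkpoints:
        target = int(round(t * params.N))
        for _ in range(target - gens_done):
            species_a = wf_generation(species_a, params, rng)
            species_b = wf_generation(species_b, params, rng)
        gens_done = target
        snapshots[t] = (species_a.copy("A"), species_b.copy("B"))
    return snapshots


# ---------------------------------------------------------------------------
# Transect construction


@dataclass
class Population:
    position_km: float
    expected_admixture: float  # expected proportion of species-B ancestry
    haplotypes: np.ndarray  # (2 * n_individuals, n_loci) allele ids
    origins: np.ndarray  # (2 * n_individuals,) 0 = species A, 1 = species B

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    def known_ancestry(self) -> np.ndarray:
        """Per-individual proportion of species-B ancestry (0, 0.5 or 1)."""
        return 0.5 * (self.origins[0::2] + self.origins[1::2])


@dataclass
class TransectSample:
    populations: list[Population]
    reference_a: np.ndarray  # (2 * n_ref, n_loci) haplotypes from pure species A
    reference_b: np.ndarray
    true_center_km: float
    true_width_km: float
    n_loci: int


def transect_positions(
    center_km: float = 100.0, core_km: float = 6.0, tail_km: float = 97.0,
    n_core: int = 15, n_tail: int = 10,
) -> np.ndarray:
    """Population positions: ``n_core`` equally spaced populations spanning
    the central ``core_km`` segment, ``n_tail`` equally spaced in each
    ``tail_km`` tail."""
    core = np.linspace(center_km - core_km / 2, center_km + core_km / 2, n_core)
    left = np.linspace(center_km - core_km / 2 - tail_km, center_km - core_km / 2, n_tail, endpoint=False)
    right = (2 * center_km - left)[::-1]
    return np.concatenate([left, core, right])


def fixed_ends_cline(x: np.ndarray, center: float, width: float) -> np.ndarray:
    """Sigmoid ancestry cline anchored at 0 and 1: (1 + tanh(2(x-c)/w)) / 2."""
    return 0.5 * (1.0 + np.tanh(2.0 * (np.asarray(x, dtype=float) - center) / width))


def build_transect(
    state_a: SimState,
    state_b: SimState,
    rng: np.random.Generator,
    width_km: float = 6.0,
    center_km: float = 100.0,
    n_per_population: int = 10,
    n_reference: int = 30,
) -> TransectSample:
    """Sample a hybrid-zone transect from two parental haplotype pools.

    35 populations (10 per 97-km tail, 15 across the 6-km core) of
    ``n_per_population`` individuals each; every haplotype is drawn from
    species B with probability equal to the fixed-ends sigmoid cline at the
    population's position, and its true origin is recorded.  Reference
    panels of ``n_reference`` individuals are drawn from each pure species.
    """
    n_loci = state_a.haplotypes.shape[1]
    if state_b.haplotypes.shape[1] != n_loci:
        raise ValueError("species pools have different locus counts")
    positions = transect_positions(center_km=center_km, core_km=width_km)
    expected = fixed_ends_cline(positions, center_km, width_km)
    populations = []
    for x, p_b in zip(positions, expected):
        n_hap = 2 * n_per_population
        origins = (rng.random(n_hap) < p_b).astype(np.int8)
        idx_a = rng.integers(0, state_a.n_haplotypes, size=n_hap)
        idx_b = rng.integers(0, state_b.n_haplotypes, size=n_hap)
        haps = np.where(origins[:, None] == 1, state_b.haplotypes[idx_b], state_a.haplotypes[idx_a])
        populations.append(Population(float(x), float(p_b), haps, origins))
    ref_a = state_a.haplotypes[rng.integers(0, state_a.n_haplotypes, size=2 * n_reference)]
    ref_b = state_b.haplotypes[rng.integers(0, state_b.n_haplotypes, size=2 * n_reference)]
    return TransectSample(populations, ref_a, ref_b, center_km, width_km, n_loci)


def binarize(
    haplotype_pairs: np.ndarray, allele_ids: list[int] | None = None
) -> tuple[np.ndarray, list[int]]:
    """Collapse diploid multilocus genotypes to binary presence/absence.

    ``haplotype_pairs`` has shape (2 * n_ind, n_loci); rows 2i and 2i+1 are
    individual i.  One column per distinct allele identifier (dominance:
    1 if the individual carries at least one copy).  Pass ``allele_ids`` to
    force a column order, e.g. the one derived from reference panels.
    """
    haps = np.asarray(haplotype_pairs)
    n_ind = haps.shape[0] // 2
    if allele_ids is None:
        allele_ids = [int(a) for a in np.unique(haps)]
    col = {a: j for j, a in enumerate(allele_ids)}
    presence = np.zeros((n_ind, len(allele_ids)), dtype=np.int8)
    for i in range(n_ind):
        for a in np.unique(haps[2 * i : 2 * i + 2]):
            j = col.get(int(a))
            if j is not None:
                presence[i, j] = 1
    return presence, allele_ids


def binarize_transect(sample: TransectSample) -> tuple[BinaryGenotypeMatrix, list[IndividualRecord]]:
    """Binary genotype matrix + metadata for a whole simulated transect."""
    all_haps = np.concatenate([p.haplotypes for p in sample.populations])
    allele_ids = [int(a) for a in np.unique(all_haps)]
    blocks, records = [], []
    for k, pop in enumerate(sample.populations):
        pres, _ = binarize(pop.haplotypes, allele_ids)
        blocks.append(pres)
        anc = pop.known_ancestry()
        for i in range(pop.n_individuals):
            records.append(
                IndividualRecord(
                    individual_id=f"pop{k:02d}_ind{i:02d}",
                    species="A" if anc[i] < 0.5 else "B",
                    locality_id=f"pop{k:02d}",
                    transect_position_km=pop.position_km,
                    q_score=float(anc[i]),
                )
            )
    presence = np.concatenate(blocks)
    matrix = BinaryGenotypeMatrix(
        [r.individual_id for r in records], [str(a) for a in allele_ids], presence
    )
    return matrix, records


# ---------------------------------------------------------------------------
# Parametric null/alternative zone generator


def generate_parametric_zone(
    n_near: int = 20,
    n_far: int = 20,
    n_alleles: int = 30,
    sharing_near: float = 0.2,
    sharing_far: float = 0.2,
    alleles_per_individual: int = 6,
    seed: int | np.random.Generator = 0,
) -> tuple[BinaryGenotypeMatrix, list[IndividualRecord]]:
    """Draw a two-species binary genotype dataset with controlled
    interspecific allele sharing per near/far category.

    Each species' pool of ``n_alleles`` alleles splits into a shared half
    (alleles common to both species, maintained as trans-species
    polymorphism) and a species-private half.  Every allele an individual
    carries is drawn from the shared pool with probability equal to its
    category's ``sharing_*`` value, otherwise from the private pool.  With
    ``sharing_near == sharing_far`` individuals are iid across categories
    within a species, so the near/far permutation null holds exactly;
    raising ``sharing_near`` above ``sharing_far`` emulates introgressed
    trans-specific alleles concentrated close to the contact.
    """
    if n_alleles <= 0:
        raise ValueError("n_alleles must be positive")
    for prop in (sharing_near, sharing_far):
        if not (0.0 <= prop <= 1.0):
            raise ValueError("sharing proportions must lie in [0, 1]")
    n_shared_pool = n_alleles // 2
    n_private_pool = n_alleles - n_shared_pool
    if max(sharing_near, sharing_far) > 0 and n_shared_pool == 0:
        raise ValueError("shared pool empty: n_alleles too small for requested sharing")
    if min(sharing_near, sharing_far) < 1 and n_private_pool == 0:
        raise ValueError("private pool empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    shared_pool = [f"sh{j}" for j in range(n_shared_pool)]
    private_pool = {sp: [f"{sp}_pr{j}" for j in range(n_private_pool)] for sp in ("sp1", "sp2")}
    allele_ids = sorted(shared_pool + private_pool["sp1"] + private_pool["sp2"])
    col = {a: j for j, a in enumerate(allele_ids)}
    rows, records = [], []
    counts = {"near": n_near, "far": n_far}
    sharing_of = {"near": sharing_near, "far": sharing_far}
    for sp in ("sp1", "sp2"):
        for cat in ("near", "far"):
            w = sharing_of[cat]
            for i in range(counts[cat]):
                row = np.zeros(len(allele_ids), dtype=np.int8)
                from_shared = rng.random(alleles_per_individual) < w
                for is_shared in from_shared:
                    pool = shared_pool if is_shared else private_pool[sp]
                    row[col[pool[rng.integers(len(pool))]]] = 1
                rows.append(row)
                records.append(
                    IndividualRecord(
                        individual_id=f"{sp}_{cat}_{i:03d}",
                        species=sp,
                        locality_id=f"{sp}_{cat}",
                        q_score=0.0,
                        zone_category=ZoneCategory(cat),
                    )
                )
    presence = np.array(rows, dtype=np.int8)
    keep = presence.sum(axis=0) > 0
    presence = presence[:, keep]
    allele_ids = [a for a, k in zip(allele_ids, keep) if k]
    matrix = BinaryGenotypeMatrix([r.individual_id for r in records], allele_ids, presence)
    return matrix, records
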