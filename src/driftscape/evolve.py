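"""Forward-time Wright-Fisher evolution with genealogy tracking.

Discrete, non-overlapping generations on a synthetic landscape: parents
are sampled proportional to fitness (non-viable genotypes occupy their
slot in the population but have sampling weight 0), and each offspring
carries at most one mutation — with probability ``U`` a uniformly
chosen site is switched to a uniformly chosen non-identical state.

Every distinct mutant genotype becomes a genealogy record pointing at
its parent, so the line of descent (LOD) of any surviving genotype — the
"fossil record" of its lineage back to the ancestor — can be replayed
exactly.  Extinct side branches are pruned periodically to bound
memory.

The optional ``revert_deleterious`` treatment re-evaluates every mutant
against its parent and silently replaces any offspring of lower fitness
with an unmutated copy, so no deleterious mutation ever enters the
population and lineage fitness is monotone non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import Genome, SyntheticLandscape
from .seeds import derive_seed

__all__ = [
    "EvolutionConfig",
    "GenealogyRecord",
    "LineOfDescent",
    "Genealogy",
    "EvolutionRun",
    "evolve_population",
    "most_abundant_genotype",
    "extract_lod",
    "drift_robustness_assay",
]


@dataclass
class EvolutionConfig:
    """Run parameters for :func:`evolve_population`."""

    N: int = 100
    generations: int = 1000
    U: float = 0.1
    revert_deleterious: bool = False
    seed: int = 0
    prune_interval: int = 100
    stop_when_monomorphic: bool = False

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size must be at least 2")
        if not 0.0 <= self.U <= 1.0:
            raise ValueError("genomic mutation rate U must lie in [0, 1]")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")


@dataclass(frozen=True)
class GenealogyRecord:
    """One genotype on a line of descent."""

    gid: int
    genome: Genome
    fitness: float
    parent: int
    mutation: tuple[int, int, int] | None  # (site, from_state, to_state)
    birth: int


class LineOfDescent(list):
    """Ordered genealogy records from the ancestor to a focal genotype."""

    @property
    def fitness_series(self) -> np.ndarray:
        return np.array([rec.fitness for rec in self])


class Genealogy:
    """Append-only genotype table with parent pointers and pruning."""

    _CHUNK = 4096

    def __init__(self) -> None:
        self._n = 0
        cap = self._CHUNK
        self.parent = np.full(cap, -1, dtype=np.int64)
        self.birth = np.zeros(cap, dtype=np.int64)
        self.mut_site = np.full(cap, -1, dtype=np.int32)
        self.mut_from = np.full(cap, -1, dtype=np.int32)
        self.mut_to = np.full(cap, -1, dtype=np.int32)
        self.fitness = np.zeros(cap, dtype=np.float64)
        self._genomes: dict[int, np.ndarray] = {}  # living-lineage genomes
        self._root_genomes: dict[int, np.ndarray] = {}

    def __len__(self) -> int:
        return self._n

    def _grow(self) -> None:
        cap = len(self.parent)
        for name in ("parent", "birth", "mut_site", "mut_from", "mut_to", "fitness"):
            arr = getattr(self, name)
            new = np.empty(cap * 2, dtype=arr.dtype)
            new[:cap] = arr
            setattr(self, name, new)

    def add(
        self,
        parent: int,
        birth: int,
        mutation: tuple[int, int, int] | None,
        fitness: float,
        genome: np.ndarray,
    ) -> int:
        if self._n == len(self.parent):
            self._grow()
        gid = self._n
        self.parent[gid] = parent
        self.birth[gid] = birth
        if mutation is not None:
            self.mut_site[gid], self.mut_from[gid], self.mut_to[gid] = mutation
        else:
            self.mut_site[gid] = self.mut_from[gid] = self.mut_to[gid] = -1
        self.fitness[gid] = fitness
        self._genomes[gid] = genome
        if parent == -1:
            self._root_genomes[gid] = genome
        self._n += 1
        return gid

    def genome_array(self, gid: int) -> np.ndarray:
        """Genome of ``gid``, replayed from the root if not cached."""
        if gid in self._genomes:
            return self._genomes[gid]
        chain = []
        cur = gid
        while cur not in self._root_genomes:
            chain.append(cur)
            cur = int(self.parent[cur])
            if cur < 0:
                raise KeyError(f"genotype {gid} has a broken parent chain")
        g = self._root_genomes[cur].copy()
        for node in reversed(chain):
            g[self.mut_site[node]] = self.mut_to[node]
        return g

    def record(self, gid: int) -> GenealogyRecord:
        if not 0 <= gid < self._n:
            raise KeyError(f"genotype {gid} not present in genealogy")
        mut = None
        if self.mut_site[gid] >= 0:
            mut = (int(self.mut_site[gid]), int(self.mut_from[gid]), int(self.mut_to[gid]))
        return GenealogyRecord(
            gid=gid,
            genome=Genome.from_array(self.genome_array(gid)),
            fitness=float(self.fitness[gid]),
            parent=int(self.parent[gid]),
            mutation=mut,
            birth=int(self.birth[gid]),
        )

    def ancestors_closure(self, living: np.ndarray) -> np.ndarray:
        keep = np.zeros(self._n, dtype=bool)
        for gid in living:
            cur = int(gid)
            while cur != -1 and not keep[cur]:
                keep[cur] = True
                cur = int(self.parent[cur])
        return keep

    def prune(self, living: np.ndarray) -> np.ndarray:
        """Drop records not ancestral to ``living``; return old->new id map."""
        keep = self.ancestors_closure(living)
        old_ids = np.flatnonzero(keep)
        remap = np.full(self._n, -1, dtype=np.int64)
        remap[old_ids] = np.arange(len(old_ids))
        n_new = len(old_ids)
        for name in ("parent", "birth", "mut_site", "mut_from", "mut_to", "fitness"):
            arr = getattr(self, name)
            arr[:n_new] = arr[old_ids]
        # parents are always older than children, so remap is order-safe
        par = self.parent[:n_new]
        par[par >= 0] = remap[par[par >= 0]]
        live_set = set(int(g) for g in living)
        self._genomes = {
            int(remap[g]): arr for g, arr in self._genomes.items() if keep[g] and int(g) in live_set
        }
        self._root_genomes = {
            int(remap[g]): arr for g, arr in self._root_genomes.items() if keep[g]
        }
        self._n = n_new
        return remap


@dataclass
class EvolutionRun:
    """Final state of a forward-evolution run."""

    population: np.ndarray  # genotype id per individual
    genealogy: Genealogy
    landscape: SyntheticLandscape
    config: EvolutionConfig
    generations_run: int = 0

    def fitnesses(self) -> np.ndarray:
        return self.genealogy.fitness[self.population]


def evolve_population(
    landscape: SyntheticLandscape,
    config: EvolutionConfig,
    ancestor: Genome | None = None,
    initial_population: list[Genome] | None = None,
) -> EvolutionRun:
    """Evolve a constant-size Wright-Fisher population on ``landscape``.

    Starts from ``N`` copies of ``ancestor`` (the landscape wild type by
    default) or from an explicit ``initial_population`` of length ``N``.
    Raises if the whole population becomes non-viable (impossible under
    ``revert_deleterious``).  Identical config and seed give identical
    runs.
    """
    rng = np.random.default_rng(config.seed)
    L, A = landscape.L, landscape.A
    N = config.N
    gen = Genealogy()

    if initial_population is not None:
        if len(initial_population) != N:
            raise ValueError("initial_population must have exactly N genomes")
        ids_by_seq: dict[str, int] = {}
        pop = np.empty(N, dtype=np.int64)
        for i, g in enumerate(initial_population):
            gid = ids_by_seq.get(g.sequence)
            if gid is None:
                arr = landscape._as_array(g)
                gid = gen.add(-1, 0, None, landscape.fitness_of(arr), arr.copy())
                ids_by_seq[g.sequence] = gid
            pop[i] = gid
    else:
        g0 = ancestor if ancestor is not None else landscape.wild_type
        arr = landscape._as_array(g0)
        w0 = landscape.fitness_of(arr)
        if w0 <= 0:
            raise ValueError("ancestor genotype is non-viable")
        root = gen.add(-1, 0, None, w0, arr.copy())
        pop = np.full(N, root, dtype=np.int64)

    mutant_cache: dict[tuple[int, int, int], int] = {}
    t = 0
    for t in range(1, config.generations + 1):
        w = gen.fitness[pop]
        total = w.sum()
        if total <= 0:
            raise RuntimeError(f"population went extinct at generation {t}")
        parents = pop[rng.choice(N, size=N, p=w / total)]
        n_mut = rng.binomial(N, config.U) if config.U > 0 else 0
        if n_mut:
            slots = rng.choice(N, size=n_mut, replace=False).tolist()
            sites = rng.integers(0, L, size=n_mut).tolist()
            offsets = rng.integers(1, A, size=n_mut).tolist()
            genomes = gen._genomes
            fitness = gen.fitness
            mutant_fitness = landscape.mutant_fitness
            cache_get = mutant_cache.get
            for slot, site, off in zip(slots, sites, offsets):
                pid = int(parents[slot])
                pg = genomes[pid]
                old = int(pg[site])
                new = (old + off) % A
                key = (pid, site, new)
                gid = cache_get(key)
                if gid is None:
                    wp = float(fitness[pid])
                    wf = mutant_fitness(pg, wp, site, new)
                    if config.revert_deleterious and wf < wp:
                        gid = pid  # mutant prevented from entering the population
                    else:
                        child = pg.copy()
                        child[site] = new
                        gid = gen.add(pid, t, (site, old, new), wf, child)
                    mutant_cache[key] = gid
                parents[slot] = gid
        pop = parents
        if config.prune_interval and t % config.prune_interval == 0:
            remap = gen.prune(np.unique(pop))
            pop = remap[pop]
            mutant_cache.clear()
        if config.stop_when_monomorphic and len(np.unique(pop)) == 1:
            break

    remap = gen.prune(np.unique(pop))
    pop = remap[pop]
    return EvolutionRun(
        population=pop,
        genealogy=gen,
        landscape=landscape,
        config=config,
        generations_run=t if config.generations else 0,
    )


def most_abundant_genotype(run: EvolutionRun) -> GenealogyRecord:
    """The most common genotype in the final population.

    Ties are broken by earliest birth generation, then lowest id.
    """
    ids, counts = np.unique(run.population, return_counts=True)
    order = sorted(
        range(len(ids)),
        key=lambda i: (-counts[i], run.genealogy.birth[ids[i]], ids[i]),
    )
    return run.genealogy.record(int(ids[order[0]]))


def extract_lod(genealogy: Genealogy, focal: int | GenealogyRecord) -> LineOfDescent:
    """Line of descent from the ancestor to ``focal`` (id or record)."""
    gid = focal.gid if isinstance(focal, GenealogyRecord) else int(focal)
    if not 0 <= gid < len(genealogy):
        raise KeyError(f"focal genotype {gid} not found in genealogy")
    chain = []
    cur = gid
    while cur != -1:
        chain.append(cur)
        cur = int(genealogy.parent[cur])
    return LineOfDescent(genealogy.record(g) for g in reversed(chain))


def drift_robustness_assay(
    genotype: Genome,
    landscape: SyntheticLandscape,
    replicates: int = 10,
    N_test: int = 50,
    generations_test: int = 1000,
    seed: int = 0,
    U: float = 0.1,
) -> np.ndarray:
    """Relative fitness after evolving ``genotype`` under strong drift.

    Seeds ``replicates`` populations of ``N_test`` clones of
    ``genotype``, evolves each for ``generations_test`` generations, and
    returns ``w(final most-abundant) / w(genotype)`` per replicate.
    """
    w0 = landscape.fitness_of(genotype)
    if w0 <= 0:
        raise ValueError("assayed genotype must be viable")
    out = np.empty(replicates)
    for r in range(replicates):
        cfg = EvolutionConfig(
            N=N_test,
            generations=generations_test,
            U=U,
            seed=derive_seed(seed, "drift-assay", r),
        )
        run = evolve_population(landscape, cfg, ancestor=genotype)
        out[r] = most_abundant_genotype(run).fitness / w0
    return out
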