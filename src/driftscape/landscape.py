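"""Synthetic genotype-fitness landscapes with tunable drift robustness.

A landscape maps genomes (length-``L`` strings over an ``A``-letter
alphabet) to non-negative multiplicative fitness, built from five site
classes:

``core_lethal``
    any non-wild state is non-viable (fitness 0) — the replication core.
``additive_small``
    non-wild states carry independent multiplicative factors.  *Plain*
    sites offer only small deleterious effects (< 5 %).  *Pathway*
    sites carry one (or a few) weakly beneficial states, a handful of
    exactly-neutral states, and large-effect deleterious states
    elsewhere; the occupied beneficial states are the *drift-fragile*
    gains — individually almost neutral at small population sizes, so
    only large populations hold them — and every occupied site adds its
    reversion states to the small-effect deleterious neighborhood.
``module_member``
    sites of an epistatic module; when every member holds its target
    state the module contributes a single large benefit, so losing any
    member is a large-effect deleterious mutation.
``modifier``
    a locus with one ON state granting a direct benefit and converting
    every mutation at its target sites (a set of beneficial-bearing
    additive sites) into a lethal.  A modifier is the single large
    *drift-robust* step: it trades the targets' combined small
    beneficials for a slightly smaller one-step gain and a mutational
    neighborhood purged of small-effect deleterious mutations.
``neutral``
    all states exactly neutral (factor 1).

The ON state of a modifier is itself lethal on any background where one
of its targets is non-wild, giving genuine sign epistasis: the fragile
and robust configurations are alternative peaks connected only through
the wild-type configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ALPHABET",
    "Genome",
    "Module",
    "Modifier",
    "LandscapeConfig",
    "SyntheticLandscape",
    "generate_landscape",
    "fitness_of",
    "enumerate_point_mutants",
    "drift_fragile_config",
    "drift_robust_config",
    "peak_genotype",
    "write_genomes_fasta",
    "read_genomes_fasta",
]

ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

SITE_CLASSES = ("core_lethal", "additive_small", "module_member", "neutral", "modifier")


@dataclass(frozen=True)
class Genome:
    """An immutable genome: a string over the first ``A`` letters."""

    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence or not set(self.sequence) <= set(ALPHABET):
            raise ValueError("genome must be a non-empty string over A-Z")

    def __len__(self) -> int:
        return len(self.sequence)

    def to_array(self) -> np.ndarray:
        return np.frombuffer(self.sequence.encode("ascii"), dtype=np.uint8) - ord("A")

    @classmethod
    def from_array(cls, states: np.ndarray) -> "Genome":
        return cls((np.asarray(states, dtype=np.uint8) + ord("A")).tobytes().decode("ascii"))


@dataclass(frozen=True)
class Module:
    """An epistatic module: full benefit only when all members hit targets."""

    members: tuple[int, ...]
    targets: tuple[int, ...]
    benefit: float


@dataclass(frozen=True)
class Modifier:
    """A robustness modifier locus.

    When ``site`` holds ``on_state`` the genotype gains ``benefit`` and
    every mutation away from wild at the ``targets`` sites is lethal;
    conversely the ON state itself is lethal if any target is non-wild.
    """

    site: int
    on_state: int
    targets: tuple[int, ...]
    benefit: float


@dataclass
class LandscapeConfig:
    """Generator parameters for a synthetic landscape.

    Class fractions must sum to 1; they are converted to site counts by
    largest remainder.  Effect sizes are multiplicative: a deleterious
    effect ``d`` gives factor ``1 - d``, a beneficial effect ``b`` gives
    ``1 + b``.  Defaults give a 50-site, 26-letter genome with about a
    third lethal point mutations and coexisting small-effect (< 5 %)
    and large-effect (>= 5 %) deleterious classes.
    """

    L: int = 50
    A: int = 26
    fractions: dict[str, float] = field(
        default_factory=lambda: {
            "core_lethal": 0.34,
            "additive_small": 0.40,
            "module_member": 0.08,
            "neutral": 0.14,
            "modifier": 0.04,
        }
    )
    deleterious_effect_range: tuple[float, float] = (0.001, 0.03)
    beneficial_effect_range: tuple[float, float] = (0.002, 0.004)
    beneficial_states_per_site: int = 1
    pathway_neutral_states: int = 3
    pathway_deleterious_range: tuple[float, float] = (0.05, 0.4)
    module_count: int = 2
    module_size: int = 2
    module_benefit_range: tuple[float, float] = (0.05, 0.08)
    member_deleterious_range: tuple[float, float] = (0.05, 0.5)
    modifier_count: int = 2
    targets_per_modifier: int = 3
    modifier_benefit: float = 0.04
    extra_beneficial_sites: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L <= 0 or not 2 <= self.A <= len(ALPHABET):
            raise ValueError("need L > 0 and 2 <= A <= 26")
        unknown = set(self.fractions) - set(SITE_CLASSES)
        if unknown:
            raise ValueError(f"unknown site classes: {sorted(unknown)}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"site-class fractions must sum to 1, got {total}")

    def site_counts(self) -> dict[str, int]:
        """Largest-remainder apportionment of ``L`` sites to classes."""
        quotas = {c: self.fractions.get(c, 0.0) * self.L for c in SITE_CLASSES}
        counts = {c: int(np.floor(q)) for c, q in quotas.items()}
        short = self.L - sum(counts.values())
        for c in sorted(quotas, key=lambda c: quotas[c] - counts[c], reverse=True)[:short]:
            counts[c] += 1
        return counts

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        Path(path).write_text(yaml.safe_dump({"landscape": data}, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LandscapeConfig":
        data = yaml.safe_load(Path(path).read_text())["landscape"]
        for key in (
            "deleterious_effect_range",
            "beneficial_effect_range",
            "pathway_deleterious_range",
            "module_benefit_range",
            "member_deleterious_range",
        ):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class SyntheticLandscape:
    """A concrete genotype-fitness map.

    ``factor[site, state]`` holds the per-site multiplicative factor
    (wild state 1.0; 0.0 marks a lethal state); modules and modifiers
    add the epistatic structure on top.
    """

    L: int
    A: int
    wild: np.ndarray  # (L,) wild state per site
    site_class: tuple[str, ...]
    factor: np.ndarray  # (L, A)
    modules: tuple[Module, ...] = ()
    modifiers: tuple[Modifier, ...] = ()
    seed: int | None = None
    config: LandscapeConfig | None = None

    def __post_init__(self) -> None:
        self.wild = np.asarray(self.wild, dtype=np.int64)
        self.factor = np.asarray(self.factor, dtype=float)
        if self.factor.shape != (self.L, self.A) or self.wild.shape != (self.L,):
            raise ValueError("factor table / wild vector shape mismatch")
        if np.any(self.factor < 0):
            raise ValueError("fitness factors must be non-negative")
        if not np.allclose(self.factor[np.arange(self.L), self.wild], 1.0):
            raise ValueError("wild states must carry factor 1 (wild-type fitness 1)")
        # site -> modifier that targets it, and site -> module index
        self._target_of: dict[int, Modifier] = {}
        for mod in self.modifiers:
            for t in mod.targets:
                self._target_of[t] = mod
        self._module_of: dict[int, Module] = {}
        for m in self.modules:
            for site in m.members:
                self._module_of[site] = m

    # -- core fitness evaluation ------------------------------------------

    @property
    def wild_type(self) -> Genome:
        return Genome.from_array(self.wild)

    def _as_array(self, genome: "Genome | np.ndarray") -> np.ndarray:
        arr = genome.to_array() if isinstance(genome, Genome) else np.asarray(genome)
        if arr.shape != (self.L,):
            raise ValueError(f"genome length {arr.shape} does not match L={self.L}")
        if arr.max(initial=0) >= self.A or arr.min(initial=0) < 0:
            raise ValueError("genome uses states outside the landscape alphabet")
        return arr

    def fitness_of(self, genome: "Genome | np.ndarray") -> float:
        """Multiplicative fitness; 0 marks a non-viable genotype."""
        g = self._as_array(genome)
        w = float(np.prod(self.factor[np.arange(self.L), g]))
        if w == 0.0:
            return 0.0
        for mod in self.modifiers:
            if g[mod.site] == mod.on_state:
                if np.any(g[list(mod.targets)] != self.wild[list(mod.targets)]):
                    return 0.0
                w *= 1.0 + mod.benefit
        for m in self.modules:
            if all(g[site] == tgt for site, tgt in zip(m.members, m.targets)):
                w *= 1.0 + m.benefit
        return w

    def mutant_fitness(
        self, genome: np.ndarray, w_parent: float, site: int, new_state: int
    ) -> float:
        """Fitness of ``genome`` with ``site -> new_state``, in O(1).

        ``w_parent`` must be the (viable, > 0) fitness of ``genome``.
        Exactly equal to ``fitness_of`` of the mutated genome.
        """
        old = int(genome[site])
        cls = self.site_class[site]
        wild = int(self.wild[site])
        if cls == "core_lethal":
            return 0.0 if new_state != wild else w_parent / self.factor[site, old]
        if cls == "neutral":
            return w_parent
        if cls == "additive_small":
            mod = self._target_of.get(site)
            if mod is not None and genome[mod.site] == mod.on_state and new_state != wild:
                return 0.0
            return w_parent * self.factor[site, new_state] / self.factor[site, old]
        if cls == "modifier":
            mod = next(m for m in self.modifiers if m.site == site)
            on_before = old == mod.on_state
            on_after = new_state == mod.on_state
            w = w_parent * self.factor[site, new_state] / self.factor[site, old]
            if on_after and not on_before:
                tg = list(mod.targets)
                if np.any(genome[tg] != self.wild[tg]):
                    return 0.0
                w *= 1.0 + mod.benefit
            elif on_before and not on_after:
                w /= 1.0 + mod.benefit
            return w
        # module member
        m = self._module_of[site]
        before = all(genome[s] == t for s, t in zip(m.members, m.targets))
        tgt = dict(zip(m.members, m.targets))[site]
        after = (new_state == tgt) and all(
            genome[s] == t for s, t in zip(m.members, m.targets) if s != site
        )
        w = w_parent * self.factor[site, new_state] / self.factor[site, old]
        if after and not before:
            w *= 1.0 + m.benefit
        elif before and not after:
            w /= 1.0 + m.benefit
        return w


def fitness_of(landscape: SyntheticLandscape, genome: Genome | np.ndarray) -> float:
    """Module-level convenience for :meth:`SyntheticLandscape.fitness_of`."""
    return landscape.fitness_of(genome)


def enumerate_point_mutants(
    landscape: SyntheticLandscape, genome: Genome | np.ndarray
) -> list[tuple[int, int, float]]:
    """All ``(A - 1) * L`` point mutants as ``(site, new_state, fitness)``.

    Enumeration is site-major, states ascending, skipping the current
    state; each fitness equals ``fitness_of`` of the mutated genome.
    """
    g = landscape._as_array(genome)
    w0 = landscape.fitness_of(g)
    out: list[tuple[int, int, float]] = []
    if w0 > 0:
        for site in range(landscape.L):
            cur = int(g[site])
            for state in range(landscape.A):
                if state == cur:
                    continue
                out.append((site, state, landscape.mutant_fitness(g, w0, site, state)))
    else:  # non-viable reference: fall back to full evaluation
        for site in range(landscape.L):
            cur = int(g[site])
            for state in range(landscape.A):
                if state == cur:
                    continue
                mutant = g.copy()
                mutant[site] = state
                out.append((site, state, landscape.fitness_of(mutant)))
    return out


def generate_landscape(config: LandscapeConfig) -> SyntheticLandscape:
    """Draw a landscape from the generator distribution (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    L, A = config.L, config.A
    counts = config.site_counts()
    if config.module_count * config.module_size != counts["module_member"]:
        raise ValueError(
            "module_count * module_size must equal the number of module_member sites "
            f"({config.module_count}*{config.module_size} != {counts['module_member']})"
        )
    if config.modifier_count != counts["modifier"]:
        raise ValueError(
            f"modifier_count ({config.modifier_count}) must equal the number of "
            f"modifier sites ({counts['modifier']})"
        )
    needed = config.modifier_count * config.targets_per_modifier + config.extra_beneficial_sites
    if needed > counts["additive_small"]:
        raise ValueError("not enough additive_small sites for modifier targets")

    labels = [c for c in SITE_CLASSES for _ in range(counts[c])]
    order = rng.permutation(L)
    site_class = [""] * L
    for pos, lab in zip(order, labels):
        site_class[pos] = lab

    wild = rng.integers(0, A, size=L)
    factor = np.ones((L, A))
    dlo, dhi = config.deleterious_effect_range
    blo, bhi = config.beneficial_effect_range

    by_class: dict[str, list[int]] = {c: [] for c in SITE_CLASSES}
    for site, lab in enumerate(site_class):
        by_class[lab].append(site)

    for site in by_class["core_lethal"]:
        factor[site, :] = 0.0
        factor[site, wild[site]] = 1.0

    additive = list(by_class["additive_small"])
    rng.shuffle(additive)
    n_targeted = config.modifier_count * config.targets_per_modifier
    bsps = config.beneficial_states_per_site
    pathway = set(additive[: n_targeted + config.extra_beneficial_sites]) if bsps > 0 else set()
    plo, phi = config.pathway_deleterious_range
    for site in sorted(additive):
        nonwild = [a for a in range(A) if a != wild[site]]
        if site in pathway:
            factor[site, nonwild] = 1.0 - rng.uniform(plo, phi, size=len(nonwild))
            k_neut = min(config.pathway_neutral_states, len(nonwild) - bsps)
            k_ben = min(bsps, len(nonwild) - k_neut)
            chosen = rng.choice(nonwild, size=k_neut + k_ben, replace=False)
            factor[site, chosen[:k_neut]] = 1.0
            factor[site, chosen[k_neut:]] = 1.0 + rng.uniform(blo, bhi, size=k_ben)
        else:
            factor[site, nonwild] = 1.0 - rng.uniform(dlo, dhi, size=len(nonwild))

    # epistatic modules over their member sites
    mlo, mhi = config.member_deleterious_range
    modules: list[Module] = []
    members = by_class["module_member"]
    for i in range(config.module_count):
        mem = tuple(members[i * config.module_size : (i + 1) * config.module_size])
        tgts = []
        for site in mem:
            nonwild = [a for a in range(A) if a != wild[site]]
            factor[site, nonwild] = 1.0 - rng.uniform(mlo, mhi, size=len(nonwild))
            tgt = int(rng.choice(nonwild))
            factor[site, tgt] = 1.0  # neutral alone, beneficial in concert
            tgts.append(tgt)
        benefit = float(rng.uniform(*config.module_benefit_range))
        modules.append(Module(members=mem, targets=tuple(tgts), benefit=benefit))

    modifiers: list[Modifier] = []
    for i, site in enumerate(by_class["modifier"]):
        nonwild = [a for a in range(A) if a != wild[site]]
        on_state = int(rng.choice(nonwild))
        tg = tuple(
            additive[i * config.targets_per_modifier : (i + 1) * config.targets_per_modifier]
        )
        modifiers.append(
            Modifier(site=site, on_state=on_state, targets=tg, benefit=config.modifier_benefit)
        )

    return SyntheticLandscape(
        L=L,
        A=A,
        wild=wild,
        site_class=tuple(site_class),
        factor=factor,
        modules=tuple(modules),
        modifiers=tuple(modifiers),
        seed=config.seed,
        config=config,
    )


def drift_fragile_config(seed: int = 0) -> LandscapeConfig:
    """Preset: additive small-effect routes only (no modules, no modifiers).

    Its peak genotype (all beneficial states occupied) has a mutational
    neighborhood whose viable deleterious mutations are all < 5 %.
    """
    return LandscapeConfig(
        fractions={
            "core_lethal": 0.34,
            "additive_small": 0.42,
            "module_member": 0.0,
            "neutral": 0.24,
            "modifier": 0.0,
        },
        deleterious_effect_range=(0.001, 0.035),
        beneficial_effect_range=(0.004, 0.012),
        beneficial_states_per_site=2,
        pathway_deleterious_range=(0.001, 0.035),
        module_count=0,
        module_size=0,
        modifier_count=0,
        targets_per_modifier=0,
        extra_beneficial_sites=21,
        seed=seed,
    )


def drift_robust_config(seed: int = 0) -> LandscapeConfig:
    """Preset: modules and modifiers only (no small beneficial routes).

    Its peak genotype (modules complete, modifiers ON) has a mutational
    neighborhood whose viable deleterious mutations are all >= 5 %.
    """
    return LandscapeConfig(
        fractions={
            "core_lethal": 0.34,
            "additive_small": 0.24,
            "module_member": 0.16,
            "neutral": 0.20,
            "modifier": 0.06,
        },
        beneficial_effect_range=(0.004, 0.012),
        beneficial_states_per_site=2,
        module_count=2,
        module_size=4,
        module_benefit_range=(0.06, 0.12),
        modifier_count=3,
        targets_per_modifier=4,
        modifier_benefit=0.06,
        extra_beneficial_sites=0,
        seed=seed,
    )


def peak_genotype(landscape: SyntheticLandscape, kind: str = "robust") -> Genome:
    """A fitness-peak genotype of the landscape.

    ``kind='robust'``: modules complete and modifiers ON (targets wild).
    ``kind='fragile'``: modules complete and, per additive site, the
    best available state occupied, modifiers OFF.
    """
    g = landscape.wild.copy()
    for m in landscape.modules:
        for site, tgt in zip(m.members, m.targets):
            g[site] = tgt
    if kind == "robust":
        for mod in landscape.modifiers:
            g[mod.site] = mod.on_state
    elif kind == "fragile":
        for site, lab in enumerate(landscape.site_class):
            if lab == "additive_small":
                g[site] = int(np.argmax(landscape.factor[site]))
    else:
        raise ValueError(f"unknown peak kind {kind!r}")
    return Genome.from_array(g)


# -- plain-text IO ---------------------------------------------------------


def write_genomes_fasta(path: str | Path, genomes: Mapping[str, Genome]) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=str(name), description="") for name, g in genomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genomes_fasta(path: str | Path) -> dict[str, Genome]:
    return {rec.id: Genome(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}
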