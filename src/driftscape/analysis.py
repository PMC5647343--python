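"""DFE classification and line-of-descent analysis.

Every point mutant of a genotype is assigned one of five exhaustive,
mutually exclusive classes from its relative fitness effect
``s = w_m / w_0 - 1``:

* ``lethal`` — non-viable (``w_m = 0``);
* ``beneficial`` — ``s > 0``;
* ``neutral`` — ``|s|`` below an exactness tolerance (the synthetic
  landscapes make neutral mutations exactly neutral);
* ``deleterious_small`` — viable, ``-0.05 < s < 0``;
* ``deleterious_large`` — viable, ``s <= -0.05`` (a 5 % effect counts
  as large).

On top of the per-genotype summaries this module implements the
lineage-level procedures: detection of *maintained* beneficial steps on
a line of descent, matching of equal-fitness genotype cohorts between
treatments, per-step epistatic signatures (changes in deleterious and
lethal likelihoods), and rank-based treatment comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .evolve import LineOfDescent
from .landscape import ALPHABET, Genome, SyntheticLandscape, enumerate_point_mutants

__all__ = [
    "MutationClass",
    "DFESummary",
    "MaintainedBeneficial",
    "EpistaticSignature",
    "ComparisonReport",
    "classify_mutation",
    "dfe_summary",
    "dfe_table",
    "maintained_beneficials",
    "equal_fitness_cohorts",
    "epistatic_signatures",
    "compare_treatments",
    "bonferroni",
]

NEUTRAL_TOL = 1e-12
SMALL_EFFECT_THRESHOLD = 0.05


class MutationClass(str, Enum):
    lethal = "lethal"
    deleterious_small = "deleterious_small"
    deleterious_large = "deleterious_large"
    neutral = "neutral"
    beneficial = "beneficial"


def classify_mutation(w_parent: float, w_mutant: float) -> MutationClass:
    """Classify a point mutation from parent and mutant fitness."""
    if w_parent <= 0:
        raise ValueError("reference genotype must be viable (w_parent > 0)")
    if w_mutant == 0:
        return MutationClass.lethal
    s = w_mutant / w_parent - 1.0
    if abs(s) < NEUTRAL_TOL:
        return MutationClass.neutral
    if s > 0:
        return MutationClass.beneficial
    if s > -SMALL_EFFECT_THRESHOLD:
        return MutationClass.deleterious_small
    return MutationClass.deleterious_large


@dataclass
class DFESummary:
    """Per-genotype distribution of fitness effects over all point mutants."""

    f_lethal: float
    f_deleterious_small: float
    f_deleterious_large: float
    f_neutral: float
    f_beneficial: float
    mean_mutant_relative_fitness: float
    n_mutants: int
    genotype_id: object = None
    label: str | None = None

    @property
    def f_deleterious(self) -> float:
        """Viable deleterious likelihood (small + large)."""
        return self.f_deleterious_small + self.f_deleterious_large

    def as_dict(self) -> dict[str, object]:
        return {
            "genotype_id": self.genotype_id,
            "label": self.label,
            "f_lethal": self.f_lethal,
            "f_deleterious_small": self.f_deleterious_small,
            "f_deleterious_large": self.f_deleterious_large,
            "f_neutral": self.f_neutral,
            "f_beneficial": self.f_beneficial,
            "mean_mutant_relative_fitness": self.mean_mutant_relative_fitness,
            "n_mutants": self.n_mutants,
        }


def dfe_summary(
    landscape: SyntheticLandscape,
    genotype: Genome | np.ndarray,
    genotype_id: object = None,
    label: str | None = None,
) -> DFESummary:
    """Enumerate and classify all ``(A-1)*L`` point mutants of ``genotype``."""
    w0 = landscape.fitness_of(genotype)
    if w0 <= 0:
        raise ValueError("cannot summarise the DFE of a non-viable genotype")
    mutants = enumerate_point_mutants(landscape, genotype)
    counts = {cls: 0 for cls in MutationClass}
    total_rel = 0.0
    for _site, _state, wm in mutants:
        counts[classify_mutation(w0, wm)] += 1
        total_rel += wm / w0
    n = len(mutants)
    return DFESummary(
        f_lethal=counts[MutationClass.lethal] / n,
        f_deleterious_small=counts[MutationClass.deleterious_small] / n,
        f_deleterious_large=counts[MutationClass.deleterious_large] / n,
        f_neutral=counts[MutationClass.neutral] / n,
        f_beneficial=counts[MutationClass.beneficial] / n,
        mean_mutant_relative_fitness=total_rel / n,
        n_mutants=n,
        genotype_id=genotype_id,
        label=label,
    )


def dfe_table(landscape: SyntheticLandscape, genotype: Genome | np.ndarray) -> pd.DataFrame:
    """Full mutant table: site, from/to state, fitness, effect, class."""
    g = landscape._as_array(genotype)
    w0 = landscape.fitness_of(g)
    rows = []
    for site, state, wm in enumerate_point_mutants(landscape, g):
        rows.append(
            {
                "site": site,
                "from_state": ALPHABET[g[site]],
                "to_state": ALPHABET[state],
                "w_mutant": wm,
                "s_effect": wm / w0 - 1.0,
                "class": classify_mutation(w0, wm).value,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MaintainedBeneficial:
    """A beneficial LOD step whose gain was at least partially maintained."""

    lod_index: int
    s_effect: float
    w_before: float
    w_after: float
    pre_deleterious: float | None = None
    post_deleterious: float | None = None
    pre_lethal: float | None = None
    post_lethal: float | None = None
    pre_deleterious_small: float | None = None
    post_deleterious_small: float | None = None


def maintained_beneficials(
    fitness_series: Sequence[float] | LineOfDescent,
    transient_length: int = 5,
    require_recovery: bool = True,
    baseline: str = "previous",
) -> list[MaintainedBeneficial]:
    """Maintained beneficial steps along a line of descent.

    A beneficial step at index ``i`` (``w_i > w_{i-1}``) is maintained
    iff it attains a new running fitness maximum and fitness never
    subsequently drops below the pre-step value ``w_{i-1}`` for
    ``transient_length`` or more consecutive LOD entries; shorter dips
    must recover to at least ``w_{i-1}`` (disable the latter with
    ``require_recovery=False``).  ``baseline='running_max'`` instead
    compares dips against the pre-step running maximum.
    """
    if isinstance(fitness_series, LineOfDescent):
        w = list(fitness_series.fitness_series)
    else:
        w = [float(v) for v in fitness_series]
    if len(w) < 2:
        return []
    if baseline not in ("previous", "running_max"):
        raise ValueError("baseline must be 'previous' or 'running_max'")
    out: list[MaintainedBeneficial] = []
    running_max = w[0]
    for i in range(1, len(w)):
        prev_max = running_max
        running_max = max(running_max, w[i])
        if w[i] <= w[i - 1] or w[i] <= prev_max:
            continue  # not beneficial, or not a new fitness maximum
        thr = w[i - 1] if baseline == "previous" else prev_max
        run = 0
        ok = True
        for v in w[i + 1 :]:
            if v < thr:
                run += 1
                if run >= transient_length:
                    ok = False
                    break
            else:
                run = 0
        if ok and require_recovery and run > 0:
            ok = False  # lineage ended inside an unrecovered dip
        if ok:
            out.append(
                MaintainedBeneficial(
                    lod_index=i,
                    s_effect=w[i] / w[i - 1] - 1.0,
                    w_before=w[i - 1],
                    w_after=w[i],
                )
            )
    return out


def _fitness_key(value: float, bin_rel_tol: float) -> float:
    if bin_rel_tol <= 0:
        return value
    return round(math.log(value) / math.log1p(bin_rel_tol))


def equal_fitness_cohorts(
    lods_small: Iterable[LineOfDescent],
    lods_large: Iterable[LineOfDescent],
    min_lineages: int = 20,
    bin_rel_tol: float = 0.0,
) -> dict[float, tuple[list, list]]:
    """Match equal-fitness genotype cohorts between two treatments.

    For each lineage and fitness value the *last* genotype at that value
    is taken; only fitness values represented by strictly more than
    ``min_lineages`` lineages in *both* treatments are retained.
    ``bin_rel_tol`` > 0 bins fitness values to that relative tolerance
    (landscapes with continuous effects rarely repeat values exactly).
    Returns ``{fitness_key: ([small records], [large records])}``;
    empty if no value qualifies.
    """

    def last_per_value(lods):
        per_value: dict[float, list] = {}
        for lod in lods:
            seen: dict[float, object] = {}
            for rec in lod:  # later entries overwrite: keeps the last genotype
                seen[_fitness_key(rec.fitness, bin_rel_tol)] = rec
            for key, rec in seen.items():
                per_value.setdefault(key, []).append(rec)
        return per_value

    small = last_per_value(lods_small)
    large = last_per_value(lods_large)
    cohorts = {}
    for key in sorted(set(small) & set(large)):
        if len(small[key]) > min_lineages and len(large[key]) > min_lineages:
            cohorts[key] = (small[key], large[key])
    return cohorts


@dataclass
class EpistaticSignature:
    """Pre/post mutational-neighborhood change of one maintained step."""

    step: MaintainedBeneficial
    deleterious_drop: float
    lethal_rise: float
    relative_drop: float
    small_effect_share: float | None
    flag_relative: bool  # deleterious likelihood halved or better
    flag_absolute: bool  # absolute drop of at least 0.1


def epistatic_signatures(
    lod: LineOfDescent,
    landscape: SyntheticLandscape,
    relative_threshold: float = 0.5,
    absolute_threshold: float = 0.1,
    **maintained_kwargs,
) -> list[EpistaticSignature]:
    """Epistatic signatures of the maintained beneficial steps of a LOD.

    For each maintained step, compares the viable-deleterious and lethal
    likelihoods of the genotype before and after the step, flags drops
    of at least ``relative_threshold`` (relative) or
    ``absolute_threshold`` (absolute), and reports the share of the
    deleterious decrease attributable to the small-effect class.
    """
    steps = maintained_beneficials(lod, **maintained_kwargs)
    out: list[EpistaticSignature] = []
    for step in steps:
        pre = dfe_summary(landscape, lod[step.lod_index - 1].genome)
        post = dfe_summary(landscape, lod[step.lod_index].genome)
        step.pre_deleterious = pre.f_deleterious
        step.post_deleterious = post.f_deleterious
        step.pre_lethal = pre.f_lethal
        step.post_lethal = post.f_lethal
        step.pre_deleterious_small = pre.f_deleterious_small
        step.post_deleterious_small = post.f_deleterious_small
        drop = pre.f_deleterious - post.f_deleterious
        rel = drop / pre.f_deleterious if pre.f_deleterious > 0 else 0.0
        share = None
        if drop > 0:
            share = (pre.f_deleterious_small - post.f_deleterious_small) / drop
        out.append(
            EpistaticSignature(
                step=step,
                deleterious_drop=drop,
                lethal_rise=post.f_lethal - pre.f_lethal,
                relative_drop=rel,
                small_effect_share=share,
                flag_relative=rel >= relative_threshold,
                flag_absolute=drop >= absolute_threshold,
            )
        )
    return out


@dataclass
class ComparisonReport:
    """One-tailed rank comparison of a metric between two treatments."""

    metric: str
    median_a: float
    median_b: float
    U: float
    p_value: float
    alternative: str
    n_a: int
    n_b: int
    spearman_rho: float | None = None
    spearman_p: float | None = None


def compare_treatments(
    values_a: Sequence[float],
    values_b: Sequence[float],
    metric: str = "",
    alternative: str = "less",
    covariates: tuple[Sequence[float], Sequence[float]] | None = None,
) -> ComparisonReport:
    """Mann-Whitney U comparison (one-tailed by default) of two groups.

    ``alternative`` states the hypothesised direction of group A versus
    group B.  If ``covariates=(x, y)`` is supplied, a Spearman rank
    correlation between the paired covariates is reported as well.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    rho = p_rho = None
    if covariates is not None:
        x = np.asarray(covariates[0], dtype=float)
        y = np.asarray(covariates[1], dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("constant covariate: Spearman correlation undefined")
        sp = stats.spearmanr(x, y)
        rho, p_rho = float(sp.statistic), float(sp.pvalue)
    return ComparisonReport(
        metric=metric,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        U=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        n_a=len(a),
        n_b=len(b),
        spearman_rho=rho,
        spearman_p=p_rho,
    )


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni-corrected p-values for a family of comparisons."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * len(p), 1.0)
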