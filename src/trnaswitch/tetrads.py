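"""Spore-viability expectations for yeast tetrad analysis.

Models sporulation of a diploid heterozygous (or homozygous) at a small
number of loci: an essential-gene deletion, optional suppressor alleles,
and selection markers.  Meiosis follows Mendelian 2:2 segregation per
heterozygous locus; unlinked loci assort independently (no crossover
interference, no gene conversion), reproducing the 1:1:4 parental-ditype :
non-parental-ditype : tetratype ratio for unlinked gene pairs.  A spore
dies exactly when it carries the essential deletion and no functional
suppressor allele — death is deterministic given genotype.

Expectations are computed exactly by enumerating segregation patterns;
``simulate_tetrads`` provides the matching Monte-Carlo.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

ROLE_DELETION = "essential_deletion"
ROLE_SUPPRESSOR = "suppressor"
ROLE_MARKER = "marker"

GT_HET = "het"
GT_HOM_ALT = "hom_alt"
GT_HOM_REF = "hom_ref"

# the 6 ways to choose which 2 of 4 spores receive the alt allele
_ALT_PATTERNS = tuple(itertools.combinations(range(4), 2))


@dataclass(frozen=True)
class Locus:
    name: str
    role: str
    genotype: str
    linked_to: Optional[str] = None  # same_locus linkage (cis), else unlinked

    def __post_init__(self) -> None:
        if self.role not in (ROLE_DELETION, ROLE_SUPPRESSOR, ROLE_MARKER):
            raise ValueError(f"unknown role {self.role!r}")
        if self.genotype not in (GT_HET, GT_HOM_ALT, GT_HOM_REF):
            raise ValueError(f"unknown genotype {self.genotype!r}")


@dataclass(frozen=True)
class CrossModel:
    """Loci of a diploid cross; the alt allele is the deletion / suppressor /
    marker allele, the ref allele is wild type."""

    loci: tuple[Locus, ...]

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names")
        for l in self.loci:
            if l.linked_to is not None:
                if l.linked_to not in names or l.linked_to == l.name:
                    raise ValueError(
                        f"{l.name}: linked_to {l.linked_to!r} is not another locus"
                    )
                target = next(t for t in self.loci if t.name == l.linked_to)
                if target.linked_to is not None:
                    raise ValueError("linkage chains are not supported")

    def locus(self, name: str) -> Locus:
        return next(l for l in self.loci if l.name == name)


@dataclass(frozen=True)
class TetradOutcome:
    """Genotypes of the four spores of one ascus; True = carries alt allele."""

    spores: tuple[dict, ...]
    viable: tuple[bool, ...]

    @property
    def n_viable(self) -> int:
        return sum(self.viable)


def _spore_is_viable(genotype: dict[str, bool], model: CrossModel) -> bool:
    carries_deletion = any(
        genotype[l.name] for l in model.loci if l.role == ROLE_DELETION
    )
    if not carries_deletion:
        return True
    has_suppressor = any(
        genotype[l.name] for l in model.loci if l.role == ROLE_SUPPRESSOR
    )
    return has_suppressor


def _independent_loci(model: CrossModel) -> list[Locus]:
    return [l for l in model.loci if l.linked_to is None]


def _pattern_space(model: CrossModel):
    """Yield (probability, tetrad genotypes) over all segregation patterns.

    Each independent heterozygous locus picks one of the 6 alt-spore pairs
    uniformly; homozygous loci are constant; a same_locus-linked locus
    copies its partner's pattern (cis configuration).
    """
    indep = _independent_loci(model)
    choices = []
    for l in indep:
        if l.genotype == GT_HET:
            choices.append(_ALT_PATTERNS)
        else:
            choices.append((None,))
    for combo in itertools.product(*choices):
        prob = Fraction(1, 1)
        pattern: dict[str, tuple[int, ...]] = {}
        for l, pick in zip(indep, combo):
            if l.genotype == GT_HET:
                prob *= Fraction(1, len(_ALT_PATTERNS))
                pattern[l.name] = pick
            else:
                pattern[l.name] = (0, 1, 2, 3) if l.genotype == GT_HOM_ALT else ()
        for l in model.loci:
            if l.linked_to is not None:
                if l.genotype == GT_HET:
                    pattern[l.name] = pattern[l.linked_to]
                else:
                    pattern[l.name] = (
                        (0, 1, 2, 3) if l.genotype == GT_HOM_ALT else ()
                    )
        spores = tuple(
            {l.name: (s in pattern[l.name]) for l in model.loci}
            for s in range(4)
        )
        yield prob, spores


def expected_viability(model: CrossModel) -> Fraction:
    """Exact expected fraction of viable spores, by enumeration."""
    total = Fraction(0)
    for prob, spores in _pattern_space(model):
        viable = sum(_spore_is_viable(g, model) for g in spores)
        total += prob * Fraction(viable, 4)
    return total


def marker_fraction(
    model: CrossModel, marker: str, among_viable: bool = True
) -> Optional[Fraction]:
    """Exact expected fraction of spores carrying a marker allele.

    Among all spores a heterozygous marker always segregates to 1/2.  Among
    viable spores the fraction depends on suppression: 0 when every
    marker/deletion spore dies, 1/2 under full suppression.  Returns None
    when no spore is ever viable.
    """
    num = Fraction(0)
    den = Fraction(0)
    for prob, spores in _pattern_space(model):
        for g in spores:
            if among_viable and not _spore_is_viable(g, model):
                continue
            den += prob
            if g[marker]:
                num += prob
    if den == 0:
        return None
    return num / den


def simulate_tetrads(
    model: CrossModel, n_tetrads: int, seed: int = 0
) -> tuple[float, list[TetradOutcome]]:
    """Monte-Carlo tetrads; returns (viable fraction, outcomes).

    Agrees with :func:`expected_viability` within binomial error and is
    reproducible under ``seed``.
    """
    if n_tetrads < 1:
        raise ValueError("need n_tetrads >= 1")
    rng = np.random.default_rng(seed)
    indep = _independent_loci(model)
    outcomes = []
    n_viable_total = 0
    for _ in range(n_tetrads):
        pattern: dict[str, tuple[int, ...]] = {}
        for l in indep:
            if l.genotype == GT_HET:
                pattern[l.name] = _ALT_PATTERNS[rng.integers(len(_ALT_PATTERNS))]
            else:
                pattern[l.name] = (0, 1, 2, 3) if l.genotype == GT_HOM_ALT else ()
        for l in model.loci:
            if l.linked_to is not None:
                if l.genotype == GT_HET:
                    pattern[l.name] = pattern[l.linked_to]
                else:
                    pattern[l.name] = (
                        (0, 1, 2, 3) if l.genotype == GT_HOM_ALT else ()
                    )
        spores = tuple(
            {l.name: (s in pattern[l.name]) for l in model.loci}
            for s in range(4)
        )
        viable = tuple(_spore_is_viable(g, model) for g in spores)
        n_viable_total += sum(viable)
        outcomes.append(TetradOutcome(spores=spores, viable=viable))
    return n_viable_total / (4 * n_tetrads), outcomes


# --- canned crosses from the thermotolerance study design --------------------

def heterozygous_deletion_cross() -> CrossModel:
    """TRT2/trt2::NatMX-style: het essential deletion, marker at the locus."""
    return CrossModel(loci=(
        Locus("trt2_deletion", ROLE_DELETION, GT_HET),
        Locus("natmx_marker", ROLE_MARKER, GT_HET, linked_to="trt2_deletion"),
    ))


def suppressed_deletion_cross(suppressor_genotype: str = GT_HOM_ALT) -> CrossModel:
    """Het essential deletion plus an unlinked anticodon-switch suppressor."""
    return CrossModel(loci=(
        Locus("trt2_deletion", ROLE_DELETION, GT_HET),
        Locus("natmx_marker", ROLE_MARKER, GT_HET, linked_to="trt2_deletion"),
        Locus("anticodon_suppressor", ROLE_SUPPRESSOR, suppressor_genotype),
    ))
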