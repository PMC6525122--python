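"""Synthetic diploid populations and assay behaviour.

Emulates the data-generating process of a multi-locus MHC genotyping
campaign: diploid individuals formed by random union of panel haplotypes
(Hardy-Weinberg sampling), assay profiles with locus-specific or
cross-amplifying primers, allele-specific dropout (e.g. alleles that fail
to amplify from cDNA), positionwise superposition of the 1-4 co-amplified
allele sequences into IUPAC ambiguity codes, length-polymorphic mixtures,
and optional novel alleles injected at a stated divergence.

There is no sequencing-noise model: the observations consumed downstream
are curated consensus sequences, so miscalls enter only through the
dropout and novel-allele knobs.  With those disabled, an individual's
observation under an assay is a deterministic function of its genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .alleledb import Allele, AlleleDatabase, HaplotypePanel
from .deconvolve import (
    NO_PRODUCT,
    LengthConflictError,
    Observation,
    iupac_union,
)

_DNA = "ACGT"

#: Fixed enumeration of child-seed slots: adding operations appends to this
#: table and never perturbs the draws of earlier operations.
_SEED_SLOTS = {"population": 0, "novel": 1, "mutate": 2, "assay": 3}


def child_rng(master_seed: int, operation: str) -> np.random.Generator:
    """Deterministic per-operation generator derived from one master seed."""
    slot = _SEED_SLOTS[operation]
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(slot,)))


@dataclass(frozen=True)
class Region:
    """Sub-interval of an allele sequence amplified by an assay.

    ``anchor`` is "5p" (coordinates from the sequence start, 1-based
    inclusive) or "3p" (the final ``end - start + 1`` bases, accommodating
    a primer that sits downstream of a length polymorphism near the 5'
    end).
    """

    start: int
    end: int
    anchor: str = "5p"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region ({self.start}, {self.end})")
        if self.anchor not in ("5p", "3p"):
            raise ValueError(f"invalid anchor {self.anchor!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def extract(self, sequence: str) -> str:
        if self.anchor == "3p":
            return sequence[-self.length :]
        return sequence[self.start - 1 : self.end]


@dataclass(frozen=True)
class AssayProfile:
    """One PCR/sequencing assay: template, target loci, region, quirks.

    ``allele_dropout`` lists alleles that yield no product under this assay
    (the cDNA-dropout phenomenon); ``extra_alleles`` lists alleles that
    cross-amplify although their locus is not a primary target
    (allele-dependent cross-amplification of imperfectly locus-specific
    primers).
    """

    name: str
    template: str  # "gDNA" | "cDNA"
    amplifies: frozenset[str]
    region: Optional[Region] = None
    allele_dropout: frozenset[str] = frozenset()
    extra_alleles: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.amplifies:
            raise ValueError(f"assay {self.name!r} amplifies no loci")
        if self.template not in ("gDNA", "cDNA"):
            raise ValueError(f"invalid template {self.template!r}")

    def region_sequence(self, sequence: str) -> str:
        return sequence if self.region is None else self.region.extract(sequence)


@dataclass(frozen=True)
class Individual:
    """A diploid individual: an unordered pair of haplotype labels."""

    id: str
    haplotypes: tuple[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "haplotypes", tuple(sorted(self.haplotypes)))

    @property
    def is_homozygous(self) -> bool:
        return self.haplotypes[0] == self.haplotypes[1]


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    ``frequencies`` follows the order of the panel's haplotype labels.
    ``novel_allele_rate`` is the per-individual probability of carrying one
    novel (mutated) allele copy; ``novel_divergence`` is the number of
    substitutions separating it from its parent allele.
    """

    frequencies: Sequence[float]
    n: int
    seed: int
    novel_allele_rate: float = 0.0
    novel_divergence: int = 3
    dropout_enabled: bool = True

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        if (freqs < 0).any():
            raise ValueError("haplotype frequencies must be non-negative")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {freqs.sum()!r}, not 1")
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not 0.0 <= self.novel_allele_rate <= 1.0:
            raise ValueError("novel_allele_rate must be in [0, 1]")
        if self.novel_divergence < 0:
            raise ValueError("novel_divergence must be >= 0")


def sample_population(panel: HaplotypePanel, config: SimConfig) -> list[Individual]:
    """Random-union (Hardy-Weinberg) sampling of diploid individuals."""
    labels = panel.labels
    freqs = np.asarray(config.frequencies, dtype=float)
    if len(freqs) != len(labels):
        raise ValueError(
            f"frequency vector length {len(freqs)} != panel size {len(labels)}"
        )
    rng = child_rng(config.seed, "population")
    width = max(1, len(str(max(config.n, 1))))
    individuals = []
    for i in range(config.n):
        pair = rng.choice(len(labels), size=2, replace=True, p=freqs)
        individuals.append(
            Individual(
                id=f"ind{i + 1:0{width}d}",
                haplotypes=(labels[pair[0]], labels[pair[1]]),
            )
        )
    return individuals


# ---------------------------------------------------------------------------
# Genotype resolution and assay simulation
# ---------------------------------------------------------------------------

#: Overrides map (haplotype slot index 0/1, allele name) -> replacement
#: Allele; used to inject novel alleles into one individual's genotype.
Overrides = Mapping[tuple[int, str], Allele]


def genotype_alleles(
    individual: Individual,
    panel: HaplotypePanel,
    db: AlleleDatabase,
    overrides: Optional[Overrides] = None,
) -> list[tuple[str, Allele]]:
    """The (locus, allele) content of both haplotype copies.

    For an ambiguity-group entry the first name is the designated truth
    allele (group members share the assayed region, so the simulated
    observation is unaffected by the choice).
    """
    overrides = dict(overrides or {})
    out: list[tuple[str, Allele]] = []
    for slot, label in enumerate(individual.haplotypes):
        if label not in panel.rows:
            raise ValueError(f"individual {individual.id!r} references unknown "
                             f"haplotype {label!r}")
        for locus, entries in panel.rows[label].items():
            for entry in entries:
                name = entry[0]
                allele = overrides.get((slot, name), db[name])
                out.append((locus, allele))
    return out


def simulate_assay(
    individual: Individual,
    assay: AssayProfile,
    panel: HaplotypePanel,
    db: AlleleDatabase,
    overrides: Optional[Overrides] = None,
    dropout_enabled: bool = True,
) -> Observation:
    """Observation for one individual under one assay.

    All alleles on both haplotypes at the assay's target loci (plus
    cross-amplified extras, minus dropouts) are superposed positionwise
    over the assay region.  No allele at all yields ``NO_PRODUCT``; alleles
    of unequal region length yield a mixed sequence flagged
    ``length_conflict`` (superposed over the shared prefix).
    """
    content = genotype_alleles(individual, panel, db, overrides)
    picked: list[Allele] = []
    for locus, allele in content:
        amplified = locus in assay.amplifies or allele.name in assay.extra_alleles
        if not amplified:
            continue
        if dropout_enabled and allele.name in assay.allele_dropout:
            continue
        picked.append(allele)
    region_seqs = sorted({assay.region_sequence(a.sequence) for a in picked})
    if not region_seqs:
        return NO_PRODUCT
    try:
        return iupac_union(region_seqs, assay=assay.name)
    except LengthConflictError:
        m = min(len(s) for s in region_seqs)
        return iupac_union(
            [s[:m] for s in region_seqs], assay=assay.name, length_conflict=True
        )


def mutate_allele(allele: Allele, n_subs: int, seed: int) -> Allele:
    """A novel allele at exactly ``n_subs`` substitutions from its parent."""
    if n_subs < 0:
        raise ValueError("n_subs must be >= 0")
    if n_subs > len(allele.sequence):
        raise ValueError("n_subs exceeds sequence length")
    rng = child_rng(seed, "mutate")
    seq = list(allele.sequence)
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    for pos in positions:
        alternatives = [b for b in _DNA if b != seq[pos]]
        seq[pos] = alternatives[rng.integers(len(alternatives))]
    return Allele(
        name=f"{allele.name}~novel{n_subs}s{seed}",
        locus=allele.locus,
        sequence="".join(seq),
        status="novel_unnamed",
        full_length=allele.full_length,
    )


@dataclass
class SimulatedCohort:
    """A population, its observations, and the generating truth."""

    individuals: list[Individual]
    observations: dict[str, dict[str, Observation]]
    novel_truth: dict[str, tuple[str, str]] = field(default_factory=dict)
    # individual id -> (replaced allele name, novel allele name)


def simulate_cohort(
    panel: HaplotypePanel,
    db: AlleleDatabase,
    assays: Sequence[AssayProfile],
    config: SimConfig,
) -> SimulatedCohort:
    """Sample a population and simulate every assay for every individual."""
    individuals = sample_population(panel, config)
    rng = child_rng(config.seed, "novel")
    observations: dict[str, dict[str, Observation]] = {}
    novel_truth: dict[str, tuple[str, str]] = {}
    for k, ind in enumerate(individuals):
        overrides: dict[tuple[int, str], Allele] = {}
        if config.novel_allele_rate > 0 and rng.random() < config.novel_allele_rate:
            slot = int(rng.integers(2))
            label = ind.haplotypes[slot]
            slot_alleles = [
                db[entry[0]]
                for entries in panel.rows[label].values()
                for entry in entries
            ]
            parent = slot_alleles[int(rng.integers(len(slot_alleles)))]
            novel = mutate_allele(
                parent, config.novel_divergence, seed=config.seed * 100003 + k
            )
            overrides[(slot, parent.name)] = novel
            novel_truth[ind.id] = (parent.name, novel.name)
        observations[ind.id] = {
            assay.name: simulate_assay(
                ind, assay, panel, db,
                overrides=overrides, dropout_enabled=config.dropout_enabled,
            )
            for assay in assays
        }
    return SimulatedCohort(individuals, observations, novel_truth)


# ---------------------------------------------------------------------------
# Truth tables
# ---------------------------------------------------------------------------

def write_population(individuals: Iterable[Individual], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\thaplotype1\thaplotype2\n")
        for ind in individuals:
            fh.write(f"{ind.id}\t{ind.haplotypes[0]}\t{ind.haplotypes[1]}\n")


def read_population(path: str | Path) -> list[Individual]:
    individuals = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            if not line.strip():
                continue
            iid, h1, h2 = line.rstrip("\n").split("\t")
            individuals.append(Individual(id=iid, haplotypes=(h1, h2)))
    return individuals


def homozygote_fraction(individuals: Sequence[Individual]) -> float:
    if not individuals:
        return float("nan")
    return sum(ind.is_homozygous for ind in individuals) / len(individuals)
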