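"""Genotype calling from mixed Sanger consensus sequences.

A diploid PCR product that co-amplifies several alleles (heterozygosity
and/or cross-locus amplification) yields, per position, the superposition
of the bases present, written as an IUPAC ambiguity code.  The calling rule
implemented here is strict accounting: a genotype is called only when a
set of known alleles reproduces *every* observed variant exactly --- the
positionwise union of the candidate set must equal the observed codes, not
merely be contained in them.  All cardinality-minimal explaining sets are
reported; a single minimal set is a call, several are an ambiguous call,
and none marks a suspected novel allele.

Candidates that are identical over the assayed region are collapsed into a
single ambiguity group before the search, so indistinguishability yields a
called group rather than a spurious ambiguity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio.Data.IUPACData import ambiguous_dna_values

from .alleledb import Allele, AlleleDatabase, Entry

# The 15 standard IUPAC nucleotide codes (Biopython's table includes the
# non-standard X synonym for N, which we exclude).
CODE_TO_BASES: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code != "X"
}
BASES_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in CODE_TO_BASES.items()}
VALID_CODES = frozenset(CODE_TO_BASES)


class LengthConflictError(ValueError):
    """Sequences of unequal length cannot be superposed positionwise."""


@dataclass(frozen=True)
class MixedSequence:
    """Per-position IUPAC consensus of co-amplified alleles."""

    codes: str
    assay: str = ""
    length_conflict: bool = False

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError("mixed sequence must be non-empty")
        bad = set(self.codes) - VALID_CODES
        if bad:
            raise ValueError(f"invalid IUPAC codes {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.codes)


class _NoProduct:
    """Sentinel: the assay yielded no PCR product (a value, not an error)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NO_PRODUCT"


NO_PRODUCT = _NoProduct()

Observation = Union[MixedSequence, _NoProduct]

CALL_STATUSES = (
    "called",
    "ambiguous",
    "novel_suspected",
    "uncallable_frameshift",
    "no_product",
)


@dataclass(frozen=True)
class GenotypeCall:
    """Outcome of deconvolving one observation against a database.

    ``explanations`` holds every cardinality-minimal explaining set; each
    explanation is a frozenset of entries, where an entry is a tuple of
    allele names (length > 1 for an ambiguity group of alleles identical
    over the assayed region).
    """

    status: str
    explanations: tuple[frozenset[Entry], ...] = ()
    assay: str = ""

    def __post_init__(self) -> None:
        if self.status not in CALL_STATUSES:
            raise ValueError(f"invalid call status {self.status!r}")
        if self.status == "called" and len(self.explanations) != 1:
            raise ValueError("a called genotype has exactly one minimal explanation")
        if self.status == "ambiguous" and len(self.explanations) < 2:
            raise ValueError("an ambiguous genotype has >= 2 minimal explanations")

    @property
    def entry_set(self) -> Optional[frozenset[Entry]]:
        """The unique explanation, when called."""
        return self.explanations[0] if self.status == "called" else None

    def allele_names(self) -> set[str]:
        out: set[str] = set()
        for exp in self.explanations:
            for entry in exp:
                out.update(entry)
        return out


# ---------------------------------------------------------------------------
# Superposition and compatibility
# ---------------------------------------------------------------------------

def iupac_union(
    sequences: Sequence[str], assay: str = "", length_conflict: bool = False
) -> MixedSequence:
    """Positionwise set-union of unambiguous sequences as IUPAC codes.

    Commutative and idempotent.  Unequal lengths raise
    :class:`LengthConflictError`; the caller decides whether to flag a
    truncated superposition instead (see the synthetic assay simulator).
    """
    if not sequences:
        raise ValueError("at least one sequence required")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise LengthConflictError(
            f"unequal sequence lengths {sorted(lengths)} in superposition"
        )
    codes = []
    for column in zip(*[s.upper() for s in sequences]):
        bases = frozenset(column)
        if not bases <= frozenset("ACGT"):
            raise ValueError(f"unexpected bases {sorted(bases - frozenset('ACGT'))}")
        codes.append(BASES_TO_CODE[bases])
    return MixedSequence("".join(codes), assay=assay, length_conflict=length_conflict)


def _as_sequence(allele: Union[str, Allele]) -> str:
    return allele.sequence if isinstance(allele, Allele) else allele


def is_compatible(
    allele: Union[str, Allele],
    observed: MixedSequence,
    treat_n_as_missing: bool = False,
) -> bool:
    """True iff the allele's base is within the observed code set everywhere.

    With ``treat_n_as_missing`` (a dialect knob for caller-supplied data in
    which 'N' denotes a no-call rather than a genuine four-peak position),
    'N' positions are excluded from the check.
    """
    seq = _as_sequence(allele).upper()
    if len(seq) != len(observed):
        raise ValueError(
            f"length mismatch: allele {len(seq)} vs observation {len(observed)}"
        )
    for base, code in zip(seq, observed.codes):
        if treat_n_as_missing and code == "N":
            continue
        if base not in CODE_TO_BASES[code]:
            return False
    return True


# ---------------------------------------------------------------------------
# Minimal-subset explanation search
# ---------------------------------------------------------------------------

MAX_CANDIDATES = 64


def explain_mixture(
    observed: MixedSequence,
    candidates: Mapping[str, str],
    kmax: int = 4,
    treat_n_as_missing: bool = False,
) -> list[frozenset[str]]:
    """All cardinality-minimal candidate subsets whose union is the observation.

    ``candidates`` maps a candidate key to its (region) sequence.  The
    search is exhaustive over compatible candidates up to size ``kmax`` and
    stops at the first cardinality with at least one exact explanation.
    Equality is exact positionwise code equality: a union that merely
    refines the observed codes does not explain them, and an observed 'N'
    must be produced by all four bases.  ``treat_n_as_missing`` switches to
    a dialect in which 'N' marks a no-call position excluded from both the
    compatibility and the equality check.
    """
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    keep = [
        i for i, c in enumerate(observed.codes)
        if not (treat_n_as_missing and c == "N")
    ]
    obs_sets = [CODE_TO_BASES[observed.codes[i]] for i in keep]
    usable = {
        key: seq.upper()
        for key, seq in candidates.items()
        if len(seq) == len(observed)
        and is_compatible(seq, observed, treat_n_as_missing)
    }
    if len(usable) > MAX_CANDIDATES:
        raise ValueError(
            f"{len(usable)} compatible candidates exceeds the enumeration cap "
            f"({MAX_CANDIDATES}); filter candidates by locus/assay first"
        )
    keys = sorted(usable)
    seqs = {k: [usable[k][i] for i in keep] for k in keys}
    for size in range(1, kmax + 1):
        found = []
        for combo in itertools.combinations(keys, size):
            ok = True
            for pos, target in enumerate(obs_sets):
                if frozenset(seqs[k][pos] for k in combo) != target:
                    ok = False
                    break
            if ok:
                found.append(frozenset(combo))
        if found:
            return found
    return []


def group_candidates_by_region(
    alleles: Iterable[Allele],
    region_of: Optional[Mapping[str, str]] = None,
) -> dict[Entry, str]:
    """Collapse alleles identical over the assayed region into entries.

    Returns entry (sorted name tuple) -> shared region sequence.
    ``region_of`` optionally maps allele name -> region sequence (defaults
    to the full stored sequence).
    """
    by_seq: dict[str, list[str]] = {}
    for a in alleles:
        seq = (region_of or {}).get(a.name, a.sequence)
        by_seq.setdefault(seq, []).append(a.name)
    return {tuple(sorted(names)): seq for seq, names in by_seq.items()}


def call_genotype(
    observed: Observation,
    db: AlleleDatabase,
    assay,
    kmax: int = 4,
    treat_n_as_missing: bool = False,
) -> GenotypeCall:
    """Deconvolve one observation into a status and explaining allele sets.

    ``assay`` is an :class:`~mhchap.synth.AssayProfile` (or anything with
    ``name``, ``amplifies``, ``extra_alleles`` and a ``region_sequence``
    method) used to select and trim the candidate alleles.
    """
    name = getattr(assay, "name", str(assay))
    if observed is NO_PRODUCT:
        return GenotypeCall(status="no_product", assay=name)
    assert isinstance(observed, MixedSequence)
    if observed.length_conflict:
        # Mirrors the length-polymorphic mixture case: a 1-bp indel shifts
        # the frames of the superposed alleles and no positionwise
        # explanation exists; callers re-assay with different primers.
        return GenotypeCall(status="uncallable_frameshift", assay=name)

    candidates: list[Allele] = []
    for locus in sorted(assay.amplifies):
        candidates.extend(db.by_locus(locus))
    for extra in sorted(getattr(assay, "extra_alleles", ()) or ()):
        if extra in db and db[extra] not in candidates:
            candidates.append(db[extra])
    region_of = {a.name: assay.region_sequence(a.sequence) for a in candidates}
    groups = group_candidates_by_region(candidates, region_of)
    group_seqs = {entry: seq for entry, seq in groups.items() if len(seq) == len(observed)}
    explanations = explain_mixture(
        observed, {"/".join(e): s for e, s in group_seqs.items()}, kmax=kmax,
        treat_n_as_missing=treat_n_as_missing,
    )
    key_to_entry = {"/".join(e): e for e in group_seqs}
    exp_entries = tuple(
        frozenset(key_to_entry[k] for k in exp)
        for exp in sorted(explanations, key=lambda e: sorted(e))
    )
    if not exp_entries:
        return GenotypeCall(status="novel_suspected", assay=name)
    if len(exp_entries) == 1:
        return GenotypeCall(status="called", explanations=exp_entries, assay=name)
    return GenotypeCall(status="ambiguous", explanations=exp_entries, assay=name)


# ---------------------------------------------------------------------------
# Observation I/O (FASTA of IUPAC consensus sequences, header
# "individual|assay"; absence of a record for an individual x assay pair
# encodes the absence of a PCR product) and call tables.
# ---------------------------------------------------------------------------

def write_observations(
    observations: Mapping[str, Mapping[str, Observation]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for ind in sorted(observations):
            for assay in sorted(observations[ind]):
                obs = observations[ind][assay]
                if obs is NO_PRODUCT:
                    continue
                flag = "|length_conflict" if obs.length_conflict else ""
                fh.write(f">{ind}|{assay}{flag}\n{obs.codes}\n")


def read_observations(
    path: str | Path, individuals: Iterable[str], assays: Iterable[str]
) -> dict[str, dict[str, Observation]]:
    table: dict[str, dict[str, Observation]] = {
        ind: {a: NO_PRODUCT for a in assays} for ind in individuals
    }
    with open(path) as fh:
        header = None
        chunks: list[str] = []

        def flush():
            if header is None:
                return
            parts = header.split("|")
            ind, assay = parts[0], parts[1]
            conflict = "length_conflict" in parts[2:]
            table.setdefault(ind, {})[assay] = MixedSequence(
                "".join(chunks).upper(), assay=assay, length_conflict=conflict
            )

        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                chunks = []
            else:
                chunks.append(line)
        flush()
    return table


def format_call(call: GenotypeCall) -> str:
    if call.status in ("no_product", "uncallable_frameshift", "novel_suspected"):
        return call.status
    parts = []
    for exp in call.explanations:
        parts.append("+".join("/".join(entry) for entry in sorted(exp)))
    return call.status + ":" + ";".join(parts)


def write_calls(
    calls: Mapping[str, Mapping[str, GenotypeCall]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tassay\tstatus\texplanation\n")
        for ind in sorted(calls):
            for assay in sorted(calls[ind]):
                call = calls[ind][assay]
                detail = format_call(call).split(":", 1)
                fh.write(
                    f"{ind}\t{assay}\t{call.status}\t"
                    f"{detail[1] if len(detail) > 1 else '-'}\n"
                )
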