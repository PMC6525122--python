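"""Allele databases, nomenclature and multi-locus haplotype panels.

The central objects of the genotyping workflow: a database of named,
locus-labelled allele sequences (the in-package analogue of a curated
reference such as IPD-MHC), and a haplotype panel mapping haplotype labels
to the ordered allele content of each locus.  Matching against the database
is ungapped best-offset identity, reflecting that amplicon consensus reads
and reference alleles are co-linear in this application.

Loci follow the ruminant MHC class IIa layout: *DRB1* plus the duplicated
*DQA1/DQA2/DQA2-like* and *DQB1/DQB2/DQB2-like* genes.  A haplotype may
lack a locus entirely (a "null" locus, e.g. *DQA1* on some haplotypes),
which locus-specific primers report as the absence of any PCR product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

LOCI = ("DRB1", "DQA1", "DQA2", "DQA2-like", "DQB1", "DQB2", "DQB2-like")
VALID_LOCI = frozenset(LOCI) | {"unassigned"}

STATUSES = frozenset(
    {"official", "temporary_accession", "temporary_haplotype", "novel_unnamed"}
)

_DNA = frozenset("ACGT")

#: Alignment-relative coordinate metadata: offset (bases from the
#: translation start codon) at which exon 2 begins for each gene family.
#: Stored as metadata only; sequence coordinates in this package are
#: 1-based within the stored amplicon and never silently shifted.
EXON2_GENOMIC_OFFSETS = {"DQA": 83, "DQB": 110}


@dataclass(frozen=True)
class Allele:
    """A named, locus-labelled nucleotide sequence.

    ``full_length`` distinguishes complete transcripts from exon-2-only
    fragments (which cannot receive official nomenclature).
    """

    name: str
    locus: str
    sequence: str
    accession: Optional[str] = None
    status: str = "official"
    full_length: bool = True

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("allele name must be non-empty")
        if self.locus not in VALID_LOCI:
            raise ValueError(
                f"invalid locus {self.locus!r} for allele {self.name!r}; "
                f"expected one of {sorted(VALID_LOCI)}"
            )
        if self.status not in STATUSES:
            raise ValueError(f"invalid status {self.status!r} for allele {self.name!r}")
        if not self.sequence:
            raise ValueError(f"allele {self.name!r} has an empty sequence")
        bad = set(self.sequence) - _DNA
        if bad:
            raise ValueError(
                f"allele {self.name!r} contains ambiguity/invalid characters "
                f"{sorted(bad)}; database sequences must be unambiguous A/C/G/T"
            )
        if self.status == "official" and "*" in self.name:
            prefix = self.name.split("*", 1)[0]
            if prefix != self.locus:
                raise ValueError(
                    f"official allele name {self.name!r} has locus prefix "
                    f"{prefix!r} inconsistent with locus field {self.locus!r}"
                )


class AlleleDatabase:
    """Mapping of allele name -> :class:`Allele` with a per-locus index."""

    def __init__(self, alleles: Iterable[Allele] = ()) -> None:
        self.alleles: dict[str, Allele] = {}
        self._by_sequence: dict[str, str] = {}
        for a in alleles:
            self.add(a)

    def add(self, allele: Allele) -> None:
        if allele.name in self.alleles:
            raise ValueError(f"duplicate allele name {allele.name!r}")
        self.alleles[allele.name] = allele
        self._by_sequence.setdefault(allele.sequence, allele.name)

    def __len__(self) -> int:
        return len(self.alleles)

    def __contains__(self, name: str) -> bool:
        return name in self.alleles

    def __getitem__(self, name: str) -> Allele:
        return self.alleles[name]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AlleleDatabase) and self.alleles == other.alleles

    @property
    def locus_index(self) -> dict[str, frozenset[str]]:
        """Locus -> set of allele names, rebuilt deterministically."""
        index: dict[str, set[str]] = {}
        for a in self.alleles.values():
            index.setdefault(a.locus, set()).add(a.name)
        return {locus: frozenset(names) for locus, names in sorted(index.items())}

    def by_locus(self, locus: str) -> list[Allele]:
        return [a for a in sorted(self.alleles.values(), key=lambda a: a.name)
                if a.locus == locus]

    def name_of_sequence(self, sequence: str) -> Optional[str]:
        return self._by_sequence.get(sequence)


# ---------------------------------------------------------------------------
# FASTA round-trip.  Header dialect: name|locus|status|accession|length-tag
# (pipe-delimited; accession "-" when absent; tag "full" or "partial";
# trailing fields may be omitted on input, defaulting to no accession and
# full-length).
# ---------------------------------------------------------------------------

def write_fasta(db: AlleleDatabase, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(db.alleles):
            a = db[name]
            acc = a.accession if a.accession else "-"
            tag = "full" if a.full_length else "partial"
            fh.write(f">{a.name}|{a.locus}|{a.status}|{acc}|{tag}\n")
            seq = a.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path: str | Path) -> AlleleDatabase:
    db = AlleleDatabase()
    name = None
    fields: list[str] = []
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        parts = fields + [""] * (5 - len(fields))
        locus, status, acc, tag = parts[1], parts[2] or "official", parts[3], parts[4]
        db.add(
            Allele(
                name=name,
                locus=locus,
                sequence="".join(chunks).upper(),
                accession=None if acc in ("", "-") else acc,
                status=status,
                full_length=(tag != "partial"),
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                fields = line[1:].split("|")
                name = fields[0]
                chunks = []
            else:
                chunks.append(line)
    flush()
    return db


# ---------------------------------------------------------------------------
# Haplotype panel
# ---------------------------------------------------------------------------

#: A panel cell is an ordered tuple of *entries*; each entry is a tuple of
#: one or more allele names.  A multi-name entry is an ambiguity group:
#: alleles indistinguishable over the assayed region that occupy a single
#: chromosomal slot (e.g. two alleles identical throughout exon 2).
Entry = tuple[str, ...]


@dataclass
class HaplotypePanel:
    """Haplotype label -> locus -> ordered allele entries (0-2 per locus)."""

    rows: dict[str, dict[str, tuple[Entry, ...]]] = field(default_factory=dict)
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, row in self.rows.items():
            for locus, entries in row.items():
                if locus not in VALID_LOCI:
                    raise ValueError(f"invalid locus {locus!r} in haplotype {label!r}")
                if len(entries) > 2:
                    raise ValueError(
                        f"haplotype {label!r} carries {len(entries)} entries at "
                        f"{locus}; at most 2 allowed"
                    )

    @property
    def labels(self) -> list[str]:
        return list(self.rows)

    def entries_at(self, label: str, locus: str) -> tuple[Entry, ...]:
        return self.rows[label].get(locus, ())

    def allele_names(self, label: Optional[str] = None) -> set[str]:
        labels = [label] if label is not None else self.labels
        out: set[str] = set()
        for lab in labels:
            for entries in self.rows[lab].values():
                for entry in entries:
                    out.update(entry)
        return out

    def content_key(self, label: str) -> tuple:
        """Canonical, label-free representation of one haplotype's content."""
        row = self.rows[label]
        return tuple(
            (locus, tuple(sorted(tuple(sorted(e)) for e in row[locus])))
            for locus in LOCI
            if row.get(locus)
        )

    def content_multiset(self) -> tuple:
        return tuple(sorted(self.content_key(lab) for lab in self.labels))


def _parse_cell(cell: str) -> tuple[Entry, ...]:
    cell = cell.strip()
    if cell in ("-", "", "–"):
        return ()
    entries = []
    for part in cell.split(","):
        entries.append(tuple(n.strip() for n in part.split("/") if n.strip()))
    return tuple(entries)


def format_cell(entries: tuple[Entry, ...]) -> str:
    if not entries:
        return "-"
    return ",".join("/".join(e) for e in entries)


def load_panel(path: str | Path, db: AlleleDatabase) -> HaplotypePanel:
    """Read a tab-separated haplotype panel; dash marks an absent locus."""
    rows: dict[str, dict[str, tuple[Entry, ...]]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        return HaplotypePanel()
    header = lines[0].split("\t")
    if header[0].lower() != "haplotype":
        raise ValueError("panel header must start with 'haplotype'")
    loci = header[1:]
    for locus in loci:
        if locus not in VALID_LOCI:
            raise ValueError(f"invalid locus column {locus!r} in panel header")
    for line in lines[1:]:
        cells = line.split("\t")
        label = cells[0]
        if label in rows:
            raise ValueError(f"duplicate haplotype label {label!r}")
        row: dict[str, tuple[Entry, ...]] = {}
        for locus, cell in zip(loci, cells[1:]):
            entries = _parse_cell(cell)
            for entry in entries:
                for name in entry:
                    if name not in db:
                        raise ValueError(
                            f"haplotype {label!r} references unknown allele {name!r}"
                        )
            if entries:
                row[locus] = entries
        rows[label] = row
    return HaplotypePanel(rows=rows)


def write_panel(panel: HaplotypePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("haplotype\t" + "\t".join(LOCI) + "\n")
        for label in panel.labels:
            cells = [format_cell(panel.entries_at(label, locus)) for locus in LOCI]
            fh.write(label + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Sequence matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hit:
    name: str
    identity: float
    aligned_length: int


def match_sequence(
    query: str,
    db: AlleleDatabase,
    locus_filter: Optional[str] = None,
    min_identity: float = 0.0,
) -> list[Hit]:
    """Rank database alleles by ungapped best-offset identity to ``query``.

    The query must be a contained segment of (or equal in length to) the
    subject; identity is matches / query length at the best offset.  Hits
    are ranked by identity (descending) then name.  Subjects shorter than
    the query are not considered.
    """
    if not query:
        raise ValueError("empty query")
    query = query.upper()
    if set(query) - _DNA:
        raise ValueError("query must be unambiguous A/C/G/T")
    subjects = [
        a for a in db.alleles.values() if locus_filter is None or a.locus == locus_filter
    ]
    if not subjects:
        raise ValueError(
            "no database alleles to match against"
            + (f" at locus {locus_filter!r}" if locus_filter else "")
        )
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    hits = []
    for a in subjects:
        if len(a.sequence) < len(q):
            continue
        s = np.frombuffer(a.sequence.encode(), dtype=np.uint8)
        best = 0
        for off in range(len(s) - len(q) + 1):
            m = int((s[off : off + len(q)] == q).sum())
            if m > best:
                best = m
                if best == len(q):
                    break
        ident = best / len(q)
        if ident >= min_identity:
            hits.append(Hit(a.name, ident, len(q)))
    hits.sort(key=lambda h: (-h.identity, h.name))
    return hits


# ---------------------------------------------------------------------------
# Nomenclature for novel alleles
# ---------------------------------------------------------------------------

def register_novel(
    db: AlleleDatabase,
    sequence: str,
    locus: str,
    haplotype_label: str,
    full_length: bool,
    genbank_match: Optional[str] = None,
) -> Allele:
    """Name and insert a novel allele.

    Naming, in priority order: a full-length transcript gets a placeholder
    official-style name and is flagged for nomenclature submission; a
    fragment matching an archived accession is named locus*accession; any
    other fragment is named locus-haplotype.  The rule is a pure function
    of its inputs.
    """
    existing = db.name_of_sequence(sequence.upper())
    if existing is not None:
        raise ValueError(f"sequence already registered as {existing!r}")
    if full_length:
        allele = Allele(
            name=f"{locus}*new-{haplotype_label}",
            locus=locus,
            sequence=sequence.upper(),
            status="novel_unnamed",
            full_length=True,
        )
    elif genbank_match is not None:
        allele = Allele(
            name=f"{locus}*{genbank_match}",
            locus=locus,
            sequence=sequence.upper(),
            accession=genbank_match,
            status="temporary_accession",
            full_length=False,
        )
    else:
        allele = Allele(
            name=f"{locus}-{haplotype_label}",
            locus=locus,
            sequence=sequence.upper(),
            status="temporary_haplotype",
            full_length=False,
        )
    db.add(allele)
    return allele


# ---------------------------------------------------------------------------
# Amino-acid identity between haplotypes
# ---------------------------------------------------------------------------

def _translate_region(allele: Allele, region) -> str:
    seq = allele.sequence
    if region is not None:
        if hasattr(region, "extract"):  # a synth.Region (supports 3' anchoring)
            seq = region.extract(seq)
        else:
            start, end = region
            if start < 1 or end > len(seq):
                raise ValueError(
                    f"region {region} out of range for allele {allele.name!r} "
                    f"(length {len(seq)})"
                )
            seq = seq[start - 1 : end]
    if len(seq) % 3:
        raise ValueError(
            f"region for allele {allele.name!r} is not in frame (length {len(seq)})"
        )
    aa = str(Seq(seq).translate())
    if "*" in aa:
        pos = aa.index("*") + 1
        raise ValueError(
            f"stop codon inside region for allele {allele.name!r} at codon {pos}"
        )
    return aa


def aa_identity_matrix(
    panel: HaplotypePanel,
    db: AlleleDatabase,
    regions: Optional[Mapping[str, tuple[int, int]]] = None,
) -> tuple[list[str], np.ndarray]:
    """Pairwise amino-acid identity between haplotypes.

    Each haplotype is represented by the translated alleles at its loci
    (first allele of each entry); identity between two haplotypes is
    computed only over loci present in both, position by position over the
    concatenated translations.  ``regions`` maps locus -> 1-based inclusive
    in-frame coding interval within the stored sequence.
    """
    regions = dict(regions or {})
    labels = panel.labels
    translations: dict[str, dict[str, str]] = {}
    for label in labels:
        per_locus: dict[str, str] = {}
        for locus in LOCI:
            entries = panel.entries_at(label, locus)
            if not entries:
                continue
            parts = [
                _translate_region(db[entry[0]], regions.get(locus))
                for entry in entries
            ]
            per_locus[locus] = "".join(parts)
        translations[label] = per_locus
    n = len(labels)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = translations[labels[i]], translations[labels[j]]
            shared = [loc for loc in LOCI if loc in a and loc in b]
            total = matches = 0
            for loc in shared:
                pa, pb = a[loc], b[loc]
                m = min(len(pa), len(pb))
                total += m
                matches += sum(x == y for x, y in zip(pa[:m], pb[:m]))
            ident = matches / total if total else float("nan")
            mat[i, j] = mat[j, i] = ident
    return labels, mat
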