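"""Packaged eight-haplotype MHC class IIa panel with synthetic sequences.

The haplotype structure (labels A-H, allele names, locus content, null
loci, shared alleles, the exon-2 ambiguity group and the three-DQB
haplotype) transcribes the published Soay sheep panel.  The nucleotide
sequences are synthetic stand-ins generated deterministically from a fixed
seed: the real exon-2 alignments are not machine-readable, so the fixture
preserves the combinatorial structure of the panel (lengths, allele
sharing, within- and between-locus divergence, the 1-bp length
polymorphism in DRB1*13:01, full-length vs exon-2-only fragments) rather
than the real base calls.

Notes kept from the source material:

* DQA1*Z28420's archived reference lacks the final 12 bp of exon 2; the
  stand-in is a full-length exon so that the DQA1 assay is not spuriously
  flagged as length-conflicted (the real amplicon is full length).
* Seven DQA alleles are non-matching against prior full-length references
  (six with new archive accessions plus Z28420), although the source text
  counts six; the discrepancy is preserved, not resolved.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from importlib import resources

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .alleledb import Allele, AlleleDatabase, HaplotypePanel, load_panel
from .synth import AssayProfile, Region

FIXTURE_SEED = 20718

_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS
)

#: In-frame coding region of each locus's stored amplicon (for translation
#: and selection analyses).  DRB1 amplicons carry a short non-coding 5'
#: leader, so the exon is anchored at the 3' end; DQB full-length
#: sequences carry a 3' UTR tag after the exon.
CODING_REGIONS = {
    "DRB1": Region(1, 240, anchor="3p"),
    "DQA1": Region(1, 249),
    "DQA2": Region(1, 249),
    "DQA2-like": Region(1, 249),
    "DQB1": Region(1, 234),
    "DQB2": Region(1, 234),
    "DQB2-like": Region(1, 234),
}

_DRB1_LEADER_LEN = 6
_DQB_UTR_LEN = 30


def _random_exon(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(rng.choice(SENSE_CODONS, size=n_codons))


def _mutate_exon(rng: np.random.Generator, exon: str, n_subs: int) -> str:
    """Exactly n_subs substitutions at distinct positions, never creating a stop."""
    seq = list(exon)
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    for pos in positions:
        codon_start = (pos // 3) * 3
        choices = [b for b in "ACGT" if b != seq[pos]]
        rng.shuffle(choices)
        for base in choices:
            codon = seq[codon_start:codon_start + 3]
            codon[pos - codon_start] = base
            if "".join(codon) not in STOP_CODONS:
                seq[pos] = base
                break
    return "".join(seq)


def _mutate_utr(rng: np.random.Generator, utr: str, n_subs: int) -> str:
    seq = list(utr)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        seq[pos] = [b for b in "ACGT" if b != seq[pos]][rng.integers(3)]
    return "".join(seq)


# (name, accession, status, full_length); substitution counts from the
# locus ancestor are drawn deterministically in declaration order.
_DRB1_ALLELES = [
    ("DRB1*01:01", None, "official"),
    ("DRB1*01:02", None, "official"),
    ("DRB1*03:02", None, "official"),
    ("DRB1*10:01", None, "official"),
    ("DRB1*13:01", None, "official"),
    ("DRB1*22:01", None, "official"),
]

_DQA_ALLELES = {
    "DQA1": [
        ("DQA1*03:01:01", None, "official", True),
        ("DQA1*Z28420", "Z28420", "temporary_accession", False),
        ("DQA1*03:02:01", "LR025209", "official", True),
        ("DQA1*04:02:01", "LR025208", "official", True),
    ],
    "DQA2": [
        ("DQA2*01:01:01", None, "official", True),
        ("DQA2*01:02:01", None, "official", True),
        ("DQA2*02:01:01", None, "official", True),
        ("DQA2*04:02:01", "LR025212", "official", True),
        ("DQA2*07:01:01", None, "official", True),
        ("DQA2*09:01:02", "LR025211", "official", True),
        ("DQA2*10:01:01", "LR025213", "official", True),
    ],
    "DQA2-like": [
        ("DQA2-like*01:01:01", None, "official", True),
        ("DQA2-like*03:01:01", "LR025210", "official", True),
    ],
}

_DQB_ALLELES = {
    "DQB1": [
        ("DQB1*02:01:01", None, "official", True),
        ("DQB1*07:01:01", None, "official", True),
        ("DQB1*07:02:01", None, "official", True),
        ("DQB1*LN868258", "LN868258", "temporary_accession", False),
        ("DQB1*AJ23941", "AJ23941", "temporary_accession", False),
        ("DQB1-H", "LR025788", "temporary_haplotype", False),
    ],
    "DQB2": [
        ("DQB2*04:01:01", None, "official", True),
        ("DQB2*09:01:01", "LR025203", "official", True),
        ("DQB2*10:01:01", "LR025204", "official", True),
        ("DQB2*11:01:01", "LR025206", "official", True),
        ("DQB2*12:01:01", "LR025205", "official", True),
        ("DQB2*AJ238945", "AJ238945", "temporary_accession", False),
        ("DQB2-D", "LR025789", "temporary_haplotype", False),
        ("DQB2-F", "LR025790", "temporary_haplotype", False),
    ],
    "DQB2-like": [
        ("DQB2-like*01:01:01", None, "official", True),
        ("DQB2-like*03:01:01", "LR025207", "official", True),
    ],
}

_LOCUS_DIVERGENCE = 24   # substitutions separating locus ancestors (~10%)
_ALLELE_SUB_RANGE = (2, 8)  # within-locus allele divergence


@lru_cache(maxsize=1)
def fixture_database() -> AlleleDatabase:
    """Deterministically generated allele database for the packaged panel."""
    rng = np.random.default_rng(FIXTURE_SEED)
    db = AlleleDatabase()

    # DRB1: 6-nt non-coding leader + 80-codon exon.  DRB1*13:01 carries a
    # 1-bp deletion in the leader, so its amplicon is one base shorter;
    # a 3'-anchored assay region (primer downstream of the deletion)
    # recovers an equal-length exon for every allele.
    leader = "".join(rng.choice(list("ACGT"), size=_DRB1_LEADER_LEN))
    drb1_anc = _random_exon(rng, 80)
    seen: set[str] = set()
    for name, acc, status in _DRB1_ALLELES:
        while True:
            n_subs = int(rng.integers(*_ALLELE_SUB_RANGE, endpoint=True))
            exon = _mutate_exon(rng, drb1_anc, n_subs)
            if exon not in seen:
                seen.add(exon)
                break
        lead = leader[1:] if name == "DRB1*13:01" else leader
        db.add(Allele(name, "DRB1", lead + exon, accession=acc, status=status))

    # DQA family: three locus ancestors diverged from a common root.
    dqa_root = _random_exon(rng, 83)
    for locus in ("DQA1", "DQA2", "DQA2-like"):
        locus_anc = _mutate_exon(rng, dqa_root, _LOCUS_DIVERGENCE)
        seen = set()
        for name, acc, status, full in _DQA_ALLELES[locus]:
            while True:
                n_subs = int(rng.integers(*_ALLELE_SUB_RANGE, endpoint=True))
                exon = _mutate_exon(rng, locus_anc, n_subs)
                if exon not in seen:
                    seen.add(exon)
                    break
            db.add(Allele(name, locus, exon, accession=acc, status=status,
                          full_length=full))

    # DQB family: exon (78 codons) plus a locus-specific 3' UTR tag on
    # full-length alleles; exon-2-only fragments lack the UTR, which is
    # where the locus-level phylogenetic signal is strongest.
    dqb_root = _random_exon(rng, 78)
    for locus in ("DQB1", "DQB2", "DQB2-like"):
        locus_anc = _mutate_exon(rng, dqb_root, _LOCUS_DIVERGENCE)
        locus_utr = "".join(rng.choice(list("ACGT"), size=_DQB_UTR_LEN))
        seen = set()
        shared_0701_exon = None
        for name, acc, status, full in _DQB_ALLELES[locus]:
            if name == "DQB1*07:02:01":
                # identical throughout exon 2 to DQB1*07:01:01; the two
                # are separable only via longer transcripts (UTR here)
                exon = shared_0701_exon
                utr = _mutate_utr(rng, locus_utr, 3)
            else:
                while True:
                    n_subs = int(rng.integers(*_ALLELE_SUB_RANGE, endpoint=True))
                    exon = _mutate_exon(rng, locus_anc, n_subs)
                    if exon not in seen:
                        seen.add(exon)
                        break
                utr = _mutate_utr(rng, locus_utr, int(rng.integers(0, 3)))
                if name == "DQB1*07:01:01":
                    shared_0701_exon = exon
            seq = exon + utr if full else exon
            db.add(Allele(name, locus, seq, accession=acc, status=status,
                          full_length=full))
    return db


def fixture_panel(db: AlleleDatabase | None = None) -> HaplotypePanel:
    """The packaged eight-haplotype panel, validated against the database."""
    if db is None:
        db = fixture_database()
    with resources.as_file(
        resources.files("mhchap.data").joinpath("soay_panel.tsv")
    ) as path:
        panel = load_panel(path, db)
    panel.provenance[("D", "DQB1")] = (
        "exon-2-only amplification; group members identical throughout exon 2"
    )
    panel.provenance[("C", "DQB1")] = "locus designated by amplifying primer set"
    panel.provenance[("C", "DQB2")] = "locus designated by amplifying primer set"
    panel.provenance[("F", "DQB1")] = "locus designated by phylogenetic analysis"
    panel.provenance[("F", "DQB2")] = "locus designated by phylogenetic analysis"
    panel.provenance[("G", "DQB2")] = "one allele from gDNA only, one from cDNA only"
    return panel


@lru_cache(maxsize=1)
def fixture_assays() -> dict[str, AssayProfile]:
    """Assay profiles mirroring the genotyping design.

    DQA1 primers are locus-specific (null haplotypes give no product); the
    DQA2 pair co-amplifies DQA2 and DQA2-like; DQB primers cross-amplify
    depending on the alleles present; cDNA assays suffer allele-specific
    dropout.  The full-exon DRB1 assay exposes the 1-bp-deletion length
    conflict that the 3'-anchored alternative avoids.
    """
    exon_dqa = None  # whole stored sequence
    exon_dqb = Region(1, 234)
    assays = [
        AssayProfile("DRB1_455", "gDNA", frozenset({"DRB1"}),
                     region=Region(1, 240, anchor="3p")),
        AssayProfile("DRB1_full", "gDNA", frozenset({"DRB1"}), region=None),
        AssayProfile("DQA1", "gDNA", frozenset({"DQA1"}), region=exon_dqa),
        AssayProfile("DQA2", "gDNA", frozenset({"DQA2", "DQA2-like"}),
                     region=exon_dqa),
        AssayProfile("DQB1", "gDNA", frozenset({"DQB1"}), region=exon_dqb,
                     extra_alleles=frozenset({"DQB2*04:01:01"})),
        AssayProfile("DQB2", "gDNA", frozenset({"DQB2", "DQB2-like"}),
                     region=exon_dqb),
        AssayProfile("DQA_cdna_244", "cDNA", frozenset({"DQA1", "DQA2"}),
                     region=exon_dqa),
        AssayProfile("DQA_cdna_348", "cDNA",
                     frozenset({"DQA1", "DQA2", "DQA2-like"}), region=exon_dqa),
        AssayProfile("DQB_cdna", "cDNA", frozenset({"DQB1", "DQB2"}),
                     region=exon_dqb,
                     allele_dropout=frozenset({"DQB2*09:01:01"})),
        AssayProfile("DQB2like_cdna", "cDNA", frozenset({"DQB2-like"}),
                     region=exon_dqb,
                     allele_dropout=frozenset({"DQB2-like*01:01:01",
                                               "DQB2-like*03:01:01"})),
    ]
    return {a.name: a for a in assays}


#: The assay set used for routine genotyping and haplotype inference.
DEFAULT_GENOTYPING_ASSAYS = ("DRB1_455", "DQA1", "DQA2", "DQB1", "DQB2")


def default_genotyping_assays() -> list[AssayProfile]:
    assays = fixture_assays()
    return [assays[name] for name in DEFAULT_GENOTYPING_ASSAYS]


def locus_alignment(db: AlleleDatabase, loci: tuple[str, ...],
                    include_utr: bool = True) -> dict[str, str]:
    """Gap-padded alignment of all alleles at the given loci.

    Stand-in sequences are generated without indels, so columns align
    positionwise; exon-2-only fragments are padded with gaps over the UTR
    columns (pairwise deletion applies downstream).
    """
    names = [a.name for locus in loci for a in db.by_locus(locus)]
    seqs = {}
    width = 0
    for name in names:
        a = db[name]
        seq = a.sequence
        if not include_utr:
            region = CODING_REGIONS[a.locus]
            seq = region.extract(seq)
        seqs[name] = seq
        width = max(width, len(seq))
    return {n: s + "-" * (width - len(s)) for n, s in seqs.items()}


def dqb_alignment(db: AlleleDatabase | None = None) -> dict[str, str]:
    """Exon-2 + UTR alignment of every DQB allele (phylogeny input)."""
    if db is None:
        db = fixture_database()
    return locus_alignment(db, ("DQB1", "DQB2", "DQB2-like"))


def coding_alignment(db: AlleleDatabase | None = None,
                     group: str = "DQB") -> dict[str, str]:
    """In-frame coding alignment per gene family (selection-analysis input)."""
    if db is None:
        db = fixture_database()
    loci = {
        "DRB1": ("DRB1",),
        "DQA": ("DQA1", "DQA2", "DQA2-like"),
        "DQB": ("DQB1", "DQB2", "DQB2-like"),
        "DQA1": ("DQA1",), "DQA2": ("DQA2",),
        "DQB1": ("DQB1",), "DQB2": ("DQB2",),
    }[group]
    return locus_alignment(db, loci, include_utr=False)
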