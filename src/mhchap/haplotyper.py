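"""Homozygote-anchored haplotype inference across linked MHC loci.

The inference strategy exploits linkage: individuals homozygous at an
anchor locus (DRB1 by default) carry two copies of the same anchor allele,
so every allele observed at a downstream locus in an *anchor-homozygous,
downstream-homozygous* individual belongs to the haplotype bearing that
anchor allele.  Three complications are handled:

* **Anchor-allele splitting.**  One anchor allele can sit on several
  haplotypes.  Anchored individuals then partition into internally
  consistent groups (the downstream profiles of pure homozygotes are
  componentwise-minimal among observed profiles), and anchor-homozygous
  but downstream-heterozygous individuals are unions of two such groups.
* **Rare alleles.**  An anchor allele with no homozygotes is recovered by
  heterozygote subtraction: in an individual carrying the rare allele with
  a fully known partner haplotype, removing the partner's expected alleles
  from each assay's call leaves the rare haplotype's alleles.  An allele
  shared between the rare haplotype and the partner is invisible to this
  rule (set semantics), a documented limitation of subtraction.
* **Null loci.**  The absence of a product from locus-specific primers is
  itself informative and must be reproduced by any candidate haplotype
  pair during validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .alleledb import LOCI, AlleleDatabase, Entry, HaplotypePanel
from .deconvolve import GenotypeCall
from .synth import AssayProfile

#: individual id -> assay name -> GenotypeCall
GenotypeTable = Mapping[str, Mapping[str, GenotypeCall]]

#: a haplotype's content: locus -> ordered entries
Contents = dict[str, tuple[Entry, ...]]


@dataclass
class InferredHaplotype:
    contents: Contents
    support: int
    provenance: str  # homozygote_anchored | heterozygote_subtraction
    low_confidence: bool = False
    #: set when the haplotype came from residue completion: the covering
    #: haplotype whose shared alleles are unrecoverable by subtraction and
    #: may need to be restored during validation-driven refinement
    residue_parent: Optional[Contents] = None

    def content_key(self) -> tuple:
        return tuple(
            (locus, tuple(sorted(tuple(sorted(e)) for e in self.contents[locus])))
            for locus in LOCI
            if self.contents.get(locus)
        )


@dataclass
class InferredHaplotypeSet:
    haplotypes: dict[str, InferredHaplotype] = field(default_factory=dict)
    deferred_anchors: list[Entry] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_panel(self) -> HaplotypePanel:
        rows = {
            label: {loc: ents for loc, ents in hap.contents.items() if ents}
            for label, hap in self.haplotypes.items()
        }
        return HaplotypePanel(rows=rows)

    def content_multiset(self) -> tuple:
        return tuple(sorted(h.content_key() for h in self.haplotypes.values()))


class SubtractionConflictError(ValueError):
    """Residues from different informative individuals disagree."""


# ---------------------------------------------------------------------------
# Expected observations from known haplotype content (shared by extension,
# subtraction and validation; mirrors the assay simulator but operates on
# inferred locus contents instead of panel rows).
# ---------------------------------------------------------------------------

def _entry_names(entries: Iterable[Entry]) -> set[str]:
    return {name for entry in entries for name in entry}


def expected_entry_set(
    contents_list: Sequence[Contents],
    assay: AssayProfile,
    db: AlleleDatabase,
    dropout_enabled: bool = True,
) -> frozenset[Entry]:
    """Entries expected in the assay product of the union of haplotypes.

    Returns the empty frozenset when no allele amplifies (no product).
    Entries sharing an identical region sequence are merged into one
    ambiguity group, matching how calls are reported.
    """
    names: set[str] = set()
    for contents in contents_list:
        for locus, entries in contents.items():
            for entry in entries:
                for name in entry:
                    amplified = (
                        locus in assay.amplifies or name in assay.extra_alleles
                    )
                    if not amplified:
                        continue
                    if dropout_enabled and name in assay.allele_dropout:
                        continue
                    names.add(name)
    by_region: dict[str, list[str]] = {}
    for name in names:
        by_region.setdefault(assay.region_sequence(db[name].sequence), []).append(name)
    return frozenset(tuple(sorted(ns)) for ns in by_region.values())


def _call_entry_sets(call: GenotypeCall) -> list[frozenset[Entry]]:
    if call.status == "no_product":
        return [frozenset()]
    if call.status in ("called", "ambiguous"):
        return list(call.explanations)
    return []


# ---------------------------------------------------------------------------
# Anchoring
# ---------------------------------------------------------------------------

def find_anchor_homozygotes(
    table: GenotypeTable, anchor_assay: str
) -> dict[Entry, list[str]]:
    """Anchor entry -> ids of individuals called homozygous for it.

    An individual is anchor-homozygous when its anchor call is ``called``
    with a single-entry explanation (one allele, or one ambiguity group).
    """
    anchors: dict[Entry, list[str]] = {}
    for ind in sorted(table):
        call = table[ind].get(anchor_assay)
        if call is None:
            raise ValueError(f"individual {ind!r} lacks anchor assay {anchor_assay!r}")
        if call.status != "called":
            continue
        entries = call.entry_set
        if entries is not None and len(entries) == 1:
            (entry,) = entries
            anchors.setdefault(entry, []).append(ind)
    return anchors


def observed_anchor_entries(table: GenotypeTable, anchor_assay: str) -> set[Entry]:
    out: set[Entry] = set()
    for ind in table:
        call = table[ind][anchor_assay]
        for exp in _call_entry_sets(call):
            out.update(exp)
    return out


# ---------------------------------------------------------------------------
# Extension within anchored individuals
# ---------------------------------------------------------------------------

def _entries_to_contents(entries: Iterable[Entry], db: AlleleDatabase) -> Contents:
    contents: dict[str, list[Entry]] = {}
    for entry in sorted(entries):
        locus = db[entry[0]].locus
        contents.setdefault(locus, []).append(entry)
    return {loc: tuple(ents) for loc, ents in contents.items()}


def _merge_contents(base: Contents, extra: Contents) -> Contents:
    merged: dict[str, list[Entry]] = {loc: list(ents) for loc, ents in base.items()}
    for loc, ents in extra.items():
        cur = merged.setdefault(loc, [])
        for e in ents:
            if e not in cur:
                cur.append(e)
    return {loc: tuple(sorted(ents)) for loc, ents in merged.items()}


Profile = tuple[tuple[str, frozenset[Entry]], ...]  # assay -> entry set, sorted


def _profile_subset(a: Profile, b: Profile) -> bool:
    da, db_ = dict(a), dict(b)
    return all(da[k] <= db_[k] for k in da)


def _profile_union(a: Profile, b: Profile) -> Profile:
    da, db_ = dict(a), dict(b)
    return tuple(sorted((k, da[k] | db_[k]) for k in da))


def extend_haplotypes(
    anchor_entry: Entry,
    anchored_ids: Sequence[str],
    table: GenotypeTable,
    assays: Sequence[AssayProfile],
    db: AlleleDatabase,
    anchor_assay: str,
    min_support: int = 4,
) -> tuple[list[InferredHaplotype], list[str]]:
    """Extend one anchor allele across downstream assays.

    Individuals with identical downstream profiles are grouped; the
    componentwise-minimal profiles are the pure (single-haplotype)
    signatures, and composite profiles must be unions of two of them.  A
    composite explained by exactly one minimal profile contributes the
    componentwise residue as an additional haplotype (flagged).  Fewer
    than ``min_support`` anchored individuals does not suppress the
    extension; it flags every resulting haplotype low-confidence.
    """
    if not anchored_ids:
        raise ValueError("extension requires at least one anchored individual")
    warnings: list[str] = []
    downstream = [a for a in assays if a.name != anchor_assay]
    profiles: dict[Profile, list[str]] = {}
    for ind in anchored_ids:
        prof: list[tuple[str, frozenset[Entry]]] = []
        usable = True
        for assay in downstream:
            call = table[ind][assay.name]
            sets = _call_entry_sets(call)
            if call.status in ("called", "no_product"):
                prof.append((assay.name, sets[0]))
            else:
                usable = False
                warnings.append(
                    f"{ind}: {assay.name} call is {call.status}; excluded from "
                    f"extension of {'/'.join(anchor_entry)}"
                )
                break
        if usable:
            profiles.setdefault(tuple(sorted(prof)), []).append(ind)
    if not profiles:
        raise ValueError(
            f"no usable anchored individuals for {'/'.join(anchor_entry)}"
        )

    distinct = list(profiles)
    minimal = [
        p for p in distinct
        if not any(q != p and _profile_subset(q, p) for q in distinct)
    ]
    low_confidence = len(anchored_ids) < min_support
    anchor_contents = _entries_to_contents([anchor_entry], db)

    haplotypes: list[InferredHaplotype] = []
    for prof in sorted(minimal):
        entries = {e for _, entry_set in prof for e in entry_set}
        contents = _merge_contents(anchor_contents, _entries_to_contents(entries, db))
        haplotypes.append(
            InferredHaplotype(
                contents=contents,
                support=len(profiles[prof]),
                provenance="homozygote_anchored",
                low_confidence=low_confidence,
            )
        )

    # composite profiles: anchor-homozygous individuals carrying two
    # haplotypes that share the anchor allele
    for prof in sorted(set(distinct) - set(minimal)):
        explained = any(
            _profile_union(p, q) == prof
            for i, p in enumerate(minimal)
            for q in minimal[i:]
        )
        if explained:
            continue
        covering = [p for p in minimal if _profile_subset(p, prof)]
        if len(covering) == 1:
            base = dict(covering[0])
            residue_entries = {
                e
                for assay_name, entry_set in prof
                for e in entry_set - base[assay_name]
            }
            contents = _merge_contents(
                anchor_contents, _entries_to_contents(residue_entries, db)
            )
            haplotypes.append(
                InferredHaplotype(
                    contents=contents,
                    support=len(profiles[prof]),
                    provenance="homozygote_anchored",
                    low_confidence=True,
                    residue_parent=dict(
                        _entries_to_contents(
                            {e for _, es in covering[0] for e in es}, db
                        )
                    ),
                )
            )
            warnings.append(
                f"anchor {'/'.join(anchor_entry)}: residue completion used for a "
                f"composite profile ({len(profiles[prof])} individuals); alleles "
                "shared with the covering haplotype cannot be recovered"
            )
        else:
            warnings.append(
                f"anchor {'/'.join(anchor_entry)}: composite profile of "
                f"{profiles[prof]} not explained by inferred haplotypes"
            )
    return haplotypes, warnings


# ---------------------------------------------------------------------------
# Heterozygote subtraction for rare anchor alleles
# ---------------------------------------------------------------------------

def subtract_heterozygotes(
    rare_entry: Entry,
    table: GenotypeTable,
    known: InferredHaplotypeSet,
    assays: Sequence[AssayProfile],
    db: AlleleDatabase,
    anchor_assay: str,
) -> InferredHaplotype:
    """Infer a rare haplotype from heterozygotes with a known partner.

    Usable individuals are heterozygous for the rare anchor allele with the
    partner anchor allele mapping to exactly one fully known haplotype
    (an anchor allele split across several haplotypes makes the partner
    ambiguous and the individual unusable).  An allele shared between the
    rare haplotype and one partner is invisible in that individual's
    residue but recoverable from a different partner background, so the
    rare haplotype is the per-assay *union* of residues; every usable
    individual's observation must then equal that union combined with its
    partner's expected alleles, otherwise the residues genuinely conflict.
    """
    downstream = [a for a in assays if a.name != anchor_assay]
    anchor_locus = db[rare_entry[0]].locus
    by_anchor: dict[Entry, list[str]] = {}
    for label, hap in known.haplotypes.items():
        for e in hap.contents.get(anchor_locus, ()):
            by_anchor.setdefault(e, []).append(label)

    residue_union: dict[str, set[Entry]] = {a.name: set() for a in downstream}
    observed_by_ind: dict[str, dict[str, frozenset[Entry]]] = {}
    partner_sets_by_ind: dict[str, dict[str, frozenset[Entry]]] = {}
    used: list[str] = []
    for ind in sorted(table):
        call = table[ind][anchor_assay]
        if call.status != "called" or call.entry_set is None:
            continue
        entries = call.entry_set
        if rare_entry not in entries:
            continue
        if len(entries) == 1:
            # degenerate case: homozygous for the rare allele; the residue
            # is the individual's own per-assay call
            partners = None
        else:
            partner_entries = [e for e in entries if e != rare_entry]
            if len(partner_entries) != 1:
                continue
            labels = by_anchor.get(partner_entries[0], [])
            if len(labels) != 1:
                continue  # partner ambiguous (split anchor) -> unusable
            partners = known.haplotypes[labels[0]]
        ind_residue: dict[str, frozenset[Entry]] = {}
        ind_partner: dict[str, frozenset[Entry]] = {}
        usable = True
        for assay in downstream:
            obs = table[ind][assay.name]
            sets = _call_entry_sets(obs)
            if obs.status not in ("called", "no_product"):
                usable = False
                break
            observed = sets[0]
            if partners is None:
                partner_set = frozenset()  # rare homozygote: residue is the call
            else:
                partner_set = expected_entry_set([partners.contents], assay, db)
                if not partner_set <= observed:
                    usable = False  # partner's alleles absent: wrong pairing
                    break
            ind_residue[assay.name] = observed - partner_set
            ind_partner[assay.name] = partner_set
        if not usable:
            continue
        used.append(ind)
        observed_by_ind[ind] = {
            a.name: _call_entry_sets(table[ind][a.name])[0] for a in downstream
        }
        partner_sets_by_ind[ind] = ind_partner
        for assay_name, entry_set in ind_residue.items():
            residue_union[assay_name] |= entry_set
    if not used:
        raise ValueError(
            f"no usable heterozygote for rare anchor {'/'.join(rare_entry)}"
        )
    for ind in used:
        for assay in downstream:
            expected = frozenset(residue_union[assay.name]) | \
                partner_sets_by_ind[ind][assay.name]
            if expected != observed_by_ind[ind][assay.name]:
                raise SubtractionConflictError(
                    f"residues for rare anchor {'/'.join(rare_entry)} disagree: "
                    f"individual {ind} at {assay.name} is inconsistent with the "
                    f"pooled residue"
                )
    entries = {e for entry_set in residue_union.values() for e in entry_set}
    contents = _merge_contents(
        _entries_to_contents([rare_entry], db), _entries_to_contents(entries, db)
    )
    return InferredHaplotype(
        contents=contents,
        support=len(used),
        provenance="heterozygote_subtraction",
        low_confidence=len(used) < 2,
    )


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def infer_haplotypes(
    table: GenotypeTable,
    db: AlleleDatabase,
    assays: Sequence[AssayProfile],
    anchor_assay: str = "DRB1_455",
    min_support: int = 4,
) -> InferredHaplotypeSet:
    """Full inference: anchor, extend, then subtraction for rare alleles."""
    result = InferredHaplotypeSet()
    anchors = find_anchor_homozygotes(table, anchor_assay)
    inferred: list[InferredHaplotype] = []
    for entry in sorted(anchors):
        haps, warns = extend_haplotypes(
            entry, anchors[entry], table, assays, db, anchor_assay, min_support
        )
        inferred.extend(haps)
        result.warnings.extend(warns)

    seen_keys = {h.content_key() for h in inferred}
    partial = InferredHaplotypeSet(
        haplotypes={f"hap{i + 1}": h for i, h in enumerate(inferred)}
    )
    rare = observed_anchor_entries(table, anchor_assay) - set(anchors)
    for entry in sorted(rare):
        try:
            hap = subtract_heterozygotes(
                entry, table, partial, assays, db, anchor_assay
            )
        except (ValueError, SubtractionConflictError) as exc:
            result.deferred_anchors.append(entry)
            result.warnings.append(str(exc))
            continue
        if hap.content_key() not in seen_keys:
            inferred.append(hap)
            seen_keys.add(hap.content_key())

    inferred.sort(key=lambda h: h.content_key())
    width = max(1, len(str(len(inferred))))
    result.haplotypes = {
        f"hap{i + 1:0{width}d}": h for i, h in enumerate(inferred)
    }
    _refine_residue_completions(result, table, assays, db)
    return result


def _count_unresolved(
    table: GenotypeTable,
    haplotypes: InferredHaplotypeSet,
    assays: Sequence[AssayProfile],
    db: AlleleDatabase,
) -> int:
    resolution = resolve_individuals(table, haplotypes, assays, db)
    return sum(1 for pairs in resolution.values() if not pairs)


def _refine_residue_completions(
    result: InferredHaplotypeSet,
    table: GenotypeTable,
    assays: Sequence[AssayProfile],
    db: AlleleDatabase,
) -> None:
    """Validation-driven repair of residue-completed haplotypes.

    Residue completion cannot see alleles shared between the inferred
    haplotype and the haplotype it was subtracted from.  Individuals
    elsewhere in the cohort (other partner backgrounds) expose the
    omission as validation failures, so each candidate restoration of
    shared alleles is scored by the number of unexplainable individuals
    and the most parsimonious repair that minimises it is kept.
    """
    import itertools as it
    from collections import Counter

    flagged = [
        label for label in sorted(result.haplotypes)
        if result.haplotypes[label].residue_parent is not None
    ]
    if not flagged:
        return
    baseline = _count_unresolved(table, result, assays, db)
    if baseline == 0:
        return
    for label in flagged:
        hap = result.haplotypes[label]
        candidates = []
        for locus, entries in hap.residue_parent.items():
            have = hap.contents.get(locus, ())
            for e in entries:
                if e not in have:
                    candidates.append((locus, e))
        best_count, best_trial, best_size = baseline, None, 0
        for r in range(1, len(candidates) + 1):
            for combo in it.combinations(candidates, r):
                per_locus = Counter(loc for loc, _ in combo)
                if any(
                    len(hap.contents.get(loc, ())) + k > 2
                    for loc, k in per_locus.items()
                ):
                    continue
                trial = {loc: ents for loc, ents in hap.contents.items()}
                for loc, e in combo:
                    trial[loc] = tuple(sorted(trial.get(loc, ()) + (e,)))
                original = hap.contents
                hap.contents = trial
                count = _count_unresolved(table, result, assays, db)
                hap.contents = original
                if count < best_count:
                    best_count, best_trial, best_size = count, trial, r
        if best_trial is not None:
            hap.contents = best_trial
            result.warnings.append(
                f"residue-completed haplotype {label} refined by validation "
                f"(restored {best_size} shared allele(s); unexplained "
                f"individuals {baseline} -> {best_count})"
            )
            baseline = best_count


# ---------------------------------------------------------------------------
# Validation and frequencies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Deviation:
    individual: str
    assay: str
    detail: str


def _pair_consistent(
    pair_expected: Mapping[str, frozenset[Entry]],
    calls: Mapping[str, GenotypeCall],
    assays: Sequence[AssayProfile],
) -> tuple[bool, list[str]]:
    failing = []
    for assay in assays:
        call = calls[assay.name]
        expected = pair_expected[assay.name]
        if not expected:
            ok = call.status == "no_product"
        elif call.status in ("called", "ambiguous"):
            ok = expected in call.explanations
        else:
            ok = False
        if not ok:
            failing.append(assay.name)
    return (not failing), failing


def resolve_individuals(
    table: GenotypeTable,
    haplotypes: InferredHaplotypeSet,
    assays: Sequence[AssayProfile],
    db: AlleleDatabase,
) -> dict[str, list[tuple[str, str]]]:
    """Individual -> all haplotype pairs consistent with every assay call."""
    labels = sorted(haplotypes.haplotypes)
    pair_expectations: dict[tuple[str, str], dict[str, frozenset[Entry]]] = {}
    for i, l1 in enumerate(labels):
        for l2 in labels[i:]:
            pair_expectations[(l1, l2)] = {
                a.name: expected_entry_set(
                    [haplotypes.haplotypes[l1].contents,
                     haplotypes.haplotypes[l2].contents],
                    a, db,
                )
                for a in assays
            }
    out: dict[str, list[tuple[str, str]]] = {}
    for ind in sorted(table):
        consistent = [
            pair
            for pair, expected in pair_expectations.items()
            if _pair_consistent(expected, table[ind], assays)[0]
        ]
        out[ind] = consistent
    return out


def validate(
    table: GenotypeTable,
    haplotypes: InferredHaplotypeSet,
    assays: Sequence[AssayProfile],
    db: AlleleDatabase,
) -> list[Deviation]:
    """Individuals not explained by any unordered haplotype pair.

    Deviations are reported per assay (cross-amplifying assays cannot
    always localise the inconsistent locus): for each unexplained
    individual, the assays failing under its best-scoring pair.
    """
    labels = sorted(haplotypes.haplotypes)
    if not labels:
        return [Deviation(ind, "*", "no haplotypes inferred") for ind in sorted(table)]
    resolution = resolve_individuals(table, haplotypes, assays, db)
    deviations: list[Deviation] = []
    pairs = [(l1, l2) for i, l1 in enumerate(labels) for l2 in labels[i:]]
    for ind, consistent in resolution.items():
        if consistent:
            continue
        best_failing: Optional[list[str]] = None
        best_pair = None
        for pair in pairs:
            expected = {
                a.name: expected_entry_set(
                    [haplotypes.haplotypes[pair[0]].contents,
                     haplotypes.haplotypes[pair[1]].contents],
                    a, db,
                )
                for a in assays
            }
            _, failing = _pair_consistent(expected, table[ind], assays)
            if best_failing is None or len(failing) < len(best_failing):
                best_failing, best_pair = failing, pair
        for assay_name in best_failing or []:
            deviations.append(
                Deviation(
                    ind, assay_name,
                    f"inconsistent with best pair {best_pair[0]}/{best_pair[1]}",
                )
            )
    return deviations


@dataclass
class FrequencyReport:
    haplotype_frequencies: dict[str, float]
    allele_frequencies: dict[str, dict[str, float]]  # locus -> entry label -> freq
    anchor_homozygosity: float
    haplotype_homozygosity: float
    n_resolved: int
    n_unresolved: int


def frequencies(
    resolution: Mapping[str, Sequence[tuple[str, str]]],
    haplotypes: InferredHaplotypeSet,
    anchor_locus: str = "DRB1",
) -> FrequencyReport:
    """Haplotype/allele frequencies and homozygosity from resolved pairs.

    Individuals with several consistent pairs contribute equal fractional
    weight to each; unresolved individuals are excluded and counted.
    """
    hap_w: dict[str, float] = {label: 0.0 for label in haplotypes.haplotypes}
    hom_w = 0.0
    anchor_hom_w = 0.0
    n_resolved = n_unresolved = 0
    for ind, pairs in resolution.items():
        if not pairs:
            n_unresolved += 1
            continue
        n_resolved += 1
        w = 1.0 / len(pairs)
        for l1, l2 in pairs:
            hap_w[l1] += w
            hap_w[l2] += w
            if l1 == l2:
                hom_w += w
            a1 = haplotypes.haplotypes[l1].contents.get(anchor_locus)
            a2 = haplotypes.haplotypes[l2].contents.get(anchor_locus)
            if a1 == a2:
                anchor_hom_w += w
    total = sum(hap_w.values())
    hap_freq = {k: (v / total if total else 0.0) for k, v in hap_w.items()}
    allele_freq: dict[str, dict[str, float]] = {}
    for label, hap in haplotypes.haplotypes.items():
        for locus, entries in hap.contents.items():
            for entry in entries:
                key = "/".join(entry)
                allele_freq.setdefault(locus, {}).setdefault(key, 0.0)
                allele_freq[locus][key] += hap_freq[label]
    for locus, freqs in allele_freq.items():
        s = sum(freqs.values())
        if s > 0:
            allele_freq[locus] = {k: v / s for k, v in freqs.items()}
    return FrequencyReport(
        haplotype_frequencies=hap_freq,
        allele_frequencies=allele_freq,
        anchor_homozygosity=(anchor_hom_w / n_resolved if n_resolved else float("nan")),
        haplotype_homozygosity=(hom_w / n_resolved if n_resolved else float("nan")),
        n_resolved=n_resolved,
        n_unresolved=n_unresolved,
    )


def write_deviations(deviations: Sequence[Deviation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tassay\tdetail\n")
        for d in deviations:
            fh.write(f"{d.individual}\t{d.assay}\t{d.detail}\n")
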