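"""Orchestration of the full analysis workflow.

Stages run in the order of the underlying study design: genotype the
cohort (deconvolution of mixed consensus sequences), infer haplotypes by
homozygote anchoring, validate the inferred set against every individual,
place DQB alleles phylogenetically, and test for positive selection.  In
demo mode the cohort is simulated from the packaged panel, so the whole
pipeline runs from a config and a seed with no external files.

All randomness flows from the single master seed; reports are written
deterministically (sorted keys, no timestamps), so a rerun with an
identical config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__, fixture
from .alleledb import read_fasta, write_panel
from .deconvolve import (
    NO_PRODUCT,
    GenotypeCall,
    call_genotype,
    read_observations,
    write_calls,
    write_observations,
)
from .haplotyper import (
    frequencies,
    infer_haplotypes,
    resolve_individuals,
    validate,
    write_deviations,
)
from .locusphylo import DistanceMatrix, bootstrap_support, nj_tree, write_newick
from .selection import (
    CodonAlignment,
    TreeIndex,
    bonferroni,
    fit_model_pair,
    lrt,
    m0_prefit,
    neb_sites,
)
from .synth import SimConfig, read_population, simulate_cohort, write_population

ALL_STAGES = ("simulate", "genotype", "haplotype", "validate", "phylo", "selection")

EXIT_OK = 0
EXIT_DEVIATIONS = 2
EXIT_STAGE_FAILURE = 3


@dataclass
class PipelineConfig:
    outdir: str = "mhchap_run"
    seed: int = 1
    stages: Sequence[str] = ALL_STAGES
    # simulation
    n_individuals: int = 300
    frequencies: Optional[Sequence[float]] = None  # default: uniform over panel
    novel_allele_rate: float = 0.0
    novel_divergence: int = 3
    # genotyping / inference
    anchor_assay: str = "DRB1_455"
    anchor_locus: str = "DRB1"
    min_support: int = 4
    kmax: int = 4
    # phylogeny
    bootstrap_B: int = 200
    # selection
    selection_groups: Sequence[str] = ("DQB",)
    selection_pairs: Sequence[Sequence[str]] = (("M1a", "M2a"),)
    selection_starts: int = 2
    # non-simulation inputs
    database_fasta: Optional[str] = None
    observations_fasta: Optional[str] = None
    population_tsv: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def canonical(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


class StageFailure(RuntimeError):
    def __init__(self, stage: str, message: str, report: dict) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.report = report


def _calls_to_json(table) -> dict:
    return {
        ind: {
            assay: {
                "status": call.status,
                "explanations": [
                    sorted(list(entry) for entry in exp)
                    for exp in call.explanations
                ],
            }
            for assay, call in assays.items()
        }
        for ind, assays in table.items()
    }


def _calls_from_json(data: dict) -> dict:
    table = {}
    for ind, assays in data.items():
        table[ind] = {}
        for assay, rec in assays.items():
            table[ind][assay] = GenotypeCall(
                status=rec["status"],
                explanations=tuple(
                    frozenset(tuple(entry) for entry in exp)
                    for exp in rec["explanations"]
                ),
                assay=assay,
            )
    return table


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the run report.

    Raises :class:`StageFailure` (carrying the partial report) when a
    stage aborts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "stages": {},
    }
    stages = list(config.stages)
    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r}")

    if config.database_fasta:
        db = read_fasta(config.database_fasta)
    else:
        db = fixture.fixture_database()
    panel = fixture.fixture_panel(db) if not config.database_fasta else None
    assay_map = fixture.fixture_assays()
    assays = fixture.default_genotyping_assays()

    observations = None
    individuals = None
    table = None
    inferred = None

    try:
        if "simulate" in stages:
            if panel is None:
                raise StageFailure("simulate", "no panel for simulation", report)
            freqs = config.frequencies or [1.0 / len(panel.labels)] * len(panel.labels)
            sim = SimConfig(
                frequencies=freqs,
                n=config.n_individuals,
                seed=config.seed,
                novel_allele_rate=config.novel_allele_rate,
                novel_divergence=config.novel_divergence,
            )
            cohort = simulate_cohort(panel, db, assays, sim)
            individuals = cohort.individuals
            observations = cohort.observations
            write_population(individuals, outdir / "population.tsv")
            write_observations(observations, outdir / "observations.fasta")
            report["stages"]["simulate"] = {
                "n_individuals": len(individuals),
                "n_observations": sum(
                    1 for od in observations.values()
                    for o in od.values() if o is not NO_PRODUCT
                ),
                "n_novel_injected": len(cohort.novel_truth),
            }

        if "genotype" in stages:
            if observations is None:
                src = config.observations_fasta or outdir / "observations.fasta"
                pop = config.population_tsv or outdir / "population.tsv"
                individuals = read_population(pop)
                observations = read_observations(
                    src, [i.id for i in individuals],
                    [a.name for a in assays],
                )
            table = {
                ind: {
                    a: call_genotype(obs, db, assay_map[a], kmax=config.kmax)
                    for a, obs in od.items()
                }
                for ind, od in observations.items()
            }
            write_calls(table, outdir / "calls.tsv")
            with open(outdir / "calls.json", "w") as fh:
                json.dump(_calls_to_json(table), fh, sort_keys=True, indent=1)
            status_counts: dict[str, int] = {}
            for od in table.values():
                for call in od.values():
                    status_counts[call.status] = status_counts.get(call.status, 0) + 1
            report["stages"]["genotype"] = {"status_counts": status_counts}

        if "haplotype" in stages:
            if table is None:
                with open(outdir / "calls.json") as fh:
                    table = _calls_from_json(json.load(fh))
            inferred = infer_haplotypes(
                table, db, assays,
                anchor_assay=config.anchor_assay,
                min_support=config.min_support,
            )
            write_panel(inferred.to_panel(), outdir / "inferred_panel.tsv")
            report["stages"]["haplotype"] = {
                "n_haplotypes": len(inferred.haplotypes),
                "n_low_confidence": sum(
                    h.low_confidence for h in inferred.haplotypes.values()
                ),
                "n_deferred_anchors": len(inferred.deferred_anchors),
                "n_warnings": len(inferred.warnings),
            }

        if "validate" in stages:
            if table is None:
                with open(outdir / "calls.json") as fh:
                    table = _calls_from_json(json.load(fh))
            if inferred is None:
                raise StageFailure(
                    "validate", "validation requires the haplotype stage", report
                )
            deviations = validate(table, inferred, assays, db)
            write_deviations(deviations, outdir / "deviations.tsv")
            resolution = resolve_individuals(table, inferred, assays, db)
            freq = frequencies(resolution, inferred, anchor_locus=config.anchor_locus)
            report["stages"]["validate"] = {
                "n_deviations": len(deviations),
                "n_resolved": freq.n_resolved,
                "n_unresolved": freq.n_unresolved,
                "anchor_homozygosity": round(freq.anchor_homozygosity, 6),
                "haplotype_homozygosity": round(freq.haplotype_homozygosity, 6),
                "haplotype_frequencies": {
                    k: round(v, 6) for k, v in freq.haplotype_frequencies.items()
                },
            }

        if "phylo" in stages:
            aln = fixture.dqb_alignment(db)
            tree, supports = bootstrap_support(
                aln, B=config.bootstrap_B, seed=config.seed
            )
            write_newick(tree, outdir / "dqb_tree.nwk")
            report["stages"]["phylo"] = {
                "n_alleles": len(aln),
                "bootstrap_B": config.bootstrap_B,
                "n_splits": len(supports),
                "mean_support": round(
                    sum(supports.values()) / len(supports), 4
                ) if supports else None,
            }

        if "selection" in stages:
            sel_report = {}
            lrt_rows = []
            for group in config.selection_groups:
                coding = fixture.coding_alignment(db, group)
                aln = CodonAlignment.from_sequences(coding)
                guide = nj_tree(DistanceMatrix.from_alignment(coding))
                m0, scaled = m0_prefit(aln, TreeIndex.from_dendropy(guide),
                                       n_starts=config.selection_starts)
                group_info = {
                    "n_alleles": aln.n_sequences,
                    "n_codons": aln.n_codons,
                    "m0_omega": round(m0.params["omega"], 4),
                    "kappa": round(m0.kappa, 4),
                    "tests": {},
                }
                for pair in config.selection_pairs:
                    null, alt = fit_model_pair(
                        aln, scaled, tuple(pair), n_starts=config.selection_starts
                    )
                    res = lrt(null, alt)
                    group_info["tests"]["%s_vs_%s" % tuple(pair)] = {
                        "lnL_null": round(null.log_likelihood, 4),
                        "lnL_alt": round(alt.log_likelihood, 4),
                        "statistic": round(res.statistic, 4),
                        "p_value": round(res.p_value, 6),
                    }
                    lrt_rows.append(
                        (group, pair[0], pair[1], null.log_likelihood,
                         alt.log_likelihood, res.statistic, res.p_value)
                    )
                    if tuple(pair) == ("M1a", "M2a"):
                        scan = neb_sites(alt, aln, scaled)
                        group_info["n_positive_sites_neb"] = int(scan.flags.sum())
                sel_report[group] = group_info
            m = len(lrt_rows)
            sel_report["bonferroni_alpha"] = round(bonferroni(0.05, max(m, 1)), 6)
            with open(outdir / "lrt.tsv", "w") as fh:
                fh.write("group\tnull\talt\tlnL_null\tlnL_alt\tstatistic\tp_value\n")
                for row in lrt_rows:
                    fh.write("\t".join(
                        f"{x:.6f}" if isinstance(x, float) else str(x) for x in row
                    ) + "\n")
            report["stages"]["selection"] = sel_report
    except StageFailure:
        raise
    except Exception as exc:  # convert to stage failure with partial report
        stage = next(
            (s for s in stages if s not in report["stages"]), "unknown"
        )
        _write_report(report, outdir)
        raise StageFailure(stage, str(exc), report) from exc

    _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir: Path) -> None:
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
        fh.write("\n")


def exit_code(report: dict) -> int:
    val = report.get("stages", {}).get("validate", {})
    if val.get("n_deviations", 0) > 0:
        return EXIT_DEVIATIONS
    return EXIT_OK
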