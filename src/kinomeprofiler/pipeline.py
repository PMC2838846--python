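"""End-to-end kinome analysis runs.

One :class:`RunConfig` drives the whole flow — classify every proteome,
scan the resulting kinases for domains, build the comparative statistics, and
run the domain-frequency PCA — writing every stage's TSV/JSON report into a
run directory together with a copy of the config and a run log.  Stage
outputs are pure functions of (inputs, config): rerunning with the same
inputs yields byte-identical reports (timestamps live only in the log).

Proteomes are discovered as ``<proteome_dir>/<abbreviation>.fasta`` for each
row of the species table, in table order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .comparative_stats import (
    KinomeSummary,
    cohort_table,
    compare_density,
    summarize_kinome,
    write_wilcoxon_json,
)
from .domain_annotator import (
    DomainInventory,
    domain_prevalence,
    scan_domains,
    summarize_domains,
    write_hits_tsv,
    write_summary_json,
)
from .domain_pca import build_frequency_matrix, pca, project3
from .kinome_classifier import (
    GroupLibrary,
    Kinome,
    extract_kinome,
    write_kinome_tsv,
)
from .profile_hmm import read_model
from .proteome_io import load_species_table, read_fasta

logger = logging.getLogger("kinomeprofiler")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the offending input id."""

    def __init__(self, stage: str, input_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on input {input_id!r}: {cause}")
        self.stage = stage
        self.input_id = input_id
        self.cause = cause


@dataclass
class RunConfig:
    """Fully serialisable description of one pipeline run."""

    proteome_dir: str
    species_table: str
    group_library: str
    domain_library: str
    out_dir: str
    kinase_cutoff_bits: float = 20.0
    domain_threshold_bits: float = 20.0
    pca_prevalence_threshold: float = 0.5
    pca_center: bool = True
    pca_scale: bool = False
    wilcoxon_clade_a: str | None = None
    wilcoxon_clade_b: str | None = None
    wilcoxon_exact_limit: int = 25
    seed: int = 0
    version: str = __version__

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        doc.pop("version", None)
        return cls(**doc)


def _load_domain_library(path: str | Path):
    files = sorted(Path(path).glob("*.json"))
    if not files:
        raise FileNotFoundError(f"no domain model JSON files in {path}")
    return [read_model(f) for f in files]


def run_full_analysis(config: RunConfig) -> Path:
    """Run classify → domains → stats → pca; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        config.to_yaml(out / "config_used.yaml")
        species = load_species_table(config.species_table)
        group_lib = GroupLibrary.from_directory(config.group_library)
        domain_lib = _load_domain_library(config.domain_library)
        logger.info(
            "run start: %d species, %d group models, %d domain models",
            len(species), len(group_lib.models), len(domain_lib),
        )

        # ---- stage 1: classify -------------------------------------------
        kinomes: list[Kinome] = []
        proteomes: dict[str, list] = {}
        (out / "kinomes").mkdir(exist_ok=True)
        for sp in species:
            fasta = Path(config.proteome_dir) / f"{sp.abbreviation}.fasta"
            try:
                proteome = read_fasta(fasta)
                kinome = extract_kinome(
                    proteome, sp, group_lib, cutoff=config.kinase_cutoff_bits
                )
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise PipelineStageError("classify", sp.abbreviation, exc) from exc
            proteomes[sp.abbreviation] = proteome
            kinomes.append(kinome)
            write_kinome_tsv(kinome, out / "kinomes" / f"{sp.abbreviation}.tsv")
            logger.info("classify %s: %d/%d kinases",
                        sp.abbreviation, len(kinome.calls), kinome.proteome_size)

        # ---- stage 2: domains --------------------------------------------
        inventories: dict[str, DomainInventory] = {}
        (out / "domains").mkdir(exist_ok=True)
        for kinome in kinomes:
            sp = kinome.species
            try:
                by_id = {p.id: p for p in proteomes[sp.abbreviation]}
                kinases = [by_id[c.protein_id] for c in kinome.calls]
                inv = scan_domains(
                    kinases, domain_lib, threshold=config.domain_threshold_bits
                )
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError("domains", sp.abbreviation, exc) from exc
            inventories[sp.abbreviation] = inv
            write_hits_tsv(inv, out / "domains" / f"{sp.abbreviation}.tsv")
            logger.info("domains %s: %d hits on %d kinases",
                        sp.abbreviation, len(inv.hits), inv.n_kinases)
        pooled_hits = [h for inv in inventories.values() for h in inv.hits]
        pooled = DomainInventory(
            hits=pooled_hits, n_kinases=sum(i.n_kinases for i in inventories.values())
        )
        write_summary_json(summarize_domains(pooled), out / "domain_summary.json")

        # ---- stage 3: stats ----------------------------------------------
        try:
            summaries = [summarize_kinome(k) for k in kinomes]
            counts, freqs, density, clade_means = cohort_table(summaries)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("stats", "cohort", exc) from exc
        counts.to_csv(out / "counts.tsv", sep="\t")
        freqs.to_csv(out / "frequencies.tsv", sep="\t", float_format="%.4f")
        density.to_csv(out / "density.tsv", sep="\t", float_format="%.6f")
        clade_means.to_csv(out / "clade_means.tsv", sep="\t", float_format="%.4f")
        clades = [s.clade_label for s in species]
        clade_a = config.wilcoxon_clade_a
        clade_b = config.wilcoxon_clade_b
        if clade_a is None or clade_b is None:
            distinct = list(dict.fromkeys(clades))
            if len(distinct) >= 2:
                clade_a, clade_b = distinct[0], distinct[1]
        if clade_a is not None and clade_b is not None:
            try:
                wres = compare_density(
                    summaries, clade_a, clade_b,
                    exact_limit=config.wilcoxon_exact_limit,
                )
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError("stats", f"{clade_a}-vs-{clade_b}", exc) from exc
            write_wilcoxon_json(
                wres, out / "wilcoxon.json",
                extra={"clade_a": clade_a, "clade_b": clade_b,
                       "quantity": "kinome_density"},
            )
            logger.info("wilcoxon %s vs %s: U=%g p=%g",
                        clade_a, clade_b, wres.U_statistic, wres.p_value)

        # ---- stage 4: pca -------------------------------------------------
        try:
            matrix = build_frequency_matrix(
                inventories, prevalence_threshold=config.pca_prevalence_threshold
            )
            result = pca(matrix, center=config.pca_center, scale=config.pca_scale)
            proj = project3(result, matrix, species)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("pca", "cohort", exc) from exc
        matrix.to_frame().to_csv(out / "pca_matrix.tsv", sep="\t", float_format="%.6f")
        proj.to_csv(out / "pca_scores.tsv", sep="\t", index=False, float_format="%.6f")
        with open(out / "pca_variance.tsv", "w") as fh:
            fh.write("component\texplained_variance_fraction\n")
            for i, v in enumerate(result.explained_variance_fraction, start=1):
                fh.write(f"PC{i}\t{v:.6f}\n")
        prevalence = domain_prevalence(inventories)
        (out / "domain_prevalence.json").write_text(
            json.dumps(prevalence, indent=1, sort_keys=True)
        )
        logger.info(
            "pca: %d domain types retained of %d observed",
            len(matrix.domain_names), len(prevalence),
        )
        logger.info("run complete")
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()
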