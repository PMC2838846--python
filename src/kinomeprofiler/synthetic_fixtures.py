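"""Synthetic benchmark data with full ground truth.

Real kinome studies need dozens of proteomes plus curated HMM libraries; for
testing, this module generates miniature stand-ins at desk scale:

* toy kinase-group libraries — one mutually divergent profile HMM per group,
  controlled by a total-variation ``divergence`` between consensus emission
  columns;
* toy domain libraries carrying the seven canonical catalytic domain names
  plus synthetic accessory families;
* synthetic proteomes — planted kinases (sampled from group models and
  embedded in null-model flanks, with planted domain segments) mixed with
  pure-background sequences;
* multi-species cohorts — two or more clades with clade-specific kinase-group
  profiles, domain-frequency profiles and kinome-density distributions, so
  that every downstream comparison (density shift, domain PCA clustering)
  has a known planted answer.

Every generator is deterministic under its seed; a cohort written twice with
the same design is byte-identical.  Planted sequences are consensus walks
with emission noise (each residue drawn from the match-state emission
distribution); full stochastic traversal of insert/delete states is available
by flag but off by default so that planted score margins stay controllable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .domain_annotator import CATALYTIC_DOMAINS
from .kinome_classifier import KINASE_GROUPS, GroupLibrary
from .profile_hmm import ProfileHMM
from .proteome_io import (
    AMINO_ACIDS,
    ProteinRecord,
    SpeciesRecord,
    write_fasta,
    write_species_table,
)

#: accessory domain names for toy libraries (FHA-like real names first,
#: synthetic ACCnn names beyond)
_ACCESSORY_NAMES = (
    "FHA", "HATPase_c", "FATC", "FAT", "C1_1",
    "PBD", "PX", "SH3_1", "WD40", "TPR_1",
)


# ---------------------------------------------------------------------------
# cohort design
# ---------------------------------------------------------------------------

def _check_profile(profile: Mapping[str, float], what: str) -> None:
    if any(w < 0 for w in profile.values()):
        raise ValueError(f"{what} has negative weights")
    if abs(sum(profile.values()) - 1.0) > 1e-6:
        raise ValueError(f"{what} weights must sum to 1")


@dataclass
class CladeDesign:
    """One clade's generative profile: species count, kinase-group sampling
    weights, domain sampling weights, and the kinome-density distribution
    (mean and SD, both in percent of proteome)."""

    name: str
    n_species: int
    group_weights: dict[str, float]
    domain_weights: dict[str, float]
    density_mean: float
    density_sd: float
    accessory_rate: float = 2.0  # mean accessory domains per kinase (Poisson)

    def __post_init__(self) -> None:
        _check_profile(self.group_weights, f"clade {self.name} group profile")
        _check_profile(self.domain_weights, f"clade {self.name} domain profile")
        if self.density_sd < 0:
            raise ValueError("density SD must be >= 0")
        unknown = set(self.group_weights) - set(KINASE_GROUPS)
        if unknown:
            raise ValueError(f"unknown kinase groups in profile: {sorted(unknown)}")


@dataclass
class CohortDesign:
    """A multi-clade synthetic cohort: clade profiles, background proteome
    size per species, and the master seed."""

    clades: list[CladeDesign]
    background_count: int = 1500
    background_length: tuple[int, int] = (150, 350)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.clades:
            raise ValueError("cohort needs at least one clade")
        if self.background_count < 1:
            raise ValueError("background_count must be >= 1")


#: kinase-group sampling weights echoing the observed fungal distribution:
#: AGC/CAMK/CMGC/STE dominate (~88% together), RGC structurally absent.
DEFAULT_GROUP_WEIGHTS = {
    "AGC": 0.20, "Alpha": 0.005, "CAMK": 0.30, "CK1": 0.04, "CMGC": 0.25,
    "PDHK": 0.01, "PIKK": 0.03, "RGC": 0.0, "RIO": 0.02, "STE": 0.13,
    "TK": 0.005, "TKL": 0.01,
}


def default_cohort_design(seed: int = 0) -> CohortDesign:
    """Two 8-species clades with a planted kinome-density shift
    (0.5% vs 1.2%, SD 0.1) and well-separated domain profiles
    (total-variation distance ~0.6 between clades)."""
    clade_a = CladeDesign(
        name="CladeA",
        n_species=8,
        group_weights=dict(DEFAULT_GROUP_WEIGHTS),
        domain_weights={
            "Pkinase": 0.38, "Pkinase_C": 0.06, "PI3_PI4_kinase": 0.06,
            "FHA": 0.20, "HATPase_c": 0.15, "C1_1": 0.10, "FAT": 0.05,
        },
        density_mean=0.5,
        density_sd=0.1,
    )
    clade_b = CladeDesign(
        name="CladeB",
        n_species=8,
        group_weights=dict(DEFAULT_GROUP_WEIGHTS),
        domain_weights={
            "Pkinase": 0.38, "RIO1": 0.06, "BCDHK_Adom3": 0.06,
            "WD40": 0.20, "TPR_1": 0.15, "PBD": 0.10, "PX": 0.05,
        },
        density_mean=1.2,
        density_sd=0.1,
    )
    return CohortDesign(clades=[clade_a, clade_b], seed=seed)


@dataclass(frozen=True)
class PlantedDomain:
    name: str
    start: int
    end: int


@dataclass
class GroundTruth:
    """Per-protein true labels (group name or 'background') and the planted
    domain architecture of every kinase."""

    labels: dict[str, str]
    domains: dict[str, list[PlantedDomain]]

    def to_json(self) -> dict:
        return {
            "labels": dict(sorted(self.labels.items())),
            "domains": {
                k: [[d.name, d.start, d.end] for d in v]
                for k, v in sorted(self.domains.items())
            },
        }

    @classmethod
    def from_json(cls, doc: Mapping) -> "GroundTruth":
        return cls(
            labels=dict(doc["labels"]),
            domains={
                k: [PlantedDomain(name=n, start=s, end=e) for n, s, e in v]
                for k, v in doc["domains"].items()
            },
        )


# ---------------------------------------------------------------------------
# toy model construction
# ---------------------------------------------------------------------------

def _default_transitions(L: int) -> np.ndarray:
    t = np.zeros((L + 1, 7))
    t[:, 0] = 0.99   # M->M (row L: M_L->E)
    t[:, 1] = 0.005  # M->I
    t[:, 2] = 0.005  # M->D
    t[:, 3] = 0.90   # I->M
    t[:, 4] = 0.10   # I->I
    t[:, 5] = 0.90   # D->M
    t[:, 6] = 0.10   # D->D
    t[L, 0] = 0.995
    t[L, 1] = 0.005
    t[L, 2] = 0.0
    t[0, 5], t[0, 6] = 1.0, 0.0  # no delete state at the begin node
    t[L, 5], t[L, 6] = 1.0, 0.0  # D_L exits deterministically
    return t


def _model_from_consensus(
    name: str, group: str | None, consensus: np.ndarray, divergence: float
) -> ProfileHMM:
    L = consensus.size
    # peak weight such that the total-variation distance between two columns
    # with different consensus letters is exactly `divergence`
    peak = (19.0 * divergence + 1.0) / 20.0
    rest = (1.0 - peak) / 19.0
    me = np.full((L, 20), rest)
    me[np.arange(L), consensus] = peak
    return ProfileHMM(
        name=name,
        group=group,
        length=L,
        match_emissions=me,
        insert_emissions=np.full((L + 1, 20), 1.0 / 20.0),
        transitions=_default_transitions(L),
        null_model=np.full(20, 1.0 / 20.0),
        alignment_mode="local",
    )


def _divergent_consensi(
    n: int, length: int, rng: np.random.Generator, max_identity: float = 0.3
) -> list[np.ndarray]:
    consensi: list[np.ndarray] = []
    while len(consensi) < n:
        cand = rng.integers(0, 20, size=length)
        if all((cand == c).mean() < max_identity for c in consensi):
            consensi.append(cand)
    return consensi


def make_group_library(
    n_groups: int = 12,
    model_length: int = 40,
    divergence: float = 0.9,
    seed: int | Sequence[int] = 0,
) -> GroupLibrary:
    """A toy kinase-group library: one divergent model per group, named after
    the 12 kinase groups (in order) for ``n_groups`` <= 12."""
    if not 1 <= n_groups <= len(KINASE_GROUPS):
        raise ValueError(f"n_groups must be 1..{len(KINASE_GROUPS)}")
    if not 0 < divergence <= 1:
        raise ValueError("divergence must be in (0, 1]")
    rng = np.random.default_rng(seed)
    consensi = _divergent_consensi(n_groups, model_length, rng)
    models = [
        _model_from_consensus(f"{g}_toy", g, c, divergence)
        for g, c in zip(KINASE_GROUPS[:n_groups], consensi)
    ]
    return GroupLibrary(models=models)


def make_domain_library(
    n_catalytic: int = 7,
    n_accessory: int = 33,
    model_length: int = 30,
    divergence: float = 0.9,
    seed: int | Sequence[int] = 0,
) -> list[ProfileHMM]:
    """A toy domain library whose first ``n_catalytic`` models carry the
    canonical catalytic domain names (Pkinase, ...), the rest accessory names."""
    catalytic_names = (
        "Pkinase", "Pkinase_C", "PI3_PI4_kinase", "BCDHK_Adom3",
        "RIO1", "Pkinase_Tyr", "Alpha_kinase",
    )[:n_catalytic]
    accessory_names = [
        _ACCESSORY_NAMES[i] if i < len(_ACCESSORY_NAMES) else f"ACC{i + 1:02d}"
        for i in range(n_accessory)
    ]
    names = list(catalytic_names) + accessory_names
    rng = np.random.default_rng(seed)
    consensi = _divergent_consensi(len(names), model_length, rng)
    return [_model_from_consensus(nm, None, c, divergence) for nm, c in zip(names, consensi)]


# ---------------------------------------------------------------------------
# sequence sampling
# ---------------------------------------------------------------------------

def _null_stretch(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _emit_from_model(rng: np.random.Generator, model: ProfileHMM,
                     stochastic_indels: bool = False) -> str:
    """Consensus walk with emission noise: one residue per match column drawn
    from its emission distribution.  With ``stochastic_indels`` the walk also
    follows the transition probabilities through insert/delete states."""
    out: list[str] = []
    if not stochastic_indels:
        for j in range(model.length):
            out.append(AMINO_ACIDS[rng.choice(20, p=model.match_emissions[j])])
        return "".join(out)
    j = 0  # node index; state machine over M/I/D
    state = "M"
    while j < model.length:
        t = model.transitions[j]
        if state == "M":
            probs, nxt = [t[0], t[1], t[2]], ["M", "I", "D"]
        elif state == "I":
            probs, nxt = [t[3], t[4]], ["M", "I"]
        else:
            probs, nxt = [t[5], t[6]], ["M", "D"]
        choice = nxt[rng.choice(len(nxt), p=np.array(probs) / sum(probs))]
        if choice == "M":
            j += 1
            out.append(AMINO_ACIDS[rng.choice(20, p=model.match_emissions[j - 1])])
        elif choice == "I":
            out.append(AMINO_ACIDS[rng.choice(20, p=model.insert_emissions[j])])
        else:
            j += 1
        state = choice
    return "".join(out)


def _weighted_choice(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    names = sorted(weights)
    p = np.array([weights[n] for n in names], dtype=float)
    p = p / p.sum()
    return names[rng.choice(len(names), p=p)]


def sample_proteome(
    group_library: GroupLibrary,
    n_background: int,
    kinase_groups: Sequence[str] | None = None,
    n_kinases: int | None = None,
    group_weights: Mapping[str, float] | None = None,
    domain_library: Sequence[ProfileHMM] | None = None,
    domain_weights: Mapping[str, float] | None = None,
    accessory_rate: float = 0.0,
    background_length: tuple[int, int] = (150, 350),
    flank_length: tuple[int, int] = (30, 100),
    spacer_length: tuple[int, int] = (10, 40),
    seed: int | Sequence[int] = 0,
    id_prefix: str = "prot",
    stochastic_indels: bool = False,
) -> tuple[list[ProteinRecord], GroundTruth]:
    """A synthetic proteome with planted kinases of known group (and optional
    planted domain architectures) plus pure-background sequences.

    The kinase roster comes either from an explicit ``kinase_groups`` list or
    by sampling ``n_kinases`` labels from ``group_weights``.  Each kinase is a
    group-model segment in null flanks; when a domain library is supplied,
    one catalytic domain segment plus Poisson(``accessory_rate``) accessory
    segments are appended, positions recorded in the ground truth.
    """
    rng = np.random.default_rng(seed)
    if kinase_groups is None:
        if n_kinases is None:
            n_kinases = 0
        weights = dict(group_weights or DEFAULT_GROUP_WEIGHTS)
        kinase_groups = [_weighted_choice(rng, weights) for _ in range(n_kinases)]
    by_group: dict[str, list[ProfileHMM]] = {}
    for m in group_library.models:
        by_group.setdefault(m.group, []).append(m)
    domain_by_name = {m.name: m for m in (domain_library or [])}
    cat_weights = acc_weights = None
    if domain_library is not None and domain_weights:
        cat_weights = {d: w for d, w in domain_weights.items()
                       if d in CATALYTIC_DOMAINS and w > 0}
        acc_weights = {d: w for d, w in domain_weights.items()
                       if d not in CATALYTIC_DOMAINS and w > 0}

    records: list[ProteinRecord] = []
    labels: dict[str, str] = {}
    domains: dict[str, list[PlantedDomain]] = {}
    counter = 0

    def _next_id() -> str:
        nonlocal counter
        counter += 1
        return f"{id_prefix}{counter:05d}"

    for group in kinase_groups:
        if group not in by_group:
            raise ValueError(f"group {group!r} has no model in the library")
        model = by_group[group][int(rng.integers(0, len(by_group[group])))]
        pid = _next_id()
        parts = [_null_stretch(rng, int(rng.integers(*flank_length)))]
        parts.append(_emit_from_model(rng, model, stochastic_indels))
        planted: list[PlantedDomain] = []
        if cat_weights:
            arch = [_weighted_choice(rng, cat_weights)]
            n_acc = int(rng.poisson(accessory_rate)) if acc_weights else 0
            arch += [_weighted_choice(rng, acc_weights) for _ in range(n_acc)]
            for dom_name in arch:
                parts.append(_null_stretch(rng, int(rng.integers(*spacer_length))))
                seg = _emit_from_model(rng, domain_by_name[dom_name], stochastic_indels)
                start = sum(len(p) for p in parts) + 1
                parts.append(seg)
                planted.append(PlantedDomain(dom_name, start, start + len(seg) - 1))
        parts.append(_null_stretch(rng, int(rng.integers(*flank_length))))
        records.append(ProteinRecord(id=pid, description=f"{pid} planted:{group}",
                                     sequence="".join(parts)))
        labels[pid] = group
        domains[pid] = planted

    for _ in range(n_background):
        pid = _next_id()
        seq = _null_stretch(rng, int(rng.integers(*background_length)))
        records.append(ProteinRecord(id=pid, description=f"{pid} background", sequence=seq))
        labels[pid] = "background"

    return records, GroundTruth(labels=labels, domains=domains)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def make_cohort(
    design: CohortDesign,
    out_dir: str | Path,
    group_library: GroupLibrary | None = None,
    domain_library: Sequence[ProfileHMM] | None = None,
) -> dict:
    """Generate a cohort directory: per-species FASTA + truth JSON, the
    species table, and the toy libraries.  Returns a manifest dict.

    Per species, a true kinome density d is drawn from the clade's normal
    distribution (clipped to [0.05, 5] percent) and converted into a planted
    kinase count against the design's background size.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if group_library is None:
        group_library = make_group_library(seed=[design.seed, 11])
    if domain_library is None:
        domain_library = make_domain_library(seed=[design.seed, 13])
    (out_dir / "libraries" / "group").mkdir(parents=True, exist_ok=True)
    (out_dir / "libraries" / "domain").mkdir(parents=True, exist_ok=True)
    group_library.write_directory(out_dir / "libraries" / "group")
    from .profile_hmm import write_model

    for m in domain_library:
        write_model(m, out_dir / "libraries" / "domain" / f"{m.name}.json")

    species: list[SpeciesRecord] = []
    manifest: dict = {"species": [], "design_seed": design.seed}
    B = design.background_count
    for ci, clade in enumerate(design.clades):
        for si in range(clade.n_species):
            rng = np.random.default_rng([design.seed, 1000 + ci, si])
            abbrev = f"{clade.name.lower()}{si + 1:02d}_syn"
            density = float(np.clip(rng.normal(clade.density_mean, clade.density_sd),
                                    0.05, 5.0))
            n_kin = max(1, round(density * B / (100.0 - density)))
            records, truth = sample_proteome(
                group_library,
                n_background=B,
                n_kinases=n_kin,
                group_weights=clade.group_weights,
                domain_library=domain_library,
                domain_weights=clade.domain_weights,
                accessory_rate=clade.accessory_rate,
                background_length=design.background_length,
                seed=[design.seed, 2000 + ci, si],
                id_prefix=f"{abbrev}_",
            )
            rec = SpeciesRecord(
                name=f"Synthetica {clade.name.lower()} {si + 1}",
                abbreviation=abbrev,
                phylum="Synthophyta",
                subphylum=clade.name,
                clade_label=clade.name,
            )
            species.append(rec)
            write_fasta(records, out_dir / f"{abbrev}.fasta")
            truth_doc = {
                "clade": clade.name,
                "true_density": density,
                "n_planted_kinases": n_kin,
                "proteome_size": len(records),
                **truth.to_json(),
            }
            (out_dir / f"{abbrev}.truth.json").write_text(
                json.dumps(truth_doc, indent=1, sort_keys=True)
            )
            manifest["species"].append(
                {"abbreviation": abbrev, "clade": clade.name,
                 "true_density": density, "n_planted_kinases": n_kin}
            )
    write_species_table(species, out_dir / "species_table.tsv")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
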