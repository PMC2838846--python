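"""Kinase extraction and group classification.

A proteome is scanned with a library of kinase-group profile HMMs covering the
12 groups of the eukaryotic protein kinase superfamily and the atypical
kinases: AGC, Alpha, CAMK, CK1, CMGC, PDHK, PIKK, RGC, RIO, STE, TK, TKL.
Classification uses a fixed bit-score cutoff rather than E-values, so the same
criterion applies to every proteome:

* a protein is called a kinase when its best local Viterbi bit score over the
  whole library is strictly greater than the cutoff (default 20 bits);
* the group of the best-scoring model wins; when a group holds several models
  its score is the maximum over them;
* exact score ties between groups break to the lexicographically smallest
  group name, for determinism;
* there is no fallback "Others" category — proteins under the cutoff are
  simply not part of the kinome (but still count toward proteome size).

The 20-bit default follows the rule of thumb that a hit is likely a true
homologue when its score exceeds log2 of the number of sequences searched;
fungal proteomes put that on the order of 20 bits.  ``recommend_cutoff``
computes the rule for an arbitrary database size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .profile_hmm import ProfileHMM, read_model, score_many, score_proteome
from .proteome_io import ProteinRecord, SpeciesRecord

#: the 12 kinase groups, ePK and atypical, in canonical (alphabetical) order
KINASE_GROUPS = (
    "AGC", "Alpha", "CAMK", "CK1", "CMGC", "PDHK",
    "PIKK", "RGC", "RIO", "STE", "TK", "TKL",
)

DEFAULT_CUTOFF_BITS = 20.0


@dataclass
class GroupLibrary:
    """A kinase-group HMM library: one or more models per represented group."""

    models: list[ProfileHMM]

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("group library is empty")
        for m in self.models:
            if m.group not in KINASE_GROUPS:
                raise ValueError(
                    f"model {m.name!r} has group {m.group!r}, not one of the 12 kinase groups"
                )

    @property
    def groups(self) -> tuple[str, ...]:
        """Represented groups, each listed once, canonical order."""
        present = {m.group for m in self.models}
        return tuple(g for g in KINASE_GROUPS if g in present)

    @classmethod
    def from_directory(cls, path: str | Path) -> "GroupLibrary":
        path = Path(path)
        files = sorted(path.glob("*.json"))
        if not files:
            raise ValueError(f"no model JSON files in {path}")
        return cls(models=[read_model(f) for f in files])

    def write_directory(self, path: str | Path) -> None:
        from .profile_hmm import write_model

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for m in self.models:
            write_model(m, path / f"{m.name}.json")


@dataclass(frozen=True)
class KinaseCall:
    """One protein's classification: winning group, its bit score, and the
    per-group score table (max over each group's models)."""

    protein_id: str
    group: str
    bit_score: float
    all_scores: dict[str, float]


@dataclass
class Kinome:
    """All kinase calls for one species, with the scanned proteome size."""

    species: SpeciesRecord
    calls: list[KinaseCall]
    proteome_size: int

    def __post_init__(self) -> None:
        ids = [c.protein_id for c in self.calls]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate protein ids among kinase calls")
        if not 0 <= len(self.calls) <= self.proteome_size:
            raise ValueError("more calls than proteins scanned")

    def group_counts(self) -> dict[str, int]:
        counts = {g: 0 for g in KINASE_GROUPS}
        for c in self.calls:
            counts[c.group] += 1
        return counts


def group_scores(protein: ProteinRecord, library: GroupLibrary) -> dict[str, float]:
    """Per-group local Viterbi bit scores (max over each group's models)."""
    raw = score_many(library.models, protein, mode="local", algorithm="viterbi")
    best: dict[str, float] = {}
    for model, s in zip(library.models, raw):
        g = model.group
        if g not in best or s > best[g]:
            best[g] = float(s)
    return best


def decide_call(all_scores: Mapping[str, float], cutoff: float) -> tuple[str, float] | None:
    """The fixed-cutoff max-score rule on a per-group score table.

    Returns ``(group, best_score)`` when the best score is strictly greater
    than *cutoff* (the higher HMM wins; exact ties break to the
    lexicographically smallest group name), else None — no fallback category.
    """
    if not all_scores:
        raise ValueError("empty score table")
    best_score = max(all_scores.values())
    if not best_score > cutoff:
        return None
    group = min(g for g, s in all_scores.items() if s == best_score)
    return group, best_score


def classify_protein(
    protein: ProteinRecord,
    library: GroupLibrary,
    cutoff: float = DEFAULT_CUTOFF_BITS,
) -> KinaseCall | None:
    """Classify one protein; returns None (no call) unless the best per-group
    score is strictly greater than *cutoff*."""
    scores = group_scores(protein, library)
    decision = decide_call(scores, cutoff)
    if decision is None:
        return None
    group, best_score = decision
    return KinaseCall(
        protein_id=protein.id, group=group, bit_score=best_score, all_scores=scores
    )


def extract_kinome(
    proteome: Sequence[ProteinRecord],
    species: SpeciesRecord,
    library: GroupLibrary,
    cutoff: float = DEFAULT_CUTOFF_BITS,
) -> Kinome:
    """Scan a whole proteome; calls come back in input order (deterministic)."""
    if not proteome:
        raise ValueError("empty proteome")
    ids = [p.id for p in proteome]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in proteome")
    raw = score_proteome(library.models, proteome)  # (n_proteins, n_models)
    model_groups = [m.group for m in library.models]
    calls = []
    for protein, row in zip(proteome, raw):
        scores: dict[str, float] = {}
        for g, s in zip(model_groups, row):
            if g not in scores or s > scores[g]:
                scores[g] = float(s)
        decision = decide_call(scores, cutoff)
        if decision is not None:
            group, best_score = decision
            calls.append(KinaseCall(protein_id=protein.id, group=group,
                                    bit_score=best_score, all_scores=scores))
    return Kinome(species=species, calls=calls, proteome_size=len(proteome))


def recommend_cutoff(n_sequences: int) -> float:
    """log2 of the target-database size: scores above it are likely true
    homologues (advisory; the pipeline default stays at 20 bits)."""
    if n_sequences < 1:
        raise ValueError("database size must be >= 1")
    return math.log2(n_sequences)


# ---------------------------------------------------------------------------
# report I/O
# ---------------------------------------------------------------------------

def kinome_to_frame(kinome: Kinome) -> pd.DataFrame:
    """Call table: protein_id, group, bit_score, then one score column per group."""
    groups = sorted({g for c in kinome.calls for g in c.all_scores} | set(KINASE_GROUPS),
                    key=KINASE_GROUPS.index)
    rows = []
    for c in kinome.calls:
        row = {"protein_id": c.protein_id, "group": c.group, "bit_score": c.bit_score}
        for g in groups:
            row[g] = c.all_scores.get(g, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows, columns=["protein_id", "group", "bit_score", *groups])


def write_kinome_tsv(kinome: Kinome, path: str | Path) -> None:
    df = kinome_to_frame(kinome)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_kinome_tsv(path: str | Path, species: SpeciesRecord, proteome_size: int) -> Kinome:
    df = pd.read_csv(path, sep="\t")
    score_cols = [c for c in df.columns if c in KINASE_GROUPS]
    calls = [
        KinaseCall(
            protein_id=str(row["protein_id"]),
            group=str(row["group"]),
            bit_score=float(row["bit_score"]),
            all_scores={g: float(row[g]) for g in score_cols if pd.notna(row[g])},
        )
        for _, row in df.iterrows()
    ]
    return Kinome(species=species, calls=calls, proteome_size=proteome_size)


def export_group_fastas(
    kinome: Kinome, proteome: Sequence[ProteinRecord], out_dir: str | Path
) -> dict[str, Path]:
    """Write one FASTA per populated group (input to external tree builders)."""
    from .proteome_io import write_fasta

    by_id = {p.id: p for p in proteome}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for g in KINASE_GROUPS:
        members = [by_id[c.protein_id] for c in kinome.calls if c.group == g]
        if members:
            path = out_dir / f"{kinome.species.abbreviation}_{g}.fasta"
            write_fasta(members, path)
            written[g] = path
    return written
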