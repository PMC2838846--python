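"""Proteome and species-table I/O.

Proteomes are plain protein FASTA files; every downstream stage consumes the
:class:`ProteinRecord` abstraction defined here.  Sequences are normalised on
input: uppercased, ``*`` stop characters stripped, and ambiguity / non-standard
residue codes (B, Z, U, O, J, ``.``) mapped to ``X``.  ``X`` is scored with
null-model probability by the HMM machinery, so predicted proteomes containing
ambiguity codes never crash a scan.

Species metadata (name, abbreviation, phylum, subphylum, clade label) is a
required side input for any cohort-level analysis and travels as a TSV table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

#: the twenty standard amino-acid letters, HMMER column order
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: residue codes normalised to X (ambiguity and rare non-standard letters)
_NONSTANDARD = set("BZUOJ.")

SPECIES_COLUMNS = ("name", "abbreviation", "phylum", "subphylum", "clade_label")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: FASTA id (first whitespace token), description, sequence."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SpeciesRecord:
    """Species metadata row: taxonomy plus the clade label used for colouring
    and for the two-sample density comparisons."""

    name: str
    abbreviation: str
    phylum: str
    subphylum: str
    clade_label: str


def normalize_sequence(raw: str) -> str:
    """Uppercase, drop ``*`` stops and gaps, map non-standard residues to X."""
    out = []
    for ch in raw.upper():
        if ch in ("*", "-", " "):
            continue
        if ch in _NONSTANDARD or ch not in AMINO_ACIDS:
            out.append("X")
        else:
            out.append(ch)
    return "".join(out)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into normalised :class:`ProteinRecord` s.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for an
    empty file, text before the first header, or duplicate ids.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if not stripped:
        raise ValueError(f"{path}: empty FASTA file")
    if not stripped.startswith(">"):
        raise ValueError(f"{path}: sequence data before the first '>' header")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        seq = normalize_sequence(str(rec.seq))
        records.append(ProteinRecord(id=pid, description=rec.description, sequence=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (id + description headers preserved)."""
    lines: list[str] = []
    for r in records:
        header = r.description if r.description.startswith(r.id) else (
            f"{r.id} {r.description}".strip()
        )
        lines.append(f">{header}")
        lines.extend(r.sequence[i: i + width] for i in range(0, len(r.sequence), width))
    Path(path).write_text("\n".join(lines) + "\n")


def load_species_table(path: str | Path) -> list[SpeciesRecord]:
    """Load the species metadata TSV (row order preserved)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"species table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in SPECIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: species table missing column(s) {missing}")
    abbrevs = df["abbreviation"].tolist()
    dupes = {a for a in abbrevs if abbrevs.count(a) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate species abbreviation(s) {sorted(dupes)}")
    return [
        SpeciesRecord(
            name=row["name"],
            abbreviation=row["abbreviation"],
            phylum=row["phylum"],
            subphylum=row["subphylum"],
            clade_label=row["clade_label"],
        )
        for row in df.to_dict("records")
    ]


def write_species_table(records: Sequence[SpeciesRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [[r.name, r.abbreviation, r.phylum, r.subphylum, r.clade_label] for r in records],
        columns=list(SPECIES_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)
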