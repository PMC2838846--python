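"""Domain architecture of predicted kinases.

Proteins already called as kinases are scanned against a domain HMM library
(a PFAM-A-style collection of family models).  Hits whose local Viterbi bit
score exceeds a significance threshold (default 20 bits, same spirit as the
kinase cutoff) are kept, with 1-based inclusive envelope coordinates.

Each hit is partitioned as *catalytic* — one of the seven domain types
annotated to carry kinase enzymatic activity (``CATALYTIC_DOMAINS``) — or
*accessory* (substrate binding, localisation, regulation, ...).  Note that
HATPase_c, despite its ATPase catalytic activity, is an accessory domain
here: it is not a kinase catalytic domain.

Multiple copies of a domain on one protein count as multiple domains; the
scanner finds non-overlapping copies by re-scanning the flanks around each
accepted hit.  Envelopes of *different* domains that overlap by more than
half of the shorter envelope are resolved in favour of the higher score, to
avoid double-counting one region under two related models.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .profile_hmm import ProfileHMM, score_proteome, viterbi_hit
from .proteome_io import ProteinRecord

#: the seven PFAM domain types with kinase catalytic activity
CATALYTIC_DOMAINS = frozenset({
    "Pkinase",
    "Pkinase_C",
    "PI3_PI4_kinase",
    "BCDHK_Adom3",
    "RIO1",
    "Pkinase_Tyr",
    "Alpha_kinase",
})

DEFAULT_DOMAIN_THRESHOLD_BITS = 20.0


@dataclass(frozen=True)
class DomainHit:
    """One significant domain match on one kinase (1-based inclusive envelope)."""

    kinase_id: str
    domain_name: str
    bit_score: float
    start: int
    end: int
    is_catalytic: bool

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad envelope {self.start}..{self.end} on {self.kinase_id}")
        if self.is_catalytic != (self.domain_name in CATALYTIC_DOMAINS):
            raise ValueError(f"is_catalytic flag inconsistent for {self.domain_name}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DomainInventory:
    """All domain hits over a set of kinases, plus corpus-level tallies."""

    hits: list[DomainHit]
    n_kinases: int
    per_type_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counted = Counter(h.domain_name for h in self.hits)
        if not self.per_type_counts:
            self.per_type_counts = dict(counted)
        elif self.hits and dict(counted) != self.per_type_counts:
            raise ValueError("per_type_counts inconsistent with hits")


@dataclass(frozen=True)
class DomainSummary:
    """Corpus-level domain statistics (counts, catalytic/accessory split, means)."""

    total_domains: int
    catalytic_count: int
    accessory_count: int
    mean_domains_per_kinase: float
    mean_catalytic_per_kinase: float
    mean_accessory_per_kinase: float
    n_domain_types: int
    n_catalytic_types: int
    n_accessory_types: int
    singleton_types: tuple[str, ...]

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        """Display rounding of the per-kinase means (1 decimal by default)."""
        return {
            "mean_domains_per_kinase": round(self.mean_domains_per_kinase, ndigits),
            "mean_catalytic_per_kinase": round(self.mean_catalytic_per_kinase, ndigits),
            "mean_accessory_per_kinase": round(self.mean_accessory_per_kinase, ndigits),
        }


def _overlap(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def _scan_one(
    kinase: ProteinRecord, model: ProfileHMM, threshold: float
) -> list[tuple[float, int, int]]:
    """All non-overlapping significant hits of one model on one sequence,
    found greedily best-first with flank re-scanning."""
    hits: list[tuple[float, int, int]] = []
    # segments are 0-based [lo, hi) windows of the sequence still unexplained
    stack = [(0, len(kinase.sequence))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 1:
            continue
        sub = kinase.sequence[lo:hi]
        score, s, e = viterbi_hit(model, sub)
        if score > threshold and s >= 1:
            start, end = lo + s, lo + e  # back to 1-based full-sequence coords
            hits.append((score, start, end))
            stack.append((lo, start - 1))
            stack.append((end, hi))
    return sorted(hits, key=lambda t: t[1])


def scan_domains(
    kinases: Sequence[ProteinRecord],
    domain_library: Sequence[ProfileHMM],
    threshold: float = DEFAULT_DOMAIN_THRESHOLD_BITS,
) -> DomainInventory:
    """Scan kinases against the domain library and build the inventory.

    An empty kinase list yields an empty inventory.  Overlapping hits from
    different models (overlap > 50% of the shorter envelope) keep only the
    higher-scoring one.
    """
    all_hits: list[DomainHit] = []
    whole_scores = score_proteome(list(domain_library), list(kinases)) if kinases else None
    for ki, kinase in enumerate(kinases):
        raw: list[DomainHit] = []
        for mi, model in enumerate(domain_library):
            # a model whose whole-sequence best hit is insignificant cannot
            # yield any significant sub-segment hit either
            if whole_scores[ki, mi] <= threshold:
                continue
            for score, s, e in _scan_one(kinase, model, threshold):
                raw.append(
                    DomainHit(
                        kinase_id=kinase.id,
                        domain_name=model.name,
                        bit_score=score,
                        start=s,
                        end=e,
                        is_catalytic=model.name in CATALYTIC_DOMAINS,
                    )
                )
        # resolve cross-model overlaps, best score first
        kept: list[DomainHit] = []
        for h in sorted(raw, key=lambda h: (-h.bit_score, h.start, h.domain_name)):
            clash = any(
                _overlap(h, k) > 0.5 * min(h.length, k.length) for k in kept
            )
            if not clash:
                kept.append(h)
        all_hits.extend(sorted(kept, key=lambda h: (h.start, h.domain_name)))
    return DomainInventory(hits=all_hits, n_kinases=len(kinases))


def summarize_counts(
    per_type_counts: Mapping[str, int], n_kinases: int
) -> DomainSummary:
    """Summary statistics from per-domain-type counts alone (no positions)."""
    if n_kinases == 0 and sum(per_type_counts.values()) > 0:
        raise ValueError("domains reported for an empty kinase set")
    total = sum(per_type_counts.values())
    catalytic = sum(c for d, c in per_type_counts.items() if d in CATALYTIC_DOMAINS)
    accessory = total - catalytic
    types = [d for d, c in per_type_counts.items() if c > 0]
    n_cat_types = sum(1 for d in types if d in CATALYTIC_DOMAINS)
    singletons = tuple(sorted(d for d in types if per_type_counts[d] == 1))
    denom = n_kinases if n_kinases else 1
    return DomainSummary(
        total_domains=total,
        catalytic_count=catalytic,
        accessory_count=accessory,
        mean_domains_per_kinase=total / denom,
        mean_catalytic_per_kinase=catalytic / denom,
        mean_accessory_per_kinase=accessory / denom,
        n_domain_types=len(types),
        n_catalytic_types=n_cat_types,
        n_accessory_types=len(types) - n_cat_types,
        singleton_types=singletons,
    )


def summarize_domains(inventory: DomainInventory) -> DomainSummary:
    return summarize_counts(inventory.per_type_counts, inventory.n_kinases)


def domain_prevalence(
    inventories: Mapping[str, DomainInventory]
) -> dict[str, float]:
    """Fraction of species carrying >= 1 occurrence of each domain type."""
    if not inventories:
        raise ValueError("no species inventories given")
    n = len(inventories)
    present: Counter[str] = Counter()
    for inv in inventories.values():
        for d, c in inv.per_type_counts.items():
            if c > 0:
                present[d] += 1
    return {d: present[d] / n for d in sorted(present)}


# ---------------------------------------------------------------------------
# report I/O
# ---------------------------------------------------------------------------

def hits_to_frame(inventory: DomainInventory) -> pd.DataFrame:
    return pd.DataFrame(
        [
            [h.kinase_id, h.domain_name, h.bit_score, h.start, h.end, h.is_catalytic]
            for h in inventory.hits
        ],
        columns=["kinase_id", "domain_name", "bit_score", "start", "end", "is_catalytic"],
    )


def write_hits_tsv(inventory: DomainInventory, path: str | Path) -> None:
    hits_to_frame(inventory).to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_summary_json(summary: DomainSummary, path: str | Path) -> None:
    doc = {
        "total_domains": summary.total_domains,
        "catalytic_count": summary.catalytic_count,
        "accessory_count": summary.accessory_count,
        "mean_domains_per_kinase": summary.mean_domains_per_kinase,
        "mean_catalytic_per_kinase": summary.mean_catalytic_per_kinase,
        "mean_accessory_per_kinase": summary.mean_accessory_per_kinase,
        "n_domain_types": summary.n_domain_types,
        "n_catalytic_types": summary.n_catalytic_types,
        "n_accessory_types": summary.n_accessory_types,
        "singleton_types": list(summary.singleton_types),
        "display": summary.rounded(),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
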