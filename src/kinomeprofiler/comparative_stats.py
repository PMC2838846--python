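"""Per-species and cross-species kinome statistics.

For each species the kinome is summarised by group counts over all 12 kinase
groups (structural zeros such as RGC included — their absence is itself a
reportable fact), by normalized frequencies (each group's share of the
species' kinome, in percent, summing to 100), and by *kinome density*: the
number of predicted kinases as a percentage of the number of predicted
proteins in the proteome.

Cross-species, kinome densities of two taxonomic groups are compared with the
unpaired two-sided Wilcoxon rank-sum (Mann-Whitney U) test, exact for small
untied samples and normal-approximated (tie-corrected, continuity-corrected)
otherwise — mirroring R's ``wilcox.test`` switching behaviour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .kinome_classifier import KINASE_GROUPS, Kinome
from .proteome_io import SpeciesRecord

DEFAULT_EXACT_LIMIT = 25


@dataclass
class KinomeSummary:
    """One species' kinome statistics.

    ``no_kinases`` flags the degenerate case of an empty kinome, where the
    normalized frequencies are undefined and reported as zeros.
    """

    species: SpeciesRecord
    group_counts: dict[str, int]
    total_kinases: int
    proteome_size: int
    normalized_freq: dict[str, float]
    kinome_density: float
    no_kinases: bool = False


@dataclass(frozen=True)
class WilcoxonResult:
    U_statistic: float
    p_value: float
    method: Literal["exact", "normal_approx"]
    two_sided: bool = True


def summarize_kinome(kinome: Kinome) -> KinomeSummary:
    """Counts, normalized frequencies (percent of kinome) and density
    (percent of proteome) for one species."""
    if kinome.proteome_size == 0:
        raise ValueError("proteome size is zero")
    counts = kinome.group_counts()
    total = sum(counts.values())
    if total > 0:
        freq = {g: 100.0 * c / total for g, c in counts.items()}
        flag = False
    else:
        freq = {g: 0.0 for g in counts}
        flag = True
    return KinomeSummary(
        species=kinome.species,
        group_counts=counts,
        total_kinases=total,
        proteome_size=kinome.proteome_size,
        normalized_freq=freq,
        kinome_density=100.0 * total / kinome.proteome_size,
        no_kinases=flag,
    )


def cohort_table(
    summaries: Sequence[KinomeSummary],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cohort-level report tables, rows in input (species-table) order.

    Returns ``(counts, frequencies, density, clade_means)``: species × group
    count and percent tables (all 12 groups as columns, plus totals), the
    per-species density/proteome-size table, and mean kinome size per clade.
    """
    if not summaries:
        raise ValueError("no summaries given")
    idx = [s.species.abbreviation for s in summaries]
    counts = pd.DataFrame(
        [[s.group_counts[g] for g in KINASE_GROUPS] for s in summaries],
        index=idx, columns=list(KINASE_GROUPS),
    )
    counts["total_kinases"] = [s.total_kinases for s in summaries]
    freqs = pd.DataFrame(
        [[s.normalized_freq[g] for g in KINASE_GROUPS] for s in summaries],
        index=idx, columns=list(KINASE_GROUPS),
    )
    density = pd.DataFrame(
        {
            "clade_label": [s.species.clade_label for s in summaries],
            "total_kinases": [s.total_kinases for s in summaries],
            "proteome_size": [s.proteome_size for s in summaries],
            "kinome_density": [s.kinome_density for s in summaries],
        },
        index=idx,
    )
    clade_means = (
        density.groupby("clade_label", sort=True)["total_kinases"]
        .mean()
        .rename("mean_kinome_size")
        .to_frame()
    )
    for df in (counts, freqs, density):
        df.index.name = "abbreviation"
    return counts, freqs, density, clade_means


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> WilcoxonResult:
    """Two-sided unpaired Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact p-value (full null distribution of U) when there are no ties and
    both samples have at most *exact_limit* observations; otherwise the
    normal approximation with tie-corrected variance and continuity
    correction.  The degenerate fully-tied case returns p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        # no rank information at all: no evidence of a shift
        return WilcoxonResult(
            U_statistic=float(x.size * y.size / 2.0), p_value=1.0,
            method="normal_approx",
        )
    exact = (not has_ties) and max(x.size, y.size) <= exact_limit
    res = _scipy_stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return WilcoxonResult(
        U_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "normal_approx",
    )


def compare_density(
    summaries: Sequence[KinomeSummary],
    clade_a: str,
    clade_b: str,
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> WilcoxonResult:
    """Wilcoxon rank-sum on kinome densities between two clade labels."""
    xs = [s.kinome_density for s in summaries if s.species.clade_label == clade_a]
    ys = [s.kinome_density for s in summaries if s.species.clade_label == clade_b]
    if not xs or not ys:
        raise ValueError(f"no species for clade {clade_a if not xs else clade_b!r}")
    return wilcoxon_rank_sum(xs, ys, exact_limit=exact_limit)


def write_wilcoxon_json(result: WilcoxonResult, path: str | Path,
                        extra: Mapping[str, object] | None = None) -> None:
    doc = {
        "U_statistic": result.U_statistic,
        "p_value": result.p_value,
        "method": result.method,
        "two_sided": result.two_sided,
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
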