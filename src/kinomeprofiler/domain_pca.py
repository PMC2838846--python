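"""Domain-frequency PCA across species.

Each species is described by the percentage of each domain type among all
domain occurrences in its kinome.  Domain types present in fewer than half of
the species (prevalence filter, threshold configurable) are discarded, and
the surviving species × domain percentage matrix is decomposed by principal
component analysis — eigendecomposition of the covariance of the (centered,
optionally variance-scaled) rows.  Species are then projected onto the first
three components with their clade labels attached, which is where taxonomic
clustering becomes visible.

Because cluster membership is judged by eye in ordination plots, a numeric
surrogate is provided for testing: a silhouette-style separation score in
[-1, 1] comparing within-clade to nearest-other-clade distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .domain_annotator import DomainInventory
from .proteome_io import SpeciesRecord


@dataclass
class DomainFrequencyMatrix:
    """Species × domain-type percentage matrix after the prevalence filter.

    ``zero_species`` flags species with no domains at all (all-zero rows).
    """

    species_ids: list[str]
    domain_names: list[str]
    values: np.ndarray  # (n_species, n_domains), percentages
    zero_species: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.species_ids, columns=self.domain_names)
        df.index.name = "species"
        return df


@dataclass
class PCAResult:
    """Orthonormal loadings (columns), species scores, and the fraction of
    total variance each component explains (descending)."""

    component_loadings: np.ndarray  # (n_features, n_components)
    scores: np.ndarray  # (n_samples, n_components)
    explained_variance_fraction: np.ndarray  # (n_components,)

    @property
    def n_components(self) -> int:
        return self.component_loadings.shape[1]


def build_frequency_matrix(
    inventories: Mapping[str, DomainInventory],
    prevalence_threshold: float = 0.5,
) -> DomainFrequencyMatrix:
    """Per-species domain percentages, filtered to domain types present in at
    least ``ceil(prevalence_threshold * n_species)`` species.

    Cell (s, d) = 100 × count of d in species s / total domain occurrences in
    species s.  Column order: descending pooled count, then name.
    """
    if len(inventories) < 2:
        raise ValueError("need at least 2 species for a frequency matrix")
    species_ids = list(inventories)
    n = len(species_ids)
    need = ceil(prevalence_threshold * n)
    presence: dict[str, int] = {}
    pooled: dict[str, int] = {}
    for inv in inventories.values():
        for d, c in inv.per_type_counts.items():
            if c > 0:
                presence[d] = presence.get(d, 0) + 1
                pooled[d] = pooled.get(d, 0) + c
    kept = [d for d, k in presence.items() if k >= need]
    kept.sort(key=lambda d: (-pooled[d], d))
    values = np.zeros((n, len(kept)))
    zero_species = []
    for i, sid in enumerate(species_ids):
        counts = inventories[sid].per_type_counts
        total = sum(counts.values())
        if total == 0:
            zero_species.append(sid)
            continue
        for j, d in enumerate(kept):
            values[i, j] = 100.0 * counts.get(d, 0) / total
    return DomainFrequencyMatrix(
        species_ids=species_ids, domain_names=kept, values=values,
        zero_species=zero_species,
    )


def pca(
    matrix: DomainFrequencyMatrix | np.ndarray,
    center: bool = True,
    scale: bool = False,
) -> PCAResult:
    """PCA by eigendecomposition of the covariance of the rows.

    Components are ordered by decreasing variance; each component's sign is
    fixed by making its largest-magnitude loading positive, so results do not
    depend on the linear-algebra backend.
    """
    X = matrix.values if isinstance(matrix, DomainFrequencyMatrix) else np.asarray(matrix, float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need a 2-D matrix with >= 2 rows and >= 1 column")
    Xc = X - X.mean(axis=0) if center else X.copy()
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        nonconst = sd > 0
        Xc[:, nonconst] = Xc[:, nonconst] / sd[nonconst]
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    total_var = float(np.trace(cov))
    if total_var <= 0:
        raise ValueError("matrix has no variance; PCA is undefined")
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[pivot, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    return PCAResult(
        component_loadings=eigvec,
        scores=Xc @ eigvec,
        explained_variance_fraction=eigval / total_var,
    )


def project3(
    result: PCAResult,
    matrix: DomainFrequencyMatrix,
    species_table: Sequence[SpeciesRecord],
) -> pd.DataFrame:
    """Species coordinates on PC1..PC3 with clade labels.

    A result with fewer than 3 components is zero-padded (``padded`` column
    flags it).  Raises if the species table does not cover the matrix rows.
    """
    by_abbrev = {s.abbreviation: s for s in species_table}
    missing = [sid for sid in matrix.species_ids if sid not in by_abbrev]
    if missing:
        raise ValueError(f"species missing from the species table: {missing}")
    n = len(matrix.species_ids)
    if result.scores.shape[0] != n:
        raise ValueError("score rows do not match the matrix's species")
    k = result.n_components
    coords = np.zeros((n, 3))
    coords[:, : min(3, k)] = result.scores[:, : min(3, k)]
    df = pd.DataFrame(coords, columns=["PC1", "PC2", "PC3"])
    df.insert(0, "species", matrix.species_ids)
    df["clade_label"] = [by_abbrev[sid].clade_label for sid in matrix.species_ids]
    df.attrs["padded"] = k < 3
    return df


def cluster_separation(coords: np.ndarray, labels: Sequence[str]) -> float:
    """Mean silhouette-style separation of clade clusters in [-1, 1].

    Per point: (nearest-other-clade mean distance − own-clade mean distance)
    divided by the larger of the two; members of singleton clades contribute 0.
    """
    coords = np.asarray(coords, dtype=float)
    labels = list(labels)
    if coords.shape[0] != len(labels):
        raise ValueError("coords and labels differ in length")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need at least two clades")
    dists = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    lab = np.array(labels)
    vals = []
    for i in range(len(labels)):
        own = (lab == lab[i])
        own[i] = False
        if not own.any():
            vals.append(0.0)  # singleton clade
            continue
        a = dists[i, own].mean()
        b = min(dists[i, lab == other].mean() for other in uniq if other != lab[i])
        denom = max(a, b)
        vals.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(vals))


def plot_projection(df: pd.DataFrame, path: str | Path) -> None:
    """Optional 2-D scatter of PC1 vs PC2 coloured by clade (requires
    matplotlib, imported lazily)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for clade, sub in df.groupby("clade_label"):
        ax.scatter(sub["PC1"], sub["PC2"], label=clade, s=30)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
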