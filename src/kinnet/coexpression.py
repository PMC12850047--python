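"""Weighted co-expression network construction and module detection.

The pipeline mirrors the standard weighted correlation-network workflow:
log2(TPM+1) normalisation with a zero-fraction gene filter, soft
thresholding chosen for scale-free topology fit, |Pearson r|^beta
adjacency, topological overlap, average-linkage clustering of 1 - TOM,
and an adaptive dendrogram cut with a minimum module size.

The dendrogram cut is this package's own adaptive-gap variant of dynamic
tree cutting: the cut height is placed in the widest gap between
consecutive merge heights above a floor mapped from ``deep_split``
(higher deep_split -> lower floor -> finer modules).  Clusters smaller
than ``min_module_size`` are relabelled "unassigned".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "AdjacencyGraph",
    "ModulePartition",
    "SoftThresholdResult",
    "preprocess",
    "pick_soft_threshold",
    "adjacency",
    "tom",
    "detect_modules",
]

UNASSIGNED = "unassigned"


@dataclass
class AdjacencyGraph:
    """Symmetric gene x gene adjacency with weights in [0, 1], zero diagonal."""

    weights: pd.DataFrame
    power: float
    mode: str = "unsigned"

    @property
    def genes(self) -> pd.Index:
        return self.weights.index


@dataclass
class ModulePartition:
    """Gene -> module label map ('unassigned' for unclustered genes)."""

    labels: pd.Series
    deep_split: int = 2
    min_module_size: int = 5
    warning: str | None = None

    def module_genes(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    @property
    def modules(self) -> list[str]:
        sizes = self.labels[self.labels != UNASSIGNED].value_counts()
        return list(sizes.index)

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()


@dataclass
class SoftThresholdResult:
    power: int
    table: pd.DataFrame  # columns: power, fit, slope, mean_k
    warning: bool = False


def preprocess(
    study, zero_threshold: float = 0.90
) -> tuple[pd.DataFrame, list[str]]:
    """log2(TPM+1)-transform a study and drop near-silent genes.

    Genes whose fraction of zero TPM values across all samples is >=
    ``zero_threshold`` are removed.  Returns the transformed gene x sample
    matrix and the list of removed genes.
    """
    tpm = study.matrix if hasattr(study, "matrix") else study
    zero_frac = (tpm.values == 0).mean(axis=1)
    removed = list(tpm.index[zero_frac >= zero_threshold])
    kept = tpm.drop(index=removed)
    if kept.shape[0] == 0:
        raise ValueError("no genes left after the zero-fraction filter")
    return np.log2(kept + 1.0), removed


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit index for a connectivity vector.

    Bins connectivities into ``n_bins`` equal-count bins, regresses the
    log10 connectivity density (bin frequency / bin width) on log10 mean
    connectivity, and returns (-sign(slope) * R^2, slope).  Equal-count
    bins need the density correction: raw per-bin frequencies are flat by
    construction.
    """
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0, 0.0
    qs = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    qs = np.unique(qs)
    if qs.size < 4:
        return 0.0, 0.0
    idx = np.clip(np.searchsorted(qs, k, side="right") - 1, 0, qs.size - 2)
    bins = [b for b in range(qs.size - 1) if np.any(idx == b)]
    mean_k = np.array([k[idx == b].mean() for b in bins])
    width = np.array([qs[b + 1] - qs[b] for b in bins])
    freq = np.array([np.mean(idx == b) for b in bins])
    ok = (mean_k > 0) & (freq > 0) & (width > 0)
    if ok.sum() < 3:
        return 0.0, 0.0
    lx, ly = np.log10(mean_k[ok]), np.log10(freq[ok] / width[ok])
    slope, intercept = np.polyfit(lx, ly, 1)
    ss_res = np.sum((ly - (slope * lx + intercept)) ** 2)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(-np.sign(slope) * r2), float(slope)


def pick_soft_threshold(
    log_matrix: pd.DataFrame,
    candidate_powers: Sequence[int] = tuple(range(1, 21)),
    fit_threshold: float = 0.7,
    plateau_tol: float = 0.02,
    mode: str = "unsigned",
    n_bins: int = 10,
) -> SoftThresholdResult:
    """Choose the soft-thresholding power by scale-free topology fit.

    Returns the smallest candidate power whose signed fit index reaches
    ``fit_threshold`` and lies within ``plateau_tol`` of the plateau
    maximum; if no power reaches the threshold the argmax is returned
    with a warning flag.
    """
    if log_matrix.shape[1] < 8:
        raise ValueError("need >= 8 samples for soft-threshold selection")
    powers = [int(p) for p in candidate_powers]
    if not powers or any(p < 1 for p in powers):
        raise ValueError("candidate powers must be positive integers")

    cor = np.corrcoef(log_matrix.values)
    np.fill_diagonal(cor, 0.0)
    base = np.abs(cor) if mode == "unsigned" else (1.0 + cor) / 2.0

    rows = []
    for p in powers:
        a = base**p
        k = a.sum(axis=1)
        fit, slope = _scale_free_fit(k, n_bins=n_bins)
        rows.append((p, fit, slope, float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "fit", "slope", "mean_k"])

    fits = table["fit"].values
    plateau = float(fits.max())
    ok = (fits >= fit_threshold) & (fits >= plateau - plateau_tol)
    if ok.any():
        power = int(table.loc[np.flatnonzero(ok)[0], "power"])
        warn = False
    else:
        power = int(table.loc[int(np.argmax(fits)), "power"])
        warn = True
        warnings.warn(
            f"no candidate power reached scale-free fit {fit_threshold}; "
            f"returning argmax power {power}"
        )
    return SoftThresholdResult(power=power, table=table, warning=warn)


def adjacency(
    log_matrix: pd.DataFrame, power: float, mode: str = "unsigned"
) -> AdjacencyGraph:
    """Soft-thresholded correlation adjacency a_ij = |cor(g_i,g_j)|^beta.

    ``signed`` mode uses ((1+cor)/2)^beta.  Zero-variance genes have no
    defined correlation and are dropped with a warning.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    sd = log_matrix.values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(log_matrix.index[~keep])
        warnings.warn(f"dropping {len(dropped)} zero-variance gene(s)")
        log_matrix = log_matrix.loc[keep]
    cor = np.corrcoef(log_matrix.values)
    a = np.abs(cor) ** power if mode == "unsigned" else ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(a, 0.0)
    a = (a + a.T) / 2.0  # enforce exact symmetry
    return AdjacencyGraph(
        weights=pd.DataFrame(a, index=log_matrix.index, columns=log_matrix.index),
        power=power,
        mode=mode,
    )


def tom(adj: AdjacencyGraph) -> pd.DataFrame:
    """Topological overlap similarity.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    k_i the connectivity of gene i; diagonal set to 1.
    """
    a = adj.weights.values
    shared = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (shared + a) / denom
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(t, index=adj.genes, columns=adj.genes)


_DEEP_SPLIT_FLOOR = {0: 0.95, 1: 0.90, 2: 0.80, 3: 0.70, 4: 0.60}


def detect_modules(
    tom_matrix: pd.DataFrame,
    deep_split: int = 2,
    min_module_size: int = 5,
) -> ModulePartition:
    """Cluster genes into modules from a TOM similarity matrix.

    Average-linkage hierarchical clustering on 1 - TOM, cut at the widest
    gap in merge heights above a ``deep_split``-dependent floor (fraction
    of the merge-height range); clusters below ``min_module_size`` become
    "unassigned".  Module labels M1, M2, ... are ordered by size.
    """
    if deep_split not in _DEEP_SPLIT_FLOOR:
        raise ValueError("deep_split must be in 0..4")
    genes = tom_matrix.index
    n = len(genes)
    if n < min_module_size:
        raise ValueError("fewer genes than min_module_size")

    d = 1.0 - tom_matrix.values
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    heights = z[:, 2]

    warning = None
    if np.ptp(heights) < 1e-12:
        warnings.warn("degenerate dissimilarity; returning a single module")
        warning = "degenerate dissimilarity"
        raw = np.ones(n, dtype=int)
    else:
        h_sorted = np.sort(heights)
        floor = h_sorted[0] + _DEEP_SPLIT_FLOOR[deep_split] * (h_sorted[-1] - h_sorted[0])
        upper = h_sorted[h_sorted >= floor]
        # candidate cut points: gaps between consecutive merges above the
        # floor, plus the gap between the floor region and the merge below it
        below = h_sorted[h_sorted < floor]
        lowers = np.concatenate([[below[-1]] if below.size else [h_sorted[0]], upper[:-1]])
        gaps = upper - lowers
        order = np.argsort(-gaps, kind="mergesort")[: min(20, gaps.size)]
        # among the widest gaps, cut where the fewest genes end up in
        # sub-minimum clusters; ties break toward the wider gap
        best = None
        for i in order:
            if gaps[i] <= 0:
                continue
            cut = (lowers[i] + upper[i]) / 2.0
            cand = hierarchy.fcluster(z, t=cut, criterion="distance")
            sizes = np.bincount(cand)
            n_unassigned = int(sizes[sizes < min_module_size].sum())
            key = (n_unassigned, -gaps[i])
            if best is None or key < best[0]:
                best = (key, cand)
        raw = best[1]

    labels = pd.Series(raw, index=genes).astype(object)
    counts = labels.value_counts()
    small = counts.index[counts < min_module_size]
    labels[labels.isin(small)] = UNASSIGNED
    kept = [c for c in counts.index if c not in set(small)]
    kept.sort(key=lambda c: (-counts[c], c))
    rename = {c: f"M{i + 1}" for i, c in enumerate(kept)}
    labels = labels.map(lambda c: rename.get(c, UNASSIGNED))
    if not (labels != UNASSIGNED).any():
        warnings.warn("all clusters below min_module_size; everything unassigned")
        warning = warning or "no module met min_module_size"
    return ModulePartition(
        labels=labels, deep_split=deep_split,
        min_module_size=min_module_size, warning=warning,
    )
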