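"""Region-wise tumor vs normal fold changes and module-level contrasts.

Per gene and tumor region (inner core IC, invasive front IF, metastasis
M) the log2 fold change against matched normal tissue is
log2((mean TPM_tumor + c) / (mean TPM_normal + c)) with pseudocount c;
module distributions are summarised by five-number (boxplot) statistics
and regions compared with a paired two-sided Wilcoxon signed-rank test,
pairing genes of the same module across regions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import UNASSIGNED, ModulePartition
from .simulate import NORMAL_LABEL, TUMOR_REGIONS, ExpressionStudy

__all__ = [
    "RegionComparison",
    "compute_log2fc",
    "module_region_summary",
    "compare_regions",
    "spearman_correlation",
]


@dataclass
class RegionComparison:
    module: str
    region_a: str
    region_b: str
    statistic: float
    pvalue: float
    n: int
    summaries: Mapping[str, tuple[float, float, float, float, float]]
    flag: str | None = None


def compute_log2fc(
    study: ExpressionStudy,
    pseudocount: float = 1.0,
    per_patient: bool = False,
    regions: Sequence[str] = TUMOR_REGIONS,
) -> pd.DataFrame:
    """Per-gene, per-region log2(tumor/normal) fold changes.

    Default aggregation pools samples: mean TPM over a region's tumor
    samples vs mean TPM over normal samples.  ``per_patient`` instead
    computes the fold change within each patient carrying both samples
    and takes the median across patients.  Returns a long frame with
    columns ``gene, region, log2fc``.
    """
    meta = study.meta.set_index("sample_id")
    mat = study.matrix
    normal_samples = meta.index[meta["region"] == NORMAL_LABEL]
    if len(normal_samples) == 0:
        raise ValueError("no normal samples present")

    out = []
    for region in regions:
        tumor_samples = meta.index[meta["region"] == region]
        if len(tumor_samples) == 0:
            raise ValueError(f"region {region!r} has no samples")
        if per_patient:
            fcs = []
            for patient, grp in meta.groupby("patient_id"):
                ts = grp.index[grp["region"] == region]
                ns = grp.index[grp["region"] == NORMAL_LABEL]
                if len(ts) == 0 or len(ns) == 0:
                    continue
                t = mat[ts].mean(axis=1)
                n = mat[ns].mean(axis=1)
                fcs.append(np.log2((t + pseudocount) / (n + pseudocount)))
            if not fcs:
                raise ValueError(f"no patient has both {region!r} and normal samples")
            fc = pd.concat(fcs, axis=1).median(axis=1)
        else:
            t = mat[tumor_samples].mean(axis=1)
            n = mat[normal_samples].mean(axis=1)
            fc = np.log2((t + pseudocount) / (n + pseudocount))
        out.append(pd.DataFrame({"gene": mat.index, "region": region, "log2fc": fc.values}))
    return pd.concat(out, ignore_index=True)


def _five_number(values: np.ndarray) -> tuple[float, float, float, float, float]:
    # linear-interpolation quartiles (boxplot convention)
    q = np.percentile(values, [0, 25, 50, 75, 100], method="linear")
    return tuple(float(v) for v in q)


def module_region_summary(
    fc: pd.DataFrame, part: ModulePartition
) -> pd.DataFrame:
    """Five-number summaries of member-gene log2FC per module and region.

    Returns columns ``module, region, n_genes, min, q1, median, q3, max,
    flag`` (flag set for modules with fewer than two genes).
    """
    rows = []
    for module in part.modules:
        genes = set(part.module_genes(module))
        sub = fc[fc["gene"].isin(genes)]
        if sub.empty:
            continue
        for region, grp in sub.groupby("region", sort=True):
            vals = grp["log2fc"].values
            rows.append(
                (module, region, vals.size, *_five_number(vals),
                 "too_few_genes" if vals.size < 2 else None)
            )
    if not rows:
        raise ValueError("no module genes present in the fold-change table")
    return pd.DataFrame(
        rows,
        columns=["module", "region", "n_genes", "min", "q1", "median", "q3", "max", "flag"],
    )


def compare_regions(
    fc: pd.DataFrame,
    part: ModulePartition,
    region_a: str,
    region_b: str,
    module: str,
    exact_max_n: int = 25,
) -> RegionComparison:
    """Paired Wilcoxon signed-rank contrast of a module between two regions.

    Member genes are the pairing unit; zero differences are dropped
    (Wilcoxon convention).  The exact null distribution is used for n <=
    ``exact_max_n`` pairs, the normal approximation with continuity
    correction above.
    """
    genes = part.module_genes(module)
    if not genes:
        raise ValueError(f"module {module!r} has no genes")
    wide = fc[fc["gene"].isin(set(genes))].pivot(index="gene", columns="region", values="log2fc")
    for r in (region_a, region_b):
        if r not in wide.columns:
            raise ValueError(f"region {r!r} missing from fold-change table")
    wide = wide.dropna(subset=[region_a, region_b])
    a, b = wide[region_a].values, wide[region_b].values
    d = a - b
    nz = d != 0
    summaries = {region_a: _five_number(a), region_b: _five_number(b)}

    if not nz.any():
        return RegionComparison(
            module=module, region_a=region_a, region_b=region_b,
            statistic=0.0, pvalue=1.0, n=0, summaries=summaries,
            flag="all_differences_zero",
        )
    n = int(nz.sum())
    if n <= exact_max_n:
        res = stats.wilcoxon(a[nz], b[nz], zero_method="wilcox", method="exact",
                             alternative="two-sided")
    else:
        res = stats.wilcoxon(a[nz], b[nz], zero_method="wilcox", method="approx",
                             correction=True, alternative="two-sided")
    return RegionComparison(
        module=module, region_a=region_a, region_b=region_b,
        statistic=float(res.statistic), pvalue=float(res.pvalue), n=n,
        summaries=summaries,
    )


def _exact_spearman_p(rho: float, n: int) -> float:
    """Two-sided exact p for Spearman's rho under the permutation null.

    Enumerates all n! rank permutations (no ties); feasible for n <= 9.
    """
    ranks = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(itertools.permutations(range(n))))
    ry = ranks[perms]
    rx = ranks
    # rho for each permutation via the d^2 formula (valid without ties)
    d2 = ((rx[None, :] - ry) ** 2).sum(axis=1)
    rhos = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    p-value is exact (full permutation null) for n <= 9 without ties,
    otherwise the t-distribution approximation.  Constant input is
    undefined: returns (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 paired finite observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input; Spearman correlation undefined")
        return (float("nan"), float("nan"))
    rho = float(stats.spearmanr(x, y).statistic)
    n = x.size
    has_ties = (np.unique(x).size < n) or (np.unique(y).size < n)
    if n <= 9 and not has_ties:
        p = _exact_spearman_p(rho, n)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p
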