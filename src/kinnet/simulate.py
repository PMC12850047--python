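"""Synthetic data generators for the kinetics and co-expression analyses.

Every generator draws from the same parametric models the fitting code
assumes, so simulate -> fit round trips have a known ground truth.  All
randomness flows through a single integer seed per call; fixed seed means
bit-identical output.

Kinetics side: initial-rate grids over substrate (PEP) x allosteric
effector (FBP or GSH) concentrations from the thermodynamic-linkage model,
linear NADH-depletion absorbance traces, hyperbolic activation
dose-response curves, and one-site binding isotherms.

Expression side: a bulk RNA-seq-like gene x sample TPM matrix with paired
tumor regions (inner core IC, invasive front IF, metastasis M) and matched
normals per patient, planted co-expression modules sharing a latent
factor, optional inter-module factor coupling, region-specific log2 shifts
in tumor samples, and zero inflation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KineticsSimConfig",
    "ModuleSpec",
    "ExpressionSimConfig",
    "PlantedTruth",
    "ExpressionStudy",
    "linkage_ka",
    "linkage_rate",
    "gen_rate_grid",
    "gen_progress_curve",
    "gen_dose_response",
    "gen_binding_curve",
    "gen_expression",
]

TUMOR_REGIONS = ("IC", "IF", "M")
NORMAL_LABEL = "N"


# ---------------------------------------------------------------------------
# kinetics generators
# ---------------------------------------------------------------------------

def linkage_ka(x, k_ia0: float, k_ix0: float, q_ax: float):
    """Apparent substrate affinity K_a at effector concentration ``x``.

    K_a(x) = K_ia0 * (K_ix0 + x) / (K_ix0 + Q_ax * x).  At x = 0 this is
    K_ia0; as x -> inf it tends to K_ia0 / Q_ax, so the ratio of the
    initial to final K_a is the coupling constant Q_ax.
    """
    x = np.asarray(x, dtype=float)
    return k_ia0 * (k_ix0 + x) / (k_ix0 + q_ax * x)


def linkage_rate(s, x, v_max: float, k_ia0: float, k_ix0: float, q_ax: float):
    """Initial rate v(S, X) = V_max * S / (K_a(X) + S)."""
    s = np.asarray(s, dtype=float)
    return v_max * s / (linkage_ka(x, k_ia0, k_ix0, q_ax) + s)


@dataclass(frozen=True)
class KineticsSimConfig:
    """Generating parameters for a rate grid over substrate x effector.

    Units follow assay convention: substrate (PEP) in mM, effector in µM,
    v_max in arbitrary rate units. ``noise_cv`` is the fractional
    (multiplicative Gaussian) coefficient of variation per measurement.
    """

    v_max: float = 2.0
    k_ia0: float = 1.5
    k_ix0: float = 10.0
    q_ax: float = 4.0
    pep_grid: Sequence[float] = (0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4)
    effector_grid: Sequence[float] = (0.0, 3.0, 10.0, 30.0, 100.0, 300.0)
    noise_cv: float = 0.05
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        vals = [self.v_max, self.k_ia0, self.k_ix0, self.q_ax, self.noise_cv]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("kinetic parameters must be finite")
        if min(self.v_max, self.k_ia0, self.k_ix0) <= 0 or self.q_ax <= 0:
            raise ValueError("v_max, k_ia0, k_ix0 and q_ax must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(c < 0 for c in self.pep_grid) or any(c < 0 for c in self.effector_grid):
            raise ValueError("concentrations must be >= 0")


def gen_rate_grid(cfg: KineticsSimConfig) -> pd.DataFrame:
    """Simulate an initial-rate table over the full substrate x effector grid.

    Returns a long-format frame with columns ``effector_conc, pep_conc,
    replicate, rate`` where rate = v_true * (1 + eps), eps ~ N(0, cv^2).
    """
    rng = np.random.default_rng(cfg.seed)
    recs = []
    for x in cfg.effector_grid:
        for s in cfg.pep_grid:
            v = float(linkage_rate(s, x, cfg.v_max, cfg.k_ia0, cfg.k_ix0, cfg.q_ax))
            eps = rng.normal(0.0, cfg.noise_cv, size=cfg.replicates) if cfg.noise_cv > 0 else np.zeros(cfg.replicates)
            for r in range(cfg.replicates):
                recs.append((x, s, r, v * (1.0 + eps[r])))
    return pd.DataFrame(recs, columns=["effector_conc", "pep_conc", "replicate", "rate"])


def gen_progress_curve(
    initial_od: float = 1.0,
    rate: float = 0.01,
    duration: float = 10.0,
    n_points: int = 601,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an NADH-consumption absorbance trace od(t) = od0 - rate*t.

    ``rate`` is the absorbance decrease per minute (>= 0, the coupled
    reaction consumes NADH); additive Gaussian noise; values clipped at 0.
    Returns columns ``time_min, od340``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate < 0:
        raise ValueError("rate must be >= 0 (absorbance decreases)")
    if n_points < 2:
        raise ValueError("need at least 2 points")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_points)
    od = initial_od - rate * t
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=t.size)
    od = np.clip(od, 0.0, None)
    return pd.DataFrame({"time_min": t, "od340": od})


def gen_dose_response(
    a0: float,
    a_max: float,
    ac50: float,
    hill: float,
    conc_grid: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate activity vs activator concentration.

    A(X) = a0 + (a_max - a0) * X^h / (AC50^h + X^h), multiplicative
    Gaussian noise at ``noise_cv``.  Returns columns ``conc, activity``.
    """
    if ac50 <= 0 or hill <= 0:
        raise ValueError("ac50 and hill must be positive")
    conc = np.asarray(conc_grid, dtype=float)
    if conc.size == 0:
        raise ValueError("empty concentration grid")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    with np.errstate(divide="ignore"):
        frac = np.where(conc > 0, conc**hill / (ac50**hill + conc**hill), 0.0)
    a = a0 + (a_max - a0) * frac
    if noise_cv > 0:
        a = a * (1.0 + rng.normal(0.0, noise_cv, size=conc.size))
    return pd.DataFrame({"conc": conc, "activity": a})


def gen_binding_curve(
    b_max: float,
    k_d: float,
    conc_series: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    include_zero_control: bool = True,
) -> pd.DataFrame:
    """Simulate a one-site binding isotherm y(L) = B_max*L/(K_d+L) + noise.

    ``conc_series`` are strictly positive ligand concentrations; a zero
    control is appended unless already present or disabled.  Additive
    Gaussian noise of SD ``noise_sd`` (same units as the signal).
    """
    if k_d <= 0:
        raise ValueError("k_d must be positive")
    conc = np.asarray(conc_series, dtype=float)
    if conc.size == 0:
        raise ValueError("empty concentration series")
    if np.any(conc[conc != 0] <= 0):
        raise ValueError("ligand concentrations must be positive (plus a zero control)")
    if include_zero_control and not np.any(conc == 0):
        conc = np.concatenate([conc, [0.0]])
    rng = np.random.default_rng(seed)
    y = b_max * conc / (k_d + conc)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=conc.size)
    return pd.DataFrame({"conc": conc, "signal": y})


# ---------------------------------------------------------------------------
# expression generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    ``within_cor`` is the target pairwise Pearson correlation of member
    genes on the log2 scale (before zero inflation); ``shifts`` maps a
    tumor region label to the log2 fold-change added to that region's
    tumor samples relative to normals.
    """

    size: int
    within_cor: float = 0.8
    shifts: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("module size must be >= 1")
        if not 0.0 <= self.within_cor < 1.0 + 1e-12:
            raise ValueError("within_cor must be in [0, 1]")


@dataclass(frozen=True)
class ExpressionSimConfig:
    n_genes: int = 300
    n_patients: int = 21
    regions: Sequence[str] = TUMOR_REGIONS
    module_spec: Sequence[ModuleSpec] = ()
    coupling_spec: Sequence[tuple[tuple[int, int], float]] = ()
    zero_fraction: float = 0.0
    gene_zero_fraction: Sequence[float] | None = None  # per-gene override
    noise_sd: float = 0.0
    base_mean: float = 4.0
    base_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(m.size for m in self.module_spec) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if not 0.0 <= self.zero_fraction < 1.0:
            raise ValueError("zero_fraction must be in [0, 1)")
        if self.gene_zero_fraction is not None:
            gz = np.asarray(self.gene_zero_fraction, dtype=float)
            if gz.size != self.n_genes or np.any(gz < 0) or np.any(gz > 1):
                raise ValueError("gene_zero_fraction must be n_genes values in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        k = len(self.module_spec)
        for (i, j), c in self.coupling_spec:
            if not (0 <= i < k and 0 <= j < k and i != j):
                raise ValueError("coupling_spec indexes invalid module pair")
            if not 0.0 <= c < 1.0:
                raise ValueError("cross-correlation must be in [0, 1)")
        for m in self.module_spec:
            for r in m.shifts:
                if r not in self.regions:
                    raise ValueError(f"shift region {r!r} not in regions")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a simulated expression study."""

    modules: Mapping[str, str]          # gene -> module label ("unassigned" for background)
    shifts: Mapping[str, Mapping[str, float]]   # module label -> region -> log2 shift
    coupled_pairs: Sequence[tuple[str, str, float]]  # (module_a, module_b, cross_cor)


@dataclass
class ExpressionStudy:
    """A TPM-scale gene x sample matrix plus sample metadata.

    ``matrix``: genes as rows, samples as columns, non-negative TPM.
    ``meta``: one row per sample with sample_id, patient_id and region in
    {IC, IF, M, N} (N = matched normal).
    """

    matrix: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.matrix.values < 0).any():
            raise ValueError("TPM matrix must be non-negative")
        if not set(self.matrix.columns) <= set(self.meta["sample_id"]):
            raise ValueError("metadata must cover all samples")


def _module_labels(k: int) -> list[str]:
    return [f"M{i + 1}" for i in range(k)]


def gen_expression(cfg: ExpressionSimConfig) -> tuple[ExpressionStudy, PlantedTruth]:
    """Simulate a paired tumor/normal regional expression study.

    Per patient: one tumor sample per region plus one matched normal.
    Module genes share a latent per-sample factor so that the pairwise
    log2-scale correlation equals ``within_cor``; coupled module pairs
    share correlated factors; region shifts are added on the log2 scale to
    tumor samples only; values are mapped back to TPM via max(2^x - 1, 0)
    and zeros injected uniformly at ``zero_fraction``.
    """
    rng = np.random.default_rng(cfg.seed)
    regions = list(cfg.regions)
    patients = [f"P{i + 1:02d}" for i in range(cfg.n_patients)]
    samples, sample_patient, sample_region = [], [], []
    for p in patients:
        for r in regions + [NORMAL_LABEL]:
            samples.append(f"{p}_{r}")
            sample_patient.append(p)
            sample_region.append(r)
    n_s = len(samples)

    k = len(cfg.module_spec)
    labels = _module_labels(k)
    # latent module factors, with configured cross-correlations
    factors = rng.standard_normal((k, n_s))
    for (i, j), c in cfg.coupling_spec:
        factors[j] = c * factors[i] + math.sqrt(1.0 - c * c) * factors[j]

    genes, rows, gene_module = [], [], {}
    gi = 0
    for mi, spec in enumerate(cfg.module_spec):
        r = spec.within_cor
        for _ in range(spec.size):
            g = f"G{gi + 1:05d}"
            mu = rng.normal(cfg.base_mean, cfg.base_sd)
            eps = rng.standard_normal(n_s)
            x = mu + math.sqrt(r) * factors[mi] + math.sqrt(max(0.0, 1.0 - r)) * eps
            genes.append(g)
            rows.append(x)
            gene_module[g] = labels[mi]
            gi += 1
    for _ in range(cfg.n_genes - gi):
        g = f"G{gi + 1:05d}"
        mu = rng.normal(cfg.base_mean, cfg.base_sd)
        genes.append(g)
        rows.append(mu + rng.standard_normal(n_s))
        gene_module[g] = "unassigned"
        gi += 1

    log2 = np.asarray(rows)
    if cfg.noise_sd > 0:
        log2 = log2 + rng.normal(0.0, cfg.noise_sd, size=log2.shape)

    # region-specific tumor shifts, log2 scale
    region_arr = np.asarray(sample_region)
    for mi, spec in enumerate(cfg.module_spec):
        if not spec.shifts:
            continue
        in_mod = np.asarray([gene_module[g] == labels[mi] for g in genes])
        for r, shift in spec.shifts.items():
            log2[np.ix_(in_mod, region_arr == r)] += shift

    tpm = np.maximum(np.exp2(log2) - 1.0, 0.0)
    if cfg.gene_zero_fraction is not None:
        gz = np.asarray(cfg.gene_zero_fraction, dtype=float)[:, None]
        tpm[rng.random(tpm.shape) < gz] = 0.0
    elif cfg.zero_fraction > 0:
        tpm[rng.random(tpm.shape) < cfg.zero_fraction] = 0.0

    matrix = pd.DataFrame(tpm, index=genes, columns=samples)
    meta = pd.DataFrame(
        {"sample_id": samples, "patient_id": sample_patient, "region": sample_region}
    )
    truth = PlantedTruth(
        modules=gene_module,
        shifts={labels[i]: dict(cfg.module_spec[i].shifts) for i in range(k)},
        coupled_pairs=[(labels[i], labels[j], c) for (i, j), c in cfg.coupling_spec],
    )
    return ExpressionStudy(matrix=matrix, meta=meta), truth
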