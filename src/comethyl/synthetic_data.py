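"""Synthetic 450K-like methylation datasets with planted structure.

The generator emulates the statistical skeleton of a methylation-array cohort
study: promoters carry latent-factor-driven co-methylation modules on the M
(logit) scale, a subset of promoters carries a case/control mean shift, each
promoter spans on average 17 CpG positions, and every position is rendered as
a pair of methylated/unmethylated channel intensities so the β = M/(M+U+α)
conversion is exercised end to end.

Generative model (per sample s):

* module factor  ``F_k(s) ~ N(0, 1)``, standardized to exactly unit sample
  variance;
* promoter r in module k: ``m_r(s) = b_r + u_r·F_k(s) + δ_r·1[s case] + e_r(s)``
  with baseline ``b_r ~ N(0, baseline_sd)``, loading ``u_r ~ U(loading_range)``
  and noise ``e_r ~ N(0, noise_sd)``; null promoters omit the factor term;
* position j of promoter r: ``M_rj(s) = m_r(s) + c_j + ε_rj(s)`` with a fixed
  per-position offset ``c_j ~ N(0, position_sd)`` and position noise
  ``ε_rj ~ N(0, position_sd)``;
* ``β = 2^M / (1 + 2^M)``; total intensity ``T ~ LogNormal`` (median
  ``intensity_median``, log-sd ``intensity_log_sd``); ``M_int = β·T``,
  ``U_int = (1 − β)·T``.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    GeneSetCollection,
    ProbeAnnotation,
    SampleSheet,
    SignalIntensities,
    write_tables,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_dataset",
    "simulate_intensities",
    "simulate_power_law_profiles",
    "simulate_gene_sets",
    "export_ground_truth",
]


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults echo the cohort layout (15 cases vs
    20 tolerant controls, ~17 CpG positions per promoter)."""

    seed: int
    n_case: int = 15
    n_control: int = 20
    n_promoters: int = 300
    n_modules: int = 3
    module_sizes: tuple[int, ...] | None = None  # default: modules cover 60% of promoters
    positions_per_promoter: float = 17.0  # mean of 1 + Poisson(mean − 1)
    loading_range: tuple[float, float] = (0.5, 0.9)
    baseline_sd: float = 1.0
    position_sd: float = 0.3
    noise_sd: float = 0.5
    n_differential: int = 0
    effect_delta: float = 1.0  # case-group shift on the M scale
    intensity_median: float = 5000.0
    intensity_log_sd: float = 0.3
    alpha: float = 100.0

    def __post_init__(self) -> None:
        if self.module_sizes is None and self.n_modules:
            # equal sizes, modules jointly spanning ~60% of promoters
            size = max(1, int(0.6 * self.n_promoters / self.n_modules))
            self.module_sizes = tuple([size] * self.n_modules)
        elif self.module_sizes is None:
            self.module_sizes = ()
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes must list one size per module")
        if sum(self.module_sizes) > self.n_promoters:
            raise ValueError("module sizes exceed the number of promoters")
        if min(self.n_case, self.n_control) < 2:
            raise ValueError("need at least 2 samples per group")
        for name in ("baseline_sd", "position_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.n_differential <= self.n_promoters:
            raise ValueError("n_differential must lie in [0, n_promoters]")
        if self.positions_per_promoter < 1:
            raise ValueError("positions_per_promoter must be ≥ 1")
        lo, hi = self.loading_range
        if not 0 < lo <= hi:
            raise ValueError("loading_range must satisfy 0 < lo ≤ hi")


@dataclass
class GroundTruth:
    """Planted structure: module labels (0 = null), per-sample factors,
    loadings, and which promoters carry the case shift."""

    promoter_module: pd.Series  # promoter_id → module index (0 = null)
    factors: pd.DataFrame  # samples × modules, exactly unit sample variance
    loadings: pd.Series  # promoter_id → u_r (0 for null promoters)
    differential: pd.Series  # promoter_id → true δ (0 if not planted)

    def __post_init__(self) -> None:
        if not self.promoter_module.index.equals(self.loadings.index):
            raise ValueError("loadings must cover all promoters")
        if not self.promoter_module.index.equals(self.differential.index):
            raise ValueError("differential flags must cover all promoters")

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.promoter_module) - {0})

    def members(self, module: int) -> list[str]:
        return list(self.promoter_module.index[self.promoter_module == module])


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def simulate_intensities(
    beta_true: np.ndarray, total_T: np.ndarray, alpha: float = 100.0
) -> tuple[np.ndarray, np.ndarray]:
    """Split total intensity into channels: M_int = β·T, U_int = (1−β)·T.

    Recomputing β through M/(M+U+α) then converges to ``beta_true`` as the
    total intensity grows relative to α.
    """
    beta_true = np.asarray(beta_true, dtype=float)
    total_T = np.broadcast_to(np.asarray(total_T, dtype=float), beta_true.shape)
    if (beta_true < 0).any() or (beta_true > 1).any():
        raise ValueError("beta_true must lie in [0, 1]")
    if (total_T <= 0).any():
        raise ValueError("total intensity must be positive")
    return beta_true * total_T, (1.0 - beta_true) * total_T


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[SampleSheet, SignalIntensities, ProbeAnnotation, GroundTruth]:
    """Draw one synthetic cohort dataset from the generative model above."""
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_case + config.n_control
    sample_ids = [f"case_{i + 1:02d}" for i in range(config.n_case)] + [
        f"ctrl_{i + 1:02d}" for i in range(config.n_control)
    ]
    is_case = np.array([s.startswith("case") for s in sample_ids])
    sheet = SampleSheet(
        pd.DataFrame(
            {"group": np.where(is_case, "case", "control")}, index=pd.Index(sample_ids, name="sample_id")
        )
    )

    promoter_ids = [f"PROM_{r + 1:04d}" for r in range(config.n_promoters)]
    module_of = np.zeros(config.n_promoters, dtype=int)
    start = 0
    for k, size in enumerate(config.module_sizes, start=1):
        module_of[start : start + size] = k
        start += size

    if config.n_modules:
        factors = np.column_stack(
            [_standardize(rng.standard_normal(n_samples)) for _ in range(config.n_modules)]
        )
        loadings = np.where(
            module_of > 0, rng.uniform(*config.loading_range, size=config.n_promoters), 0.0
        )
        factor_term = (
            loadings[:, None]
            * factors[:, np.maximum(module_of - 1, 0)].T
            * (module_of > 0)[:, None]
        )
    else:
        factors = np.zeros((n_samples, 0))
        loadings = np.zeros(config.n_promoters)
        factor_term = np.zeros((config.n_promoters, n_samples))
    baselines = rng.normal(0.0, config.baseline_sd, size=config.n_promoters)

    delta = np.zeros(config.n_promoters)
    if config.n_differential:
        chosen = rng.choice(config.n_promoters, size=config.n_differential, replace=False)
        delta[chosen] = config.effect_delta

    # promoter-level M profiles
    profiles = (
        baselines[:, None]
        + factor_term
        + delta[:, None] * is_case[None, :]
        + rng.normal(0.0, config.noise_sd, size=(config.n_promoters, n_samples))
    )

    # positions per promoter: 1 + Poisson(mean − 1)
    n_positions = 1 + rng.poisson(config.positions_per_promoter - 1.0, size=config.n_promoters)
    total_positions = int(n_positions.sum())
    probe_ids = [f"cg{i + 1:06d}" for i in range(total_positions)]
    probe_promoter = np.repeat(np.arange(config.n_promoters), n_positions)

    offsets = rng.normal(0.0, config.position_sd, size=total_positions)
    eps = rng.normal(0.0, config.position_sd, size=(total_positions, n_samples))
    m_values = profiles[probe_promoter] + offsets[:, None] + eps

    beta = 1.0 / (1.0 + np.exp2(-m_values))
    total = rng.lognormal(
        np.log(config.intensity_median), config.intensity_log_sd, size=beta.shape
    )
    meth, unmeth = simulate_intensities(beta, total, config.alpha)

    columns = pd.Index(sample_ids, name="sample_id")
    probe_index = pd.Index(probe_ids, name="probe_id")
    intensities = SignalIntensities(
        pd.DataFrame(meth, index=probe_index, columns=columns),
        pd.DataFrame(unmeth, index=probe_index, columns=columns),
        config.alpha,
    )

    # annotation: every position belongs to a promoter, its gene, a tiling
    # window, and (first third of promoters) a CpG island
    promoter_col = [promoter_ids[r] for r in probe_promoter]
    gene_col = [f"GENE_{r + 1:04d}" for r in probe_promoter]
    chrom = [f"chr{(r % 22) + 1}" for r in probe_promoter]
    position = np.arange(total_positions) * 50 + 1_000_000
    tiling = [f"TILE_{i // 20 + 1:04d}" for i in range(total_positions)]
    island = [
        f"CGI_{r + 1:04d}" if r < config.n_promoters // 3 else None for r in probe_promoter
    ]
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "chromosome": chrom,
                "position": position,
                "promoter_id": promoter_col,
                "gene_id": gene_col,
                "tiling_id": tiling,
                "cpg_island_id": island,
                "promoter_annotated": True,
            },
            index=probe_index,
        )
    )

    truth = GroundTruth(
        promoter_module=pd.Series(module_of, index=pd.Index(promoter_ids, name="promoter_id")),
        factors=pd.DataFrame(
            factors,
            index=columns,
            columns=[f"factor_{k + 1}" for k in range(config.n_modules)],
        ),
        loadings=pd.Series(loadings, index=pd.Index(promoter_ids, name="promoter_id")),
        differential=pd.Series(delta, index=pd.Index(promoter_ids, name="promoter_id")),
    )
    return sheet, intensities, annotation, truth


def simulate_power_law_profiles(
    n_features: int = 1000,
    n_samples: int = 5000,
    power: int = 6,
    pareto_exponent: float = 2.0,
    communality_range: tuple[float, float] = (0.3, 0.95),
    seed: int = 0,
) -> pd.DataFrame:
    """Single-factor profiles whose network connectivity follows a power law.

    Feature i is ``sqrt(r_i)·F + sqrt(1 − r_i)·e_i`` with communality
    ``r_i ∈ communality_range``. The soft-powered communality
    ``t_i = r_i^{power/2}`` is drawn from a truncated Pareto with the given
    exponent; since the network connectivity at that soft-thresholding power
    is ``k_i = t_i · Σ_{j≠i} t_j``, k inherits the Pareto (power-law) shape,
    and remains power-law at nearby powers.

    The default sample count is deliberately large: the planted law lives in
    the *population* correlations, and the sample correlations must converge
    to it for the connectivity histogram to show it.
    """
    rng = np.random.default_rng(seed)
    r_lo, r_hi = communality_range
    if not 0 < r_lo < r_hi < 1:
        raise ValueError("communality_range must satisfy 0 < lo < hi < 1")
    t_lo, t_hi = r_lo ** (power / 2.0), r_hi ** (power / 2.0)
    a = pareto_exponent - 1.0
    u = rng.uniform(size=n_features)
    t = (t_lo**-a - u * (t_lo**-a - t_hi**-a)) ** (-1.0 / a)
    r = t ** (2.0 / power)
    factor = _standardize(rng.standard_normal(n_samples))
    noise = rng.standard_normal((n_features, n_samples))
    profiles = np.sqrt(r)[:, None] * factor[None, :] + np.sqrt(1.0 - r)[:, None] * noise
    return pd.DataFrame(
        profiles,
        index=pd.Index([f"F{i + 1:04d}" for i in range(n_features)], name="feature_id"),
        columns=[f"S{j + 1:04d}" for j in range(n_samples)],
    )


def simulate_gene_sets(
    truth: GroundTruth,
    annotation: ProbeAnnotation,
    n_random_sets: int = 5,
    random_set_size: int = 30,
    seed: int = 0,
) -> GeneSetCollection:
    """Gene sets for exercising over-representation on a simulated cohort.

    One set per planted module (its member genes) plus random draws from the
    whole gene universe, so planted-module sets should enrich in the matching
    detected module while random sets should not.
    """
    rng = np.random.default_rng(seed)
    gene_of = annotation.promoter_gene_map()
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for k in truth.module_ids:
        genes = frozenset(gene_of.reindex(truth.members(k)).dropna())
        sets[f"planted_module_{k}"] = genes
        descriptions[f"planted_module_{k}"] = f"genes of planted module {k}"
    universe = sorted(set(gene_of))
    for i in range(n_random_sets):
        size = min(random_set_size, len(universe))
        sets[f"random_set_{i + 1}"] = frozenset(rng.choice(universe, size=size, replace=False))
        descriptions[f"random_set_{i + 1}"] = "uniform random gene draw"
    return GeneSetCollection(sets, descriptions)


def export_ground_truth(truth: GroundTruth, out_dir: str | Path) -> dict[str, str]:
    """Write the planted structure as TSV tables (via core_io.write_tables)."""
    tables = {
        "truth_promoters": pd.DataFrame(
            {
                "module": truth.promoter_module,
                "loading": truth.loadings,
                "delta": truth.differential,
            }
        ),
        "truth_factors": truth.factors,
    }
    return write_tables(
        tables,
        out_dir,
        index_labels={"truth_promoters": "promoter_id", "truth_factors": "sample_id"},
    )
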