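"""Differential methylation screening for positions (DMPs) and regions (DMRs).

Per feature (CpG position or region aggregate) the case and control groups are
compared with a two-sample t-test on M values; effect size is reported as Δβ
(case − control mean on the β scale); multiplicity is handled with
Benjamini–Hochberg. Features are then ordered by a *combined rank*: each
feature is ranked separately by |Δβ| (largest first), by p-value, and by
q-value, and its combined rank is the worst (maximum) of the three — a
feature is only as reliable as its weakest criterion.

Region-level screening averages member-probe M values per sample within each
annotated region (tiling window, gene, promoter, CpG island) and applies the
identical test, so regions double as network nodes downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .core_io import MethylationMatrix, ProbeAnnotation, SampleSheet, REGION_KINDS
from .methylation_values import m_to_beta

__all__ = [
    "RegionMatrix",
    "DifferentialMethylationScreen",
    "test_features",
    "benjamini_hochberg",
    "combined_rank",
    "summarize_regions",
    "select_top",
    "volcano_table",
    "TINY_P",
]

#: stand-in p-value for a zero-variance feature with unequal group means
TINY_P = float(np.finfo(np.float64).tiny)

STAT_COLUMNS = [
    "mean_beta_case",
    "mean_beta_control",
    "delta_beta",
    "t",
    "p_value",
    "q_value",
    "zero_variance",
]


@dataclass
class RegionMatrix:
    """Region × sample matrix of mean member-probe M values."""

    values: pd.DataFrame  # index: region_id, columns: sample_id
    kind: str
    member_counts: pd.Series  # region_id → number of member probes

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"kind must be one of {REGION_KINDS}")
        if not self.values.index.equals(self.member_counts.index):
            raise ValueError("member_counts must cover exactly the regions of the matrix")
        if (self.member_counts < 1).any():
            raise ValueError("every region needs at least one member probe")

    def as_methylation_matrix(self) -> MethylationMatrix:
        return MethylationMatrix(self.values, scale="m")


def _group_arrays(
    values: pd.DataFrame, groups: SampleSheet
) -> tuple[np.ndarray, np.ndarray]:
    case = values.loc[:, groups.ids_in("case")].to_numpy(dtype=float)
    control = values.loc[:, groups.ids_in("control")].to_numpy(dtype=float)
    return case, control


def test_features(
    matrix: MethylationMatrix, groups: SampleSheet, welch: bool = False
) -> pd.DataFrame:
    """Two-sided two-sample t-test on M values per feature.

    Returns a DataFrame indexed by feature id with group β means, Δβ, t, p,
    BH q, and a zero-variance flag; rank columns are added by
    :func:`combined_rank`. Degenerate features (zero variance in both groups)
    get t=0, p=1 when the means agree and p=``TINY_P`` when they do not.
    """
    if matrix.scale != "m":
        raise ValueError("test_features expects an M-scale matrix")
    for g in ("case", "control"):
        if len(groups.ids_in(g)) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if matrix.values.isna().any().any():
        raise ValueError("matrix contains missing values; run QC first")

    case, control = _group_arrays(matrix.values, groups)
    n1, n2 = case.shape[1], control.shape[1]
    m1, m2 = case.mean(axis=1), control.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = control.var(axis=1, ddof=1)

    if welch:
        with np.errstate(divide="ignore", invalid="ignore"):
            se2 = v1 / n1 + v2 / n2
            t = (m1 - m2) / np.sqrt(se2)
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = np.full_like(t, float(n1 + n2 - 2))

    zero_var = ~np.isfinite(t)
    equal_means = np.isclose(m1, m2)
    p = np.empty_like(t)
    ok = ~zero_var
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    t = np.where(zero_var, 0.0, t)
    p[zero_var & equal_means] = 1.0
    p[zero_var & ~equal_means] = TINY_P

    beta = m_to_beta(matrix).values
    beta_case = beta.loc[:, groups.ids_in("case")].mean(axis=1)
    beta_control = beta.loc[:, groups.ids_in("control")].mean(axis=1)

    out = pd.DataFrame(
        {
            "mean_beta_case": beta_case,
            "mean_beta_control": beta_control,
            "delta_beta": beta_case - beta_control,
            "t": t,
            "p_value": p,
            "q_value": benjamini_hochberg(p),
            "zero_variance": zero_var,
        },
        index=matrix.values.index,
    )
    out.index.name = "feature_id"
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min_{j ≥ i} p_(j)·n/j, clipped to 1, returned in input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _rank_with_id_tiebreak(values: np.ndarray, feature_ids: np.ndarray) -> np.ndarray:
    """Ascending 1..n ranks, ties broken by feature id (deterministic)."""
    order = np.lexsort((feature_ids, values))
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def combined_rank(stats_table: pd.DataFrame) -> pd.DataFrame:
    """Add per-criterion ranks and the combined (worst-of-three) rank.

    ``rank_delta`` ranks −|Δβ| ascending (largest effect first), ``rank_p``
    and ``rank_q`` rank p and q ascending; per-criterion ties are broken by
    feature id so each rank column is a permutation of 1..n. The combined
    rank is the maximum of the three; the returned table is sorted by
    combined rank, ties broken by p then feature id.
    """
    out = stats_table.copy()
    ids = out.index.to_numpy(dtype=str)
    out["rank_delta"] = _rank_with_id_tiebreak(-np.abs(out["delta_beta"].to_numpy()), ids)
    out["rank_p"] = _rank_with_id_tiebreak(out["p_value"].to_numpy(), ids)
    out["rank_q"] = _rank_with_id_tiebreak(out["q_value"].to_numpy(), ids)
    out["combined_rank"] = out[["rank_delta", "rank_p", "rank_q"]].max(axis=1)
    order = np.lexsort((ids, out["p_value"].to_numpy(), out["combined_rank"].to_numpy()))
    return out.iloc[order]


def summarize_regions(
    matrix: MethylationMatrix, annotation: ProbeAnnotation, kind: str
) -> RegionMatrix:
    """Aggregate probe M values into per-sample region means.

    For ``kind='promoter'`` only probes flagged as annotated protein-coding
    promoters contribute (ribosomal-RNA, pseudogene and unannotated promoters
    are excluded). Probes without a region id of the requested kind are
    skipped.
    """
    if matrix.scale != "m":
        raise ValueError("summarize_regions expects an M-scale matrix")
    ann = annotation.restrict(matrix.probe_ids).data
    region_ids = ann[f"{kind}_id"] if kind in REGION_KINDS else None
    if region_ids is None:
        raise ValueError(f"kind must be one of {REGION_KINDS}, got {kind!r}")
    mask = region_ids.notna()
    if kind == "promoter":
        mask &= ann["promoter_annotated"]
    if not mask.any():
        raise ValueError(f"no probes carry a {kind} region id")
    member_of = region_ids[mask]
    values = matrix.values.loc[member_of.index]
    grouped = values.groupby(member_of, sort=True)
    region_values = grouped.mean()
    counts = grouped.size()
    region_values.index.name = f"{kind}_id"
    return RegionMatrix(region_values, kind, counts)


def select_top(
    stats_table: pd.DataFrame, k: int | None = None, rank_threshold: int | None = None
) -> pd.DataFrame:
    """Rows with combined_rank ≤ threshold, or the k smallest, stable order."""
    if "combined_rank" not in stats_table.columns:
        raise ValueError("ranks not computed; call combined_rank first")
    if (k is None) == (rank_threshold is None):
        raise ValueError("give exactly one of k or rank_threshold")
    ordered = stats_table.sort_values(["combined_rank", "p_value"], kind="stable")
    if k is not None:
        if k <= 0:
            raise ValueError("k must be positive")
        return ordered.head(k)
    return ordered[ordered["combined_rank"] <= rank_threshold]


def volcano_table(stats_table: pd.DataFrame) -> pd.DataFrame:
    """Δβ and −log10(p) columns for volcano plotting; −log10 capped at TINY_P."""
    p = stats_table["p_value"].to_numpy(dtype=float)
    neglog = -np.log10(np.maximum(p, TINY_P))
    return pd.DataFrame(
        {"delta_beta": stats_table["delta_beta"], "neg_log10_p": neglog},
        index=stats_table.index,
    )


class DifferentialMethylationScreen(BaseEstimator):
    """sklearn-style wrapper for the differential screen.

    ``fit(X, y)`` takes ``X`` (n_samples, n_features) of M values and ``y``
    group labels ('case'/'control'); ``stats_`` holds the full ranked table.
    """

    def __init__(self, welch: bool = False):
        self.welch = welch

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=str)
        if len(y) != X.shape[0]:
            raise ValueError("y must have one label per sample")
        if X.index.is_unique:
            sample_ids = [str(s) for s in X.index]
        else:
            sample_ids = [f"S{i}" for i in range(X.shape[0])]
        values = X.T
        values.columns = sample_ids
        sheet = SampleSheet(pd.DataFrame({"group": y}, index=sample_ids))
        matrix = MethylationMatrix(values, scale="m")
        stats_table = test_features(matrix, sheet, welch=self.welch)
        self.stats_ = combined_rank(stats_table)
        self.n_features_in_ = X.shape[1]
        return self

    def top(self, k: int) -> pd.DataFrame:
        return select_top(self.stats_, k=k)
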