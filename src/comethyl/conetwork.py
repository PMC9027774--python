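"""Weighted co-methylation network analysis on region-level M profiles.

The network follows the weighted-correlation-network (WGCNA) recipe on an
*unsigned* network:

* adjacency ``a_ij = |cor(x_i, x_j)|^β'`` with a soft-thresholding power β'
  chosen so connectivity approximates a scale-free distribution;
* topological overlap ``TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) /
  (min(k_i, k_j) + 1 − a_ij)`` with connectivity ``k_i = Σ_{j≠i} a_ij``;
* average-linkage hierarchical clustering on ``distTOM = 1 − TOM`` with a
  static cut, minimum module size, and iterative merging of modules whose
  eigengenes are closer than a merge height;
* module eigengene = first principal direction of the standardized member
  profiles, oriented so members correlate positively with it on average;
* per-feature gene significance ``GS = −log2(p)`` from the differential
  screen, module membership ``MM = cor(x_i, ME)``, and hub selection by MM.

Modules are named by size-ordered colors (largest = ``turquoise``), with
``grey`` reserved for unassigned features.

The pieces compose into the sklearn-style :class:`CoMethylationNetwork`
clusterer; the module-level functions are the individual steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "MODULE_COLORS",
    "GREY",
    "TOMResult",
    "ModuleAssignment",
    "compute_adjacency",
    "pick_soft_threshold",
    "compute_tom",
    "detect_modules",
    "compute_eigengenes",
    "merge_close_modules",
    "gene_significance",
    "module_membership",
    "intramodular_connectivity",
    "module_gs_summary",
    "select_hubs",
    "export_edges",
    "CoMethylationNetwork",
]

#: size-ordered module palette (WGCNA convention); overflow → "module_N"
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)
GREY = "grey"

#: cap for −log2(p) when p underflows (matches the differential TINY_P flag)
GS_CAP = float(-np.log2(np.finfo(np.float64).tiny))


# ---------------------------------------------------------------------------
# adjacency and soft threshold


def _as_profiles(region_matrix) -> pd.DataFrame:
    """Accept a features × samples DataFrame or a RegionMatrix-like object."""
    if hasattr(region_matrix, "values") and isinstance(region_matrix.values, pd.DataFrame):
        return region_matrix.values
    return pd.DataFrame(region_matrix)


def compute_adjacency(region_matrix, power: int) -> pd.DataFrame:
    """Unsigned adjacency a_ij = |cor(x_i, x_j)|^power, diagonal set to 1."""
    profiles = _as_profiles(region_matrix)
    if power < 1:
        raise ValueError("power must be a positive integer")
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate profiles")
    values = profiles.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    dead = profiles.index[sd == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance feature(s): {dead[:10]}")
    corr = np.corrcoef(values)
    adj = np.abs(corr) ** power
    np.fill_diagonal(adj, 1.0)
    adj = np.clip(adj, 0.0, 1.0)
    return pd.DataFrame(adj, index=profiles.index, columns=profiles.index)


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """Signed scale-free fit index and slope from a binned log-log regression.

    Connectivities are binned into ``n_bins`` equal-width bins on log10(k)
    (empty bins dropped); log10 of each bin's relative frequency is regressed
    on log10 of its mean connectivity. Returns (−sign(slope)·R², slope).
    """
    k = k[k > 0]
    if k.size < 2:
        raise ValueError("all connectivities are zero")
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    fit = stats.linregress(xs, ys)
    r2 = fit.rvalue**2
    return float(-np.sign(fit.slope) * r2), float(fit.slope)


def pick_soft_threshold(
    region_matrix,
    candidate_powers=range(1, 21),
    n_bins: int = 10,
    fit_target: float = 0.8,
    power: int | None = None,
) -> tuple[pd.DataFrame, int]:
    """Scan candidate powers for scale-free topology fit.

    Returns the fit table (power, signed fit R², slope, mean/median/max
    connectivity) and the chosen power: the smallest candidate whose signed
    fit reaches ``fit_target``, else the argmax; an explicit ``power``
    overrides the scan unconditionally.
    """
    profiles = _as_profiles(region_matrix)
    if profiles.shape[0] < 20:
        raise ValueError("need at least 20 features to assess scale-free fit")
    abs_corr = np.abs(np.corrcoef(profiles.to_numpy(dtype=float)))
    np.fill_diagonal(abs_corr, 0.0)
    rows = []
    for b in candidate_powers:
        k = (abs_corr**b).sum(axis=1)
        fit, slope = _scale_free_fit(k, n_bins)
        rows.append(
            {
                "power": int(b),
                "sft_fit_signed_r2": fit,
                "slope": slope,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows).set_index("power")
    if power is not None:
        chosen = int(power)
    else:
        reaching = table.index[table["sft_fit_signed_r2"] >= fit_target]
        chosen = int(reaching[0]) if len(reaching) else int(table["sft_fit_signed_r2"].idxmax())
    return table, chosen


# ---------------------------------------------------------------------------
# topological overlap


@dataclass
class TOMResult:
    tom: pd.DataFrame
    dist_tom: pd.DataFrame
    connectivity: pd.Series  # k_i = Σ_{j≠i} a_ij


def compute_tom(adjacency: pd.DataFrame) -> TOMResult:
    """Topological overlap matrix of an unsigned adjacency.

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij) with
    k excluding the diagonal; the TOM diagonal is set to 1 (distTOM 0).
    """
    a = adjacency.to_numpy(dtype=float).copy()
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # with zero diagonal this is Σ_{u≠i,j} a_iu·a_uj
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    idx = adjacency.index
    tom_df = pd.DataFrame(tom, index=idx, columns=idx)
    return TOMResult(tom_df, 1.0 - tom_df, pd.Series(k, index=idx, name="k"))


# ---------------------------------------------------------------------------
# modules


@dataclass
class ModuleAssignment:
    """Feature → module color label; ``grey`` marks unassigned features."""

    labels: pd.Series  # feature_id → color

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)
        self.labels.name = "module"

    @property
    def module_names(self) -> list[str]:
        """Non-grey module colors, largest first (palette order)."""
        sizes = self.sizes()
        return [m for m in sizes.index if m != GREY]

    def sizes(self) -> pd.Series:
        counts = self.labels.value_counts()
        rank = {c: i for i, c in enumerate(MODULE_COLORS)}
        keys = sorted(
            counts.index, key=lambda c: (c == GREY, rank.get(c, len(MODULE_COLORS)), c)
        )
        return counts.loc[keys]

    def members(self, module: str) -> list[str]:
        if module not in set(self.labels):
            raise KeyError(f"unknown module label {module!r}")
        return list(self.labels.index[self.labels == module])


def _color_name(i: int) -> str:
    return MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module_{i + 1}"


def _relabel_by_size(groups: pd.Series) -> pd.Series:
    """Map arbitrary cluster ids (0 = unassigned) to size-ordered colors."""
    labels = pd.Series(GREY, index=groups.index, dtype=object, name="module")
    sizes = groups[groups != 0].value_counts()
    # deterministic: size descending, then first-member position ascending
    first_pos = {cid: int(np.argmax(groups.to_numpy() == cid)) for cid in sizes.index}
    ordered = sorted(sizes.index, key=lambda cid: (-sizes[cid], first_pos[cid]))
    for i, cid in enumerate(ordered):
        labels[groups == cid] = _color_name(i)
    return labels


def detect_modules(
    dist_tom: pd.DataFrame, cut_height: float = 0.97, min_module_size: int = 30
) -> ModuleAssignment:
    """Average-linkage clustering of distTOM with a static cut.

    Clusters whose size falls below ``min_module_size`` are relegated to
    ``grey``; the survivors are labelled by descending size with the fixed
    color palette.
    """
    if not 0 < cut_height <= 1:
        raise ValueError("cut_height must lie in (0, 1]")
    d = dist_tom.to_numpy(dtype=float).copy()
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    tree = linkage(condensed, method="average")
    flat = fcluster(tree, t=cut_height, criterion="distance")
    groups = pd.Series(flat, index=dist_tom.index)
    sizes = groups.value_counts()
    groups[groups.map(sizes) < min_module_size] = 0
    return ModuleAssignment(_relabel_by_size(groups))


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mean) / sd


def compute_eigengenes(region_matrix, assignment: ModuleAssignment) -> pd.DataFrame:
    """First-principal-direction eigengene per non-grey module.

    Member profiles are standardized across samples; the eigengene is the
    leading right-singular vector over samples, rescaled to unit sample
    variance and sign-oriented so the mean correlation with member profiles
    is positive. Returns samples × modules (columns ``ME_<color>``).
    """
    profiles = _as_profiles(region_matrix)
    eigengenes = {}
    for module in assignment.module_names:
        members = assignment.members(module)
        block = profiles.loc[members].to_numpy(dtype=float)
        if block.shape[0] == 1:
            warnings.warn(f"module {module!r} has a single member; eigengene = its profile")
        z = _standardize_rows(block)
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        me = me / me.std(ddof=1)
        if np.mean([np.corrcoef(row, me)[0, 1] for row in z]) < 0:
            me = -me
        eigengenes[f"ME_{module}"] = me
    out = pd.DataFrame(eigengenes, index=profiles.columns)
    out.index.name = "sample_id"
    return out


def merge_close_modules(
    region_matrix, assignment: ModuleAssignment, merge_cut: float = 0.15
) -> ModuleAssignment:
    """Iteratively merge module pairs with eigengene dissimilarity < merge_cut.

    Dissimilarity is 1 − cor(ME_a, ME_b); the closest qualifying pair is
    merged first, eigengenes are recomputed, and the loop repeats until no
    pair qualifies. Colors are reassigned by the merged sizes.
    """
    profiles = _as_profiles(region_matrix)
    labels = assignment.labels.copy()
    while True:
        current = ModuleAssignment(labels)
        modules = current.module_names
        if len(modules) < 2:
            break
        me = compute_eigengenes(profiles, current)
        corr = np.corrcoef(me.to_numpy(dtype=float).T)
        diss = 1.0 - corr
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_cut:
            break
        a, b = modules[i], modules[j]
        labels[labels == b] = a
    # renumber by size through the integer path to refresh color ordering
    final = ModuleAssignment(labels)
    groups = pd.Series(0, index=labels.index)
    for n, module in enumerate(final.module_names, start=1):
        groups[labels == module] = n
    return ModuleAssignment(_relabel_by_size(groups))


# ---------------------------------------------------------------------------
# significance, membership, hubs, edges


def gene_significance(p_values, base: int = 2) -> np.ndarray:
    """GS = −log_base(p); p = 0 is capped at the zero-variance flag value."""
    p = np.asarray(p_values, dtype=float)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("p = 0 capped at the zero-variance flag value")
    gs = -np.log(np.maximum(p, np.finfo(np.float64).tiny)) / np.log(base)
    return np.minimum(gs, GS_CAP if base == 2 else -np.log10(np.finfo(np.float64).tiny))


def module_membership(region_matrix, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """MM = cor(feature profile, module eigengene), features × modules."""
    profiles = _as_profiles(region_matrix)
    x = profiles.to_numpy(dtype=float)
    if (x.std(axis=1, ddof=1) == 0).any():
        dead = profiles.index[x.std(axis=1, ddof=1) == 0].tolist()
        raise ValueError(f"zero-variance feature(s): {dead[:10]}")
    me = eigengenes.to_numpy(dtype=float).T  # modules × samples
    xz = _standardize_rows(x)
    mez = _standardize_rows(me)
    n = x.shape[1]
    mm = (xz @ mez.T) / (n - 1)
    mm = np.clip(mm, -1.0, 1.0)
    return pd.DataFrame(mm, index=profiles.index, columns=eigengenes.columns)


def intramodular_connectivity(
    adjacency: pd.DataFrame, assignment: ModuleAssignment
) -> pd.Series:
    """kWithin_i = Σ_{j in module(i), j≠i} a_ij (0 for grey features)."""
    k_within = pd.Series(0.0, index=adjacency.index, name="k_within")
    for module in assignment.module_names:
        members = assignment.members(module)
        block = adjacency.loc[members, members].to_numpy(dtype=float)
        k_within[members] = block.sum(axis=1) - np.diag(block)
    return k_within


def module_gs_summary(assignment: ModuleAssignment, gs: pd.Series) -> pd.DataFrame:
    """Per-module mean GS and member count, sorted descending by mean GS."""
    gs = gs.reindex(assignment.labels.index)
    if gs.isna().any():
        raise ValueError("GS missing for some features")
    table = (
        pd.DataFrame({"module": assignment.labels, "gs": gs})
        .groupby("module")
        .agg(mean_gs=("gs", "mean"), n_features=("gs", "size"))
        .sort_values("mean_gs", ascending=False)
    )
    table["is_unassigned"] = table.index == GREY
    return table


def select_hubs(
    mm: pd.DataFrame,
    gs: pd.Series,
    assignment: ModuleAssignment,
    module: str,
    top_n: int = 20,
    gs_alpha: float = 0.05,
) -> pd.DataFrame:
    """Top hub features of a module: ranked by MM to that module, descending.

    ``gs_significant`` marks features whose GS clears −log2(gs_alpha); the
    whole module is returned when it has fewer than ``top_n`` members.
    """
    members = assignment.members(module)
    col = f"ME_{module}"
    if col not in mm.columns:
        raise KeyError(f"no eigengene column for module {module!r}")
    table = pd.DataFrame(
        {
            "module": module,
            "MM": mm.loc[members, col],
            "GS": gs.reindex(members),
        }
    )
    table["gs_significant"] = table["GS"] >= -np.log2(gs_alpha)
    table = table.sort_values("MM", ascending=False, kind="stable").head(top_n)
    table["hub_rank"] = np.arange(1, len(table) + 1)
    table.index.name = "feature_id"
    return table


def export_edges(
    weights: pd.DataFrame,
    assignment: ModuleAssignment,
    module: str,
    threshold: float,
) -> pd.DataFrame:
    """Undirected edge list of a module: pairs with weight ≥ threshold.

    Each unordered pair is emitted once with ``feature_a < feature_b``
    lexicographically. ``weights`` may be a TOM or an |cor| matrix.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    members = sorted(assignment.members(module))
    block = weights.loc[members, members].to_numpy(dtype=float)
    rows = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            if block[i, j] >= threshold:
                rows.append((members[i], members[j], block[i, j]))
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "weight"])


# ---------------------------------------------------------------------------
# estimator


class CoMethylationNetwork(BaseEstimator, ClusterMixin):
    """Weighted co-methylation network as an sklearn-style clusterer.

    Parameters
    ----------
    power : int or None
        Soft-thresholding power β'. ``None`` picks the smallest candidate
        whose signed scale-free fit reaches ``fit_target``.
    cut_height : float
        Static cut height on the average-linkage distTOM dendrogram.
    min_module_size : int
        Clusters below this size become ``grey``.
    merge_cut : float
        Eigengene-dissimilarity height below which modules merge.

    ``fit(X)`` takes ``X`` (n_samples, n_features) of M values — note the
    sklearn orientation, the transpose of the probes × samples matrix.

    Attributes (post-fit)
    ---------------------
    power_, soft_threshold_table_, adjacency_, tom_, dist_tom_,
    connectivity_, labels_ (colors, aligned to features), assignment_,
    eigengenes_ (samples × modules), module_membership_, k_within_.
    """

    def __init__(
        self,
        power: int | None = None,
        candidate_powers=tuple(range(1, 21)),
        fit_target: float = 0.8,
        n_bins: int = 10,
        cut_height: float = 0.97,
        min_module_size: int = 30,
        merge_cut: float = 0.15,
    ):
        self.power = power
        self.candidate_powers = candidate_powers
        self.fit_target = fit_target
        self.n_bins = n_bins
        self.cut_height = cut_height
        self.min_module_size = min_module_size
        self.merge_cut = merge_cut

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        profiles = X.T  # features × samples
        self.feature_names_in_ = np.asarray(profiles.index, dtype=object)
        self.soft_threshold_table_, self.power_ = pick_soft_threshold(
            profiles,
            candidate_powers=self.candidate_powers,
            n_bins=self.n_bins,
            fit_target=self.fit_target,
            power=self.power,
        )
        self.adjacency_ = compute_adjacency(profiles, self.power_)
        tom = compute_tom(self.adjacency_)
        self.tom_ = tom.tom
        self.dist_tom_ = tom.dist_tom
        self.connectivity_ = tom.connectivity
        initial = detect_modules(self.dist_tom_, self.cut_height, self.min_module_size)
        self.assignment_ = merge_close_modules(profiles, initial, self.merge_cut)
        self.labels_ = self.assignment_.labels.to_numpy(dtype=object)
        if self.assignment_.module_names:
            self.eigengenes_ = compute_eigengenes(profiles, self.assignment_)
            self.module_membership_ = module_membership(profiles, self.eigengenes_)
        else:
            self.eigengenes_ = pd.DataFrame(index=profiles.columns)
            self.module_membership_ = pd.DataFrame(index=profiles.index)
        self.k_within_ = intramodular_connectivity(self.adjacency_, self.assignment_)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
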