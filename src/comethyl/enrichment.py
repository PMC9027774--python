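"""Gene-set over-representation analysis (ORA) for module gene lists.

For each (module, gene set) pair the overlap is scored with the upper-tail
hypergeometric probability P(X ≥ observed) — equivalent to a one-sided
Fisher exact test on the 2×2 table — against a universe of the annotated
genes that entered the network. q-values are Benjamini–Hochberg within each
module across its tested sets.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .conetwork import GREY, ModuleAssignment
from .core_io import GeneSetCollection
from .differential import benjamini_hochberg

__all__ = ["ora_hypergeometric", "enrich_modules"]


def ora_hypergeometric(
    module_genes: Iterable[str], gene_set: Iterable[str], universe: Iterable[str]
) -> float:
    """Upper-tail hypergeometric p-value of the module/set overlap.

    Population = universe, successes = set ∩ universe, draws = module size,
    observed = |module ∩ set ∩ universe|; returns P(X ≥ observed).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module = set(module_genes)
    if not module:
        raise ValueError("empty module gene list")
    if not module <= universe:
        raise ValueError("module genes must be a subset of the universe")
    successes = set(gene_set) & universe
    overlap = len(module & successes)
    # sf(k-1) = P(X >= k)
    return float(hypergeom.sf(overlap - 1, len(universe), len(successes), len(module)))


def enrich_modules(
    assignment: ModuleAssignment,
    gene_sets: GeneSetCollection,
    feature_to_gene: Mapping[str, str] | pd.Series,
    top_k: int | None = None,
) -> pd.DataFrame:
    """ORA table for every (non-grey module, gene set) pair.

    ``feature_to_gene`` maps network features (promoter ids) to gene ids; the
    universe is every mapped gene that entered the network, grey included.
    Sets with zero universe overlap are skipped with a warning. q-values are
    BH-adjusted within each module; ``top_k`` keeps the k smallest-p sets per
    module.
    """
    gene_of = pd.Series(feature_to_gene)
    mapped = gene_of.reindex(assignment.labels.index).dropna()
    if mapped.empty:
        raise ValueError("no network feature maps to a gene")
    universe = set(mapped)

    usable = []
    for name, members in gene_sets:
        if members & universe:
            usable.append(name)
        else:
            warnings.warn(f"gene set {name!r} has no overlap with the universe; skipped")

    rows = []
    for module in assignment.module_names:
        module_genes = set(mapped.reindex(assignment.members(module)).dropna())
        if not module_genes:
            continue
        pvals = []
        for name in usable:
            members = gene_sets[name] & universe
            overlap = len(module_genes & members)
            p = ora_hypergeometric(module_genes, members, universe)
            pvals.append(p)
            rows.append(
                {
                    "module": module,
                    "set_name": name,
                    "overlap": overlap,
                    "module_size": len(module_genes),
                    "set_size": len(members),
                    "universe_size": len(universe),
                    "p_value": p,
                }
            )
        qvals = benjamini_hochberg(pvals) if pvals else []
        for offset, q in enumerate(qvals):
            rows[len(rows) - len(qvals) + offset]["q_value"] = float(q)

    table = pd.DataFrame(
        rows,
        columns=[
            "module",
            "set_name",
            "overlap",
            "module_size",
            "set_size",
            "universe_size",
            "p_value",
            "q_value",
        ],
    )
    if table.empty:
        return table
    table = table.sort_values(["module", "p_value", "set_name"], kind="stable").reset_index(
        drop=True
    )
    if top_k is not None:
        table = table.groupby("module", sort=False).head(top_k).reset_index(drop=True)
    return table
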