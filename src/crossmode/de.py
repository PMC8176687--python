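"""Two-group differential expression on log2 CPM with BH FDR control.

The test is a per-gene Welch two-sample t on log2 CPM (unequal variances,
Satterthwaite degrees of freedom), pooling sexes within each genetic
group.  This is a documented stand-in for moderated-variance models such
as limma-voom: it shares the contrast definitions, multiplicity control
and selection semantics while remaining a self-contained, exactly
testable primitive.  The DE stage is pluggable: anything producing a
DEResult-shaped table can feed selection and the downstream classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ConfigError

__all__ = [
    "de_test",
    "bh_adjust",
    "deg_select",
    "DEGSetSummary",
    "degs_across_tissues",
    "pairwise_group_deg_counts",
]

DE_COLUMNS = (
    "gene_id",
    "tissue",
    "contrast",
    "log2_fold_change",
    "t_statistic",
    "p_value",
    "q_value",
    "mean_expression",
)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min over ranks j >= rank(i) of p_(j) * m / j, capped at 1.
    Order-preserving and >= the input p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ConfigError("p_values must be one-dimensional")
    if p.size == 0:
        return np.array([])
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ConfigError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def de_test(
    logmat: pd.DataFrame,
    design: pd.DataFrame,
    tissue: str,
    group_a: int,
    group_b: int,
) -> pd.DataFrame:
    """Welch t-test of group_a vs group_b within one tissue, sexes pooled.

    log2_fold_change is mean(group_a) - mean(group_b) on log2 CPM, so
    swapping the contrast order flips its sign exactly.  q-values are BH
    across all genes of the contrast.  Genes that are constant and equal
    in both groups get t = 0, p = 1 (no evidence); constant but unequal
    groups get p = 0.
    """
    d = design.set_index("sample_id").loc[logmat.columns]
    samples_a = d.index[(d["tissue"] == tissue) & (d["group"] == group_a)]
    samples_b = d.index[(d["tissue"] == tissue) & (d["group"] == group_b)]
    for g, s in ((group_a, samples_a), (group_b, samples_b)):
        if len(s) < 2:
            raise AnalysisError(
                f"group {g} has {len(s)} sample(s) in tissue {tissue!r}; need >= 2"
            )
    a = logmat[samples_a].to_numpy(dtype=float)
    b = logmat[samples_b].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate & (lfc == 0), 0.0, t)
    p = np.where(degenerate, np.where(lfc == 0, 1.0, 0.0), p)
    result = pd.DataFrame(
        {
            "gene_id": logmat.index,
            "tissue": tissue,
            "contrast": f"{group_a}v{group_b}",
            "log2_fold_change": lfc,
            "t_statistic": t,
            "p_value": p,
            "q_value": bh_adjust(p),
            "mean_expression": np.concatenate([a, b], axis=1).mean(axis=1),
        }
    )
    return result


def deg_select(
    results: pd.DataFrame, fdr: float = 0.05, min_abs_log2fc: float = 0.0
) -> set[str]:
    """Genes with q < fdr (strict) and |log2FC| >= min_abs_log2fc.

    A fold-change filter of "FC >= 2" corresponds to min_abs_log2fc = 1.
    """
    if results.empty:
        return set()
    if results["contrast"].nunique() > 1:
        raise AnalysisError("deg_select expects results from a single contrast")
    keep = (results["q_value"] < fdr) & (
        results["log2_fold_change"].abs() >= min_abs_log2fc
    )
    return set(results.loc[keep, "gene_id"])


@dataclass
class DEGSetSummary:
    """Venn-style breakdown of per-tissue DEG sets.

    ``regions`` maps each non-empty tissue combination (frozenset) to the
    genes DE in exactly those tissues (disjoint regions); ``shared_all``
    is the all-tissue intersection; ``tissue_specific`` the exactly-one-
    tissue sets.
    """

    tissues: tuple[str, ...]
    regions: dict[frozenset, set[str]]
    shared_all: set[str]
    tissue_specific: dict[str, set[str]]

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def region_counts(self) -> dict[str, int]:
        return {
            "+".join(sorted(k)): len(v) for k, v in sorted(self.regions.items(), key=lambda kv: sorted(kv[0]))
        }


def degs_across_tissues(deg_sets: Mapping[str, Iterable[str]]) -> DEGSetSummary:
    """All 2^k - 1 disjoint Venn regions of k per-tissue DEG sets."""
    if not deg_sets:
        raise AnalysisError("need at least one tissue")
    tissues = tuple(deg_sets)
    sets = {t: set(deg_sets[t]) for t in tissues}
    membership: dict[str, frozenset] = {}
    for t in tissues:
        for gene in sets[t]:
            membership[gene] = membership.get(gene, frozenset()) | {t}
    regions: dict[frozenset, set[str]] = {}
    for size in range(1, len(tissues) + 1):
        for combo in combinations(tissues, size):
            regions[frozenset(combo)] = set()
    for gene, combo in membership.items():
        regions[combo].add(gene)
    shared_all = set.intersection(*sets.values()) if sets else set()
    tissue_specific = {t: regions[frozenset({t})] for t in tissues}
    return DEGSetSummary(tissues, regions, shared_all, tissue_specific)


def pairwise_group_deg_counts(
    logmat: pd.DataFrame,
    design: pd.DataFrame,
    tissue: str,
    fdr: float = 0.05,
    min_abs_log2fc: float = 0.0,
) -> pd.DataFrame:
    """4x4 symmetric table of DEG counts for all six group contrasts in a tissue."""
    d = design.set_index("sample_id").loc[logmat.columns]
    present = set(d.loc[d["tissue"] == tissue, "group"])
    missing = sorted(set((1, 2, 3, 4)) - present)
    if missing:
        raise AnalysisError(f"tissue {tissue!r} is missing genetic groups {missing}")
    table = pd.DataFrame(0, index=[1, 2, 3, 4], columns=[1, 2, 3, 4])
    for a, b in combinations((1, 2, 3, 4), 2):
        n = len(deg_select(de_test(logmat, design, tissue, a, b), fdr, min_abs_log2fc))
        table.loc[a, b] = table.loc[b, a] = n
    return table
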