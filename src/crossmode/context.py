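"""Genomic-context side analyses: lncRNA neighbors and gene-set enrichment.

Two independent utilities: (1) pairing DE lncRNAs with coding genes within
a genomic window (default 100 kb) and scoring how often the two members of
a pair change expression in opposite directions; (2) one-sided Fisher's
exact over-representation tests of a query gene set against user-supplied
collections (GMT), BH-adjusted across sets.  Gene-set names (GO/KEGG ids
or anything else) are opaque strings; no database is queried.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .errors import AnalysisError, FormatError

__all__ = [
    "read_annotation",
    "read_gmt",
    "neighbor_pairs",
    "ConcordanceResult",
    "direction_concordance",
    "fisher_enrichment",
]

ANNOTATION_COLUMNS = ("gene_id", "chrom", "start", "end", "strand", "biotype")


def read_annotation(path, zero_based: bool = False) -> pd.DataFrame:
    """Read a BED-like gene annotation TSV.

    Columns: gene_id, chrom, start, end, strand, biotype.  Coordinates are
    1-based closed intervals by default; pass ``zero_based=True`` for
    BED-convention input (0-based half-open), which is converted on read.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation missing columns: {missing}")
    if zero_based:
        df = df.copy()
        df["start"] = df["start"] + 1  # end of a half-open interval == closed end
    return validate_annotation(df)


def validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"duplicate gene ids in annotation: {dups}")
    bad = df[(df["start"] > df["end"]) | (df["start"] < 1)]
    if not bad.empty:
        raise FormatError(f"invalid coordinates for genes: {bad['gene_id'].tolist()}")
    if not df["strand"].isin(["+", "-"]).all():
        raise FormatError("strand must be '+' or '-'")
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> gene ids..."""
    collection: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name, genes = fields[0], {g for g in fields[2:] if g}
            if name in collection:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            collection[name] = genes
    return collection


def _gap_distance(s1: int, e1: int, s2: int, e2: int) -> int:
    # closest-ends gap on 1-based closed intervals; 0 when overlapping/adjacent-touching
    return max(0, max(s1, s2) - min(e1, e2))


def neighbor_pairs(
    annotation: pd.DataFrame,
    lnc_ids,
    coding_ids,
    max_distance: int = 100_000,
) -> pd.DataFrame:
    """All same-chromosome (lncRNA, coding) pairs within ``max_distance`` bp.

    Distance is the gap between closest gene ends on 1-based closed
    intervals (0 if the genes overlap); the threshold is inclusive.
    Returns columns lnc_id, coding_id, distance, direction_relation
    (same/opposite strand).
    """
    ann = annotation.set_index("gene_id")
    missing = [g for g in list(lnc_ids) + list(coding_ids) if g not in ann.index]
    if missing:
        raise AnalysisError(f"unannotated gene ids: {sorted(set(missing))}")
    lnc = ann.loc[list(lnc_ids)]
    coding = ann.loc[list(coding_ids)]
    trees: dict[str, IntervalTree] = {}
    for gid, row in coding.iterrows():
        # expand by max_distance so a stabbing query finds everything in range
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            row["start"] - max_distance, row["end"] + max_distance + 1, gid
        )
    rows = []
    for gid, row in lnc.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        for hit in tree.overlap(row["start"], row["end"] + 1):
            cid = hit.data
            if cid == gid:
                continue
            crow = coding.loc[cid]
            dist = _gap_distance(row["start"], row["end"], crow["start"], crow["end"])
            if dist <= max_distance:
                rows.append(
                    {
                        "lnc_id": gid,
                        "coding_id": cid,
                        "distance": dist,
                        "direction_relation": "same" if row["strand"] == crow["strand"] else "opposite",
                    }
                )
    return (
        pd.DataFrame(rows, columns=["lnc_id", "coding_id", "distance", "direction_relation"])
        .sort_values(["lnc_id", "coding_id"])
        .reset_index(drop=True)
    )


@dataclass
class ConcordanceResult:
    """Opposite-direction summary for lncRNA/coding neighbor pairs.

    ``fraction_pairs_opposite`` counts pairs; because one lncRNA can have
    several neighbors, ``fraction_lnc_opposite`` also reports the lncRNA-
    level denominator (a lncRNA counts as opposite when more than half of
    its scored pairs are).
    """

    fraction_pairs_opposite: float
    n_pairs: int
    fraction_lnc_opposite: float
    n_lncrnas: int
    n_excluded_zero_fc: int
    detail: pd.DataFrame


def direction_concordance(pairs: pd.DataFrame, de_results: pd.DataFrame) -> ConcordanceResult:
    """Fraction of neighbor pairs whose members change in opposite directions.

    "Opposite" means sign(log2FC_lnc) * sign(log2FC_coding) < 0 in the
    given DE table.  Pairs where either member is absent or has zero
    fold change are excluded from the denominator and counted separately.
    """
    lfc = de_results.set_index("gene_id")["log2_fold_change"]
    detail = pairs.copy()
    detail["lfc_lnc"] = detail["lnc_id"].map(lfc)
    detail["lfc_coding"] = detail["coding_id"].map(lfc)
    valid = (
        detail["lfc_lnc"].notna()
        & detail["lfc_coding"].notna()
        & (detail["lfc_lnc"] != 0)
        & (detail["lfc_coding"] != 0)
    )
    n_excluded = int((~valid).sum())
    detail = detail[valid].copy()
    detail["opposite"] = np.sign(detail["lfc_lnc"]) * np.sign(detail["lfc_coding"]) < 0
    n_pairs = len(detail)
    frac_pairs = float(detail["opposite"].mean()) if n_pairs else float("nan")
    by_lnc = detail.groupby("lnc_id")["opposite"].mean()
    n_lnc = len(by_lnc)
    frac_lnc = float((by_lnc > 0.5).mean()) if n_lnc else float("nan")
    return ConcordanceResult(frac_pairs, n_pairs, frac_lnc, n_lnc, n_excluded, detail)


def fisher_enrichment(
    query, universe, collection: dict[str, set[str]]
) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric) over-representation per gene set.

    Each set is intersected with the universe before testing; p is the
    upper hypergeometric tail P(overlap >= observed); q is BH across all
    tested sets.  Fold enrichment is (k/n) / (K/N).
    """
    from .de import bh_adjust

    query, universe = set(query), set(universe)
    if not query:
        raise AnalysisError("empty query set: over-representation is undefined")
    extra = query - universe
    if extra:
        raise AnalysisError(f"query genes not in universe: {sorted(extra)}")
    n_universe, n_query = len(universe), len(query)
    rows = []
    for name, genes in collection.items():
        in_universe = genes & universe
        k_set = len(in_universe)
        overlap = len(in_universe & query)
        p = float(hypergeom.sf(overlap - 1, n_universe, k_set, n_query)) if k_set else 1.0
        expected = k_set * n_query / n_universe
        rows.append(
            {
                "set_name": name,
                "set_size": k_set,
                "overlap": overlap,
                "fold_enrichment": overlap / expected if expected > 0 else np.nan,
                "p_value": min(1.0, p),
            }
        )
    result = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "fold_enrichment", "p_value"])
    result["q_value"] = bh_adjust(result["p_value"].to_numpy()) if len(result) else []
    return result
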