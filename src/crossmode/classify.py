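"""Diff-ratio classification of expression inheritance in reciprocal crosses.

Given per-tissue group means m1..m4 (log2 CPM of purebred taurine, the two
reciprocal crosses, and purebred indicine), form the six pairwise absolute
differences d12..d34 and normalize each by the purebred separation d14.
The normalized positions of the crosses between the purebred levels,

    r_g = (m_g - m4) / (m1 - m4)   for g in {2, 3},

place each gene in a 2-D rule space: both crosses near 1/2 is additive;
cross 2 at its dam's purebred level and cross 3 at its dam's level (r2~1,
r3~0, since group 2's dam is taurine) is maternally driven; the mirror
image is paternally driven; both crosses at one purebred's level is breed
dominance (activation when that breed is the high expresser).  A large
cross separation relative to the purebreds (r23 = d23/d14 > theta_high,
default 0.8) flags parental-driven expression; small normalized diffs use
theta_low (default 0.2).

Two rule modes are provided.  ``consistent`` (default) uses mutually
disjoint regions in (r2, r3) space.  ``as_printed`` evaluates the eight
published inequality sets verbatim in their printed order, first match
wins; those rules overlap, admit additive geometry into the dominant
classes, and define no additive region — kept for auditability only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .categories import InheritanceCategory as C
from .errors import AnalysisError, ConfigError

__all__ = [
    "ClassifierThresholds",
    "pairwise_diffs",
    "classify_gene",
    "classify_table",
    "category_counts",
]

DIFF_PAIRS = ((1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4))
#: ratios are each diff divided by d14 (r14 == 1 is omitted)
RATIO_NAMES = ("r12", "r13", "r23", "r24", "r34")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Rule thresholds for the diff-ratio classifier.

    theta_high: a normalized cross separation d23/d14 above this flags
        parental-driven expression (default 0.8).
    theta_low: normalized diffs below this count as "no difference"
        (default 0.2); the additive band is [theta_low, 1 - theta_low].
    min_d14: minimum purebred separation (log2 units) for ratios to be
        meaningful; genes below it are UNCLASSIFIED (default 0.5).
    mode: "consistent" (disjoint regions) or "as_printed" (published
        inequalities, printed order, first match wins).
    """

    theta_high: float = 0.8
    theta_low: float = 0.2
    min_d14: float = 0.5
    mode: str = "consistent"

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_low < 0.5 <= self.theta_high <= 1.0):
            raise ConfigError(
                "need 0 < theta_low < 0.5 <= theta_high <= 1; got "
                f"theta_low={self.theta_low}, theta_high={self.theta_high}"
            )
        if self.min_d14 < 0:
            raise ConfigError(f"min_d14 must be >= 0, got {self.min_d14}")
        if self.mode not in ("consistent", "as_printed"):
            raise ConfigError(f"mode must be 'consistent' or 'as_printed', got {self.mode!r}")


def pairwise_diffs(
    profiles: pd.DataFrame, min_d14: float = 0.5
) -> pd.DataFrame:
    """All six pairwise |group mean| differences and their d14-normalized ratios.

    ``profiles`` needs columns m1..m4 (gene_id/tissue columns are carried
    through if present).  Ratios are NaN wherever d14 < ``min_d14`` (the
    guard against ratio blow-up at small purebred separations).
    """
    out = profiles.loc[:, [c for c in ("gene_id", "tissue") if c in profiles.columns]].copy()
    m = {g: profiles[f"m{g}"].to_numpy(dtype=float) for g in (1, 2, 3, 4)}
    for i, j in DIFF_PAIRS:
        out[f"d{i}{j}"] = np.abs(m[i] - m[j])
    d14 = out["d14"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        for i, j in DIFF_PAIRS:
            if (i, j) == (1, 4):
                continue
            out[f"r{i}{j}"] = np.where(d14 >= min_d14, out[f"d{i}{j}"] / d14, np.nan)
    out["signed_d14"] = m[1] - m[4]
    return out


def _classify_consistent(
    m1: float, m2: float, m3: float, m4: float, th: ClassifierThresholds
) -> C:
    d14 = abs(m1 - m4)
    if d14 < th.min_d14:
        return C.UNCLASSIFIED
    # relative cross positions between the purebred levels
    r2 = (m2 - m4) / (m1 - m4)
    r3 = (m3 - m4) / (m1 - m4)
    r23 = abs(m2 - m3) / d14
    lo, hi = th.theta_low, th.theta_high
    taurine_high = m1 > m4
    if r23 > hi:
        if r2 > 1 - lo and r3 < lo:
            return C.MATERNAL_TAURINE if taurine_high else C.MATERNAL_INDICINE
        if r3 > 1 - lo and r2 < lo:
            return C.PATERNAL_TAURINE if taurine_high else C.PATERNAL_INDICINE
        return C.COMPLEX
    if r23 < lo:
        if r2 > 1 - lo and r3 > 1 - lo:
            return (
                C.TAURINE_DOMINANT_ACTIVATION if taurine_high else C.TAURINE_DOMINANT_INHIBITION
            )
        if r2 < lo and r3 < lo:
            return (
                C.INDICINE_DOMINANT_ACTIVATION
                if not taurine_high
                else C.INDICINE_DOMINANT_INHIBITION
            )
        if lo <= r2 <= 1 - lo and lo <= r3 <= 1 - lo:
            return C.ADDITIVE
    return C.COMPLEX


def _classify_as_printed(
    m1: float, m2: float, m3: float, m4: float, th: ClassifierThresholds
) -> C:
    d14 = abs(m1 - m4)
    if d14 < th.min_d14:
        return C.UNCLASSIFIED
    d12, d13 = abs(m1 - m2), abs(m1 - m3)
    d23, d24, d34 = abs(m2 - m3), abs(m2 - m4), abs(m3 - m4)
    r12, r13, r23, r24, r34 = (d / d14 for d in (d12, d13, d23, d24, d34))
    lo, hi = th.theta_low, th.theta_high
    bt_high = m1 > m4  # "high expression level in Bt"
    bi_high = m4 > m1
    # published inequality sets, printed order, first match wins; the
    # duplicated final indicine label is corrected to Activation
    rules: tuple[tuple[bool, C], ...] = (
        (r23 > hi and r12 < lo and r34 < lo and bt_high, C.MATERNAL_TAURINE),
        (r23 > hi and r12 < lo and r34 < lo and bi_high, C.MATERNAL_INDICINE),
        (r23 > hi and r13 < lo and r24 < lo and bt_high, C.PATERNAL_TAURINE),
        (r23 > hi and r13 < lo and r24 < lo and bi_high, C.PATERNAL_INDICINE),
        (r23 < lo and r24 < hi and r34 < hi and bi_high, C.TAURINE_DOMINANT_INHIBITION),
        (r23 < lo and r24 < hi and r34 < hi and bt_high, C.TAURINE_DOMINANT_ACTIVATION),
        (r23 < lo and r12 < hi and r13 < hi and bt_high, C.INDICINE_DOMINANT_INHIBITION),
        (r23 < lo and r12 < hi and r13 < hi and bi_high, C.INDICINE_DOMINANT_ACTIVATION),
    )
    for hit, category in rules:
        if hit:
            return category
    return C.COMPLEX


def classify_gene(
    m1: float,
    m2: float,
    m3: float,
    m4: float,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> C:
    """Classify one gene's inheritance mode from its four group means.

    Pure function of (m1..m4, thresholds); scale- and location-invariant
    in the means.
    """
    if not all(np.isfinite(v) for v in (m1, m2, m3, m4)):
        raise AnalysisError("group means must be finite")
    if thresholds.mode == "consistent":
        return _classify_consistent(m1, m2, m3, m4, thresholds)
    return _classify_as_printed(m1, m2, m3, m4, thresholds)


def classify_table(
    profiles: pd.DataFrame,
    deg_set: Iterable[str] | Mapping[str, Iterable[str]],
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> pd.DataFrame:
    """Classify the purebred-DEG genes of a group-mean profile table.

    ``profiles`` is the long (gene_id, tissue, m1..m4) table; ``deg_set``
    is either one gene-id set applied to every tissue or a mapping
    tissue -> gene ids (the purebred 1-vs-4 DEGs of that tissue, as in the
    source analysis).  Returns one call per (gene, tissue) with the six
    diffs, five ratios, signed purebred difference and category.
    """
    tissues = list(pd.unique(profiles["tissue"]))
    if isinstance(deg_set, Mapping):
        per_tissue = {t: set(deg_set.get(t, ())) for t in tissues}
    else:
        flat = set(deg_set)
        per_tissue = {t: flat for t in tissues}
    pieces = []
    for tissue in tissues:
        sub = profiles[profiles["tissue"] == tissue]
        wanted = per_tissue[tissue]
        missing = sorted(wanted - set(sub["gene_id"]))
        if missing:
            raise AnalysisError(
                f"genes in deg_set absent from profiles for tissue {tissue!r}: {missing}"
            )
        sub = sub[sub["gene_id"].isin(wanted)]
        if sub.empty:
            continue
        diffs = pairwise_diffs(sub, min_d14=thresholds.min_d14)
        diffs["category"] = [
            classify_gene(row.m1, row.m2, row.m3, row.m4, thresholds).value
            for row in sub.itertuples()
        ]
        diffs["mode"] = thresholds.mode
        pieces.append(diffs)
    cols = (
        ["gene_id", "tissue"]
        + [f"d{i}{j}" for i, j in DIFF_PAIRS]
        + list(RATIO_NAMES)
        + ["signed_d14", "category", "mode"]
    )
    if not pieces:
        return pd.DataFrame(columns=cols)
    return pd.concat(pieces, ignore_index=True)[cols]


def category_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Tissue x category count table with the additive fraction alongside.

    The additive fraction is ADDITIVE calls over all classified calls
    (UNCLASSIFIED excluded), per tissue — the "~90% additive" style
    summary.
    """
    all_categories = [c.value for c in C if c is not C.NULL]
    if calls.empty:
        return pd.DataFrame(columns=all_categories + ["additive_fraction"])
    table = (
        calls.pivot_table(
            index="tissue", columns="category", values="gene_id", aggfunc="count", fill_value=0
        )
        .reindex(columns=all_categories, fill_value=0)
        .astype(int)
    )
    classified = table.drop(columns=[C.UNCLASSIFIED.value]).sum(axis=1)
    with np.errstate(invalid="ignore"):
        table["additive_fraction"] = np.where(
            classified > 0, table[C.ADDITIVE.value] / classified, np.nan
        )
    return table
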