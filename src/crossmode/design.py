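"""Experimental design tables for the reciprocal-cross study layout.

The emulated study collects five tissues (brain, liver, lung, muscle,
placenta) from four genetic groups x two sexes x three biological
replicates: 24 samples per tissue, 120 in total.
"""

from __future__ import annotations

from typing import Callable, Sequence

import pandas as pd

from .categories import GROUP_CODES
from .errors import InvalidDesignError

DEFAULT_TISSUES = ("brain", "liver", "lung", "muscle", "placenta")
DEFAULT_SEXES = ("M", "F")

#: Columns of a design table, in canonical order.
DESIGN_COLUMNS = ("sample_id", "tissue", "group", "sex", "replicate", "batch")

BatchRule = Callable[[str, int, str, int], str]


def _replicate_parity_batch(tissue: str, group: int, sex: str, replicate: int) -> str:
    # Two sequencing runs, balanced within every (tissue, group, sex) cell.
    return f"b{(replicate - 1) % 2 + 1}"


BATCH_RULES: dict[str, BatchRule] = {
    "replicate_parity": _replicate_parity_batch,
    "single": lambda tissue, group, sex, replicate: "b1",
}


def make_design(
    tissues: Sequence[str] = DEFAULT_TISSUES,
    groups: Sequence[int] = GROUP_CODES,
    sexes: Sequence[str] = DEFAULT_SEXES,
    replicates: int = 3,
    batches: str | BatchRule = "replicate_parity",
) -> pd.DataFrame:
    """Build a full-factorial design table.

    Rows are ordered by (tissue, group, sex, replicate) in the order the
    factor levels are given; the row count is the product of the factor
    level counts.  ``batches`` is either a named rule ("replicate_parity",
    "single") or a callable ``(tissue, group, sex, replicate) -> label``.

    With the defaults this reproduces the study layout: 5 tissues x
    4 groups x 2 sexes x 3 replicates = 120 samples, 24 per tissue.
    """
    if not tissues or not groups or not sexes:
        raise InvalidDesignError(
            "tissues, groups and sexes must all be non-empty "
            f"(got {len(tissues)}, {len(groups)}, {len(sexes)} levels)"
        )
    if replicates < 1:
        raise InvalidDesignError(f"replicates must be >= 1, got {replicates}")
    bad = [g for g in groups if g not in GROUP_CODES]
    if bad:
        raise InvalidDesignError(f"unknown genetic group codes {bad}; valid codes are 1-4")
    if callable(batches):
        batch_rule = batches
    else:
        try:
            batch_rule = BATCH_RULES[batches]
        except KeyError:
            raise InvalidDesignError(
                f"unknown batch rule {batches!r}; known rules: {sorted(BATCH_RULES)}"
            ) from None

    rows = []
    for tissue in tissues:
        for group in groups:
            for sex in sexes:
                for rep in range(1, replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{tissue}_g{group}_{sex}_r{rep}",
                            "tissue": tissue,
                            "group": int(group),
                            "sex": sex,
                            "replicate": rep,
                            "batch": batch_rule(tissue, group, sex, rep),
                        }
                    )
    design = pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise InvalidDesignError(f"duplicate sample_id generated: {dup!r}")
    return design


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check a user-supplied design table and return it with canonical dtypes."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise InvalidDesignError(f"design table missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        dups = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise InvalidDesignError(f"duplicate sample ids: {dups}")
    design = design.copy()
    design["group"] = design["group"].astype(int)
    bad = sorted(set(design["group"]) - set(GROUP_CODES))
    if bad:
        raise InvalidDesignError(f"unknown genetic group codes {bad}; valid codes are 1-4")
    design["replicate"] = design["replicate"].astype(int)
    return design


def read_design(path) -> pd.DataFrame:
    """Read a design table from CSV (columns: sample, tissue, group, sex, replicate, batch)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "tissue": str, "sex": str, "batch": str})
    return validate_design(df)


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, index=False)
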