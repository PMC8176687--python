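"""Count-matrix containers, normalization and QC for bulk RNA-seq.

Implements the standard edgeR-style preprocessing chain on a gene x sample
count matrix: counts-per-million (CPM), low-expression filtering,
trimmed-mean-of-M-values (TMM) between-sample normalization, log2 CPM with
a prior count, linear batch centering, per-group means, top-expressed gene
reports, and classical multidimensional scaling of pairwise
leading-fold-change distances for sample QC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import AnalysisError, ConfigError, FormatError

__all__ = [
    "CountMatrix",
    "read_counts",
    "write_counts",
    "cpm",
    "filter_low_expression",
    "tmm_factors",
    "log_cpm",
    "batch_center",
    "group_means",
    "top_expressed",
    "mds_coordinates",
]


@dataclass
class CountMatrix:
    """Non-negative integer read counts, genes as rows, samples as columns.

    ``library_sizes`` defaults to column sums and is *not* recomputed when
    genes are filtered, so CPM values are stable across filtering (the
    usual edgeR convention).
    """

    counts: pd.DataFrame
    library_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                g, s = np.argwhere(values != np.round(values))[0]
                raise FormatError(
                    f"non-integer count for gene {counts.index[g]!r}, "
                    f"sample {counts.columns[s]!r}: {values[g, s]}"
                )
            counts = counts.astype(np.int64)
            self.counts = counts
            values = counts.to_numpy()
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count for gene {counts.index[g]!r}, "
                f"sample {counts.columns[s]!r}: {values[g, s]}"
            )
        if self.library_sizes is None:
            self.library_sizes = counts.sum(axis=0)
        else:
            self.library_sizes = pd.Series(self.library_sizes).reindex(counts.columns)
            if self.library_sizes.isna().any():
                missing = self.library_sizes.index[self.library_sizes.isna()].tolist()
                raise FormatError(f"library sizes missing for samples: {missing}")
        if (self.library_sizes <= 0).any():
            bad = self.library_sizes.index[self.library_sizes <= 0].tolist()
            raise FormatError(f"non-positive library size for samples: {bad}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids) -> "CountMatrix":
        """Restrict to the given samples, keeping their library sizes."""
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise AnalysisError(f"unknown sample ids: {missing}")
        return CountMatrix(
            self.counts.loc[:, list(sample_ids)],
            self.library_sizes.loc[list(sample_ids)],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.library_sizes.equals(
            other.library_sizes
        )


def read_counts(path) -> CountMatrix:
    """Read a gene x sample count TSV (first column gene ids, header sample ids)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = {s for s in header if header.count(s) > 1}
    if dup:  # pandas would silently mangle duplicate columns
        raise FormatError(f"duplicate sample id: {sorted(dup)[0]!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df)


def write_counts(matrix: CountMatrix, path) -> None:
    """Write counts as TSV; first column ``gene_id``, then one column per sample."""
    out = matrix.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def _check_factors(matrix: CountMatrix, factors: pd.Series) -> np.ndarray:
    f = pd.Series(factors).reindex(matrix.sample_ids)
    if f.isna().any():
        raise ConfigError(
            f"normalization factors missing for samples: {f.index[f.isna()].tolist()}"
        )
    vals = f.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ConfigError("normalization factors must be positive")
    gm = np.exp(np.mean(np.log(vals)))
    if abs(gm - 1.0) > 1e-9:
        raise ConfigError(
            f"normalization factors must have geometric mean 1 (got {gm:.6g}); "
            "rescale before use"
        )
    return vals


def cpm(matrix: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million mapped reads.

    CPM = count / (library_size * factor) * 1e6.  Without factors every
    column of a matrix whose library sizes are its column sums totals 1e6.
    """
    libs = matrix.library_sizes.to_numpy(dtype=float)
    if factors is not None:
        libs = libs * _check_factors(matrix, factors)
    return matrix.counts / libs * 1e6


def filter_low_expression(
    matrix: CountMatrix, cpm_threshold: float = 0.5, min_samples: int = 3
) -> CountMatrix:
    """Drop genes below ``cpm_threshold`` CPM in all but < ``min_samples`` samples.

    A gene is retained iff its CPM is >= the threshold in at least
    ``min_samples`` samples.  Library sizes are preserved, which makes the
    filter idempotent.  The default ``min_samples=3`` is the smallest
    group size in the emulated design.
    """
    if cpm_threshold < 0:
        raise ConfigError(f"cpm_threshold must be >= 0, got {cpm_threshold}")
    if min_samples > matrix.shape[1]:
        raise ConfigError(
            f"min_samples={min_samples} exceeds sample count {matrix.shape[1]}"
        )
    keep = (cpm(matrix) >= cpm_threshold).sum(axis=1) >= min_samples
    return CountMatrix(matrix.counts.loc[keep], matrix.library_sizes)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    m_trim: float,
    a_trim: float,
) -> float:
    """Two-sample TMM log2 factor: doubly trimmed, precision-weighted mean M."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        raise AnalysisError("sample shares no expressed gene with the reference")
    obs_k, ref_k = obs[keep].astype(float), ref[keep].astype(float)
    p_obs, p_ref = obs_k / n_obs, ref_k / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # binomial delta-method variance of M; weights are its inverse
    v = (n_obs - obs_k) / (n_obs * obs_k) + (n_ref - ref_k) / (n_ref * ref_k)
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = np.floor(n * m_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * a_trim) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    kept = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not kept.any():
        return 0.0
    f = np.sum(m[kept] / v[kept]) / np.sum(1.0 / v[kept])
    return 0.0 if not np.isfinite(f) else float(f)


def tmm_factors(
    matrix: CountMatrix,
    reference: str | None = None,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    Per sample, M-values (log2 relative abundance vs a reference sample)
    are trimmed by 30% on M and 5% on A (both tails), averaged with
    inverse-asymptotic-variance weights, and exponentiated; factors are
    rescaled to geometric mean 1.  The reference defaults to the sample
    whose upper-quartile relative abundance is closest to the mean
    upper quartile.  Genes with a zero count in either member of a pair
    are excluded pairwise.
    """
    if matrix.shape[1] < 2:
        raise AnalysisError("TMM requires at least 2 samples")
    counts = matrix.counts.to_numpy(dtype=float)
    libs = matrix.library_sizes.to_numpy(dtype=float)
    if reference is None:
        f75 = np.quantile(counts / libs, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        if reference not in matrix.sample_ids:
            raise ConfigError(f"reference sample {reference!r} not in matrix")
        ref_idx = int(matrix.sample_ids.get_loc(reference))
    log_factors = np.array(
        [
            _tmm_pair(counts[:, j], counts[:, ref_idx], libs[j], libs[ref_idx], m_trim, a_trim)
            for j in range(counts.shape[1])
        ]
    )
    factors = 2.0 ** (log_factors - log_factors.mean())
    return pd.Series(factors, index=matrix.sample_ids, name="tmm_factor")


def log_cpm(
    matrix: CountMatrix,
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 CPM with a prior count on the CPM scale (finite at zero counts).

    Computes log2((count + pc_j) / (L_j + 2 pc_j) * 1e6) with effective
    library sizes L_j = library_size * factor and per-sample prior
    pc_j = prior_count * L_j / 1e6, i.e. the prior is ``prior_count`` CPM
    in every library.  Scaling a library and its counts by a common
    constant leaves the transform exactly unchanged.
    """
    if prior_count <= 0:
        raise ConfigError(f"prior_count must be > 0, got {prior_count}")
    libs = matrix.library_sizes.to_numpy(dtype=float)
    if factors is not None:
        libs = libs * _check_factors(matrix, factors)
    pc = prior_count * libs / 1e6
    vals = np.log2((matrix.counts.to_numpy(dtype=float) + pc) / (libs + 2 * pc) * 1e6)
    return pd.DataFrame(vals, index=matrix.gene_ids, columns=matrix.sample_ids)


def _factor_dummies(values: pd.Series, drop_first: bool) -> np.ndarray:
    levels = pd.unique(values)
    cols = [(values == lv).to_numpy(dtype=float) for lv in levels]
    return np.column_stack(cols[1:] if drop_first else cols) if len(cols) > (1 if drop_first else 0) else np.empty((len(values), 0))


def batch_center(
    logmat: pd.DataFrame,
    design: pd.DataFrame,
    preserve: tuple[str, ...] = ("tissue", "group", "sex"),
) -> pd.DataFrame:
    """Remove per-gene batch means by least squares, protecting design factors.

    Fits, per gene, expression ~ intercept + preserved factors + batch
    (sum-to-zero batch coding) and subtracts the fitted batch component.
    With balanced batches this leaves preserved-factor contrasts exactly
    unchanged.  Batch contrasts aliased with preserved factors are dropped
    with a warning (no-op on those components).
    """
    d = design.set_index("sample_id").loc[logmat.columns]
    if "batch" not in d.columns or d["batch"].isna().any():
        raise AnalysisError("every sample needs a batch label")
    n = len(d)
    x_cols = [np.ones((n, 1))]
    for f in preserve:
        if f in d.columns:
            x_cols.append(_factor_dummies(d[f].astype(str), drop_first=True))
    x = np.column_stack(x_cols)
    levels = pd.unique(d["batch"].astype(str))
    if len(levels) < 2:
        return logmat.copy()
    # sum-to-zero batch coding: last level is minus the sum of the others
    b = np.column_stack(
        [
            (d["batch"].astype(str) == lv).to_numpy(dtype=float)
            - (d["batch"].astype(str) == levels[-1]).to_numpy(dtype=float)
            for lv in levels[:-1]
        ]
    )
    # orthogonalize batch columns against the protected design; aliased
    # columns have (numerically) zero residual and cannot be corrected
    coef, *_ = np.linalg.lstsq(x, b, rcond=None)
    b_resid = b - x @ coef
    norms = np.linalg.norm(b_resid, axis=0)
    aliased = norms < 1e-8 * max(1.0, np.linalg.norm(b))
    if aliased.any():
        warnings.warn(
            "batch is confounded with preserved design factors for "
            f"{int(aliased.sum())} contrast(s); those components are left uncorrected",
            stacklevel=2,
        )
        b = b[:, ~aliased]
        if b.shape[1] == 0:
            return logmat.copy()
    z = np.column_stack([x, b])
    y = logmat.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(z, y, rcond=None)
    batch_part = b @ beta[x.shape[1] :, :]
    return pd.DataFrame(
        (y - batch_part).T, index=logmat.index, columns=logmat.columns
    )


def group_means(
    logmat: pd.DataFrame,
    design: pd.DataFrame,
    tissues: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene, per-tissue mean log2 CPM of the four genetic groups.

    Returns a long table with columns gene_id, tissue, m1..m4 (one row per
    gene per tissue).  Every (tissue, group) cell must contain at least one
    sample of ``logmat``.
    """
    d = design.set_index("sample_id").loc[logmat.columns]
    tissues = list(tissues) if tissues is not None else list(pd.unique(d["tissue"]))
    frames = []
    for tissue in tissues:
        row = {"tissue": tissue}
        cols = {}
        for g in (1, 2, 3, 4):
            samples = d.index[(d["tissue"] == tissue) & (d["group"] == g)]
            if len(samples) == 0:
                raise AnalysisError(f"no samples for (tissue={tissue!r}, group={g})")
            cols[f"m{g}"] = logmat[samples].mean(axis=1)
        frame = pd.DataFrame(cols)
        frame.insert(0, "tissue", tissue)
        frame.insert(0, "gene_id", frame.index)
        frames.append(frame.reset_index(drop=True))
    return pd.concat(frames, ignore_index=True)


def top_expressed(
    logmat: pd.DataFrame,
    design: pd.DataFrame,
    n: int = 20,
    tissue_specific_cutoff: float = 10.0,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Most abundant transcripts per tissue, and tissue-exclusive high expressers.

    Returns (rankings, specific): ``rankings`` maps tissue -> the top ``n``
    genes by mean log2 CPM (ties broken by gene id); ``specific`` lists
    genes whose mean log2 CPM exceeds the cutoff in exactly one tissue.
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    d = design.set_index("sample_id").loc[logmat.columns]
    tissue_means = {
        t: logmat[d.index[d["tissue"] == t]].mean(axis=1)
        for t in pd.unique(d["tissue"])
    }
    rankings = {}
    for t, means in tissue_means.items():
        tbl = (
            pd.DataFrame({"gene_id": means.index, "mean_log2_cpm": means.to_numpy()})
            .sort_values(["mean_log2_cpm", "gene_id"], ascending=[False, True])
            .head(n)
            .reset_index(drop=True)
        )
        rankings[t] = tbl
    above = pd.DataFrame({t: m > tissue_specific_cutoff for t, m in tissue_means.items()})
    exclusive = above.sum(axis=1) == 1
    rows = []
    for gene in above.index[exclusive]:
        tissue = above.columns[above.loc[gene]][0]
        rows.append(
            {"gene_id": gene, "tissue": tissue, "mean_log2_cpm": tissue_means[tissue][gene]}
        )
    specific = pd.DataFrame(rows, columns=["gene_id", "tissue", "mean_log2_cpm"])
    return rankings, specific


def _pairwise_lfc_distances(values: np.ndarray, top: int) -> np.ndarray:
    """limma-style 'pairwise' MDS distance: RMS of the top squared log-FCs."""
    n = values.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sq = (values[:, i] - values[:, j]) ** 2
            k = min(top, sq.size)
            top_sq = np.partition(sq, sq.size - k)[sq.size - k :]
            d[i, j] = d[j, i] = np.sqrt(top_sq.mean())
    return d


def mds_coordinates(
    logmat: pd.DataFrame, k: int = 2, top: int = 500
) -> pd.DataFrame:
    """Classical multidimensional scaling of pairwise expression distances.

    The distance between two samples is the root-mean-square of their
    ``top`` largest squared log2 fold changes (leading fold-change style).
    Classical scaling (double-centering + eigendecomposition) returns
    coordinates defined up to rotation/reflection; compare distances, not
    axes.  Degenerate (all-identical) input yields zero coordinates.
    """
    n = logmat.shape[1]
    if n < k + 1:
        raise AnalysisError(f"need at least k+1={k + 1} samples, got {n}")
    d = _pairwise_lfc_distances(logmat.to_numpy(dtype=float), top)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval[0] <= 1e-12:
        warnings.warn("degenerate input: all samples identical; returning zeros", stacklevel=2)
        coords = np.zeros((n, k))
    else:
        lam = np.clip(eigval[:k], 0.0, None)
        coords = eigvec[:, :k] * np.sqrt(lam)
    return pd.DataFrame(
        coords, index=logmat.columns, columns=[f"dim{i + 1}" for i in range(k)]
    )
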