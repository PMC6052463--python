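"""Count normalization: low-expression filtering, TMM scale factors,
log-RPKM conversion, per-gene standardization, and a normality QC summary.

The fixed order of the pipeline is
``filter_low_expression -> tmm_factors -> to_log_rpkm -> standardize``;
re-running :func:`standardize` is a no-op.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "filter_low_expression",
    "tmm_factors",
    "to_log_rpkm",
    "standardize",
    "normalcy_fraction",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_expression_tsv",
    "write_expression_tsv",
]


@dataclass
class CountMatrix:
    """Gene x species read counts with per-gene lengths.

    ``library_size`` defaults to the column sums.
    """

    counts: pd.DataFrame               # genes x species, nonnegative ints
    gene_length_bp: pd.Series          # indexed by gene
    library_size: pd.Series = field(default=None)

    def __post_init__(self):
        c = self.counts
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValueError("duplicate gene or species IDs")
        if (c.values < 0).any():
            raise ValueError("negative counts")
        self.gene_length_bp = self.gene_length_bp.reindex(c.index)
        if self.gene_length_bp.isna().any() or (self.gene_length_bp <= 0).any():
            raise ValueError("gene lengths must be positive and cover all genes")
        if self.library_size is None:
            self.library_size = c.sum(axis=0).astype(float)
        else:
            self.library_size = self.library_size.reindex(c.columns).astype(float)
            if self.library_size.isna().any() or (self.library_size <= 0).any():
                raise ValueError("library sizes must be positive for all species")

    @property
    def gene_ids(self):
        return list(self.counts.index)

    @property
    def species_ids(self):
        return list(self.counts.columns)


@dataclass
class ExpressionMatrix:
    """Gene x species real-valued expression at a named stage
    (``log_rpkm`` or ``standardized``)."""

    values: pd.DataFrame
    stage: str = "log_rpkm"

    def __post_init__(self):
        if self.stage not in ("log_rpkm", "standardized"):
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def gene_ids(self):
        return list(self.values.index)

    @property
    def species_ids(self):
        return list(self.values.columns)


def filter_low_expression(m: CountMatrix, min_count: int = 3,
                          min_species: int = 3) -> CountMatrix:
    """Drop genes with low expression: a gene is removed when ``min_species``
    or more species have fewer than ``min_count`` counts.  Gene order is
    preserved; library sizes are kept as computed on the unfiltered matrix.
    """
    low = (m.counts < min_count).sum(axis=1)
    keep = low < min_species
    if not keep.any():
        warnings.warn("low-expression filter removed every gene")
    return CountMatrix(counts=m.counts.loc[keep].copy(),
                       gene_length_bp=m.gene_length_bp.loc[keep].copy(),
                       library_size=m.library_size.copy())


def _tmm_pair(obs, ref, lib_obs, lib_ref, trim_m, trim_a):
    """Doubly trimmed weighted mean of M-values of one library vs the
    reference; returns the scale factor on the linear (not log2) scale."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("library shares no expressed gene with the reference")
    o = obs[pos] / lib_obs
    r = ref[pos] / lib_ref
    M = np.log2(o / r)
    A = 0.5 * np.log2(o * r)
    # inverse of the delta-method (binomial) variance of M
    v = (lib_obs - obs[pos]) / (lib_obs * obs[pos]) \
        + (lib_ref - ref[pos]) / (lib_ref * ref[pos])
    w = 1.0 / v
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = len(M)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(M)
    ra = stats.rankdata(A)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(w[keep] * M[keep]) / np.sum(w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(m: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05,
                ref: str | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values scale factor per species.

    M-values (log2 ratios of library-size-normalized counts vs a reference
    library) are trimmed by ``trim_m`` on each side, absolute log2
    intensities by ``trim_a``, and the surviving M-values averaged with
    inverse-variance (delta-method binomial) weights.  The reference
    defaults to the species whose upper-quartile normalized count is closest
    to the mean upper-quartile.  Factors are rescaled so their geometric
    mean is 1.
    """
    c = m.counts.to_numpy(float)
    if c.shape[1] < 2:
        raise ValueError("need at least 2 species")
    lib = m.library_size.to_numpy(float)
    if (c.sum(axis=0) == 0).any():
        raise ValueError("degenerate all-zero library")
    if ref is None:
        uq = np.array([np.quantile(c[:, k] / lib[k], 0.75)
                       for k in range(c.shape[1])])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = m.species_ids.index(ref)
    factors = np.ones(c.shape[1])
    for k in range(c.shape[1]):
        if k == ref_idx:
            continue
        factors[k] = _tmm_pair(c[:, k], c[:, ref_idx], lib[k], lib[ref_idx],
                               trim_m, trim_a)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.counts.columns, name="tmm_factor")


def to_log_rpkm(m: CountMatrix, factors: pd.Series | None = None,
                pseudocount: float = 0.0) -> ExpressionMatrix:
    """Natural-log RPKM: ``ln(count * 1e9 / (length_bp * effective_library)
    + pseudocount)`` with effective library = library size x TMM factor."""
    if factors is None:
        eff = m.library_size
    else:
        eff = m.library_size * factors.reindex(m.counts.columns)
    vals = (m.counts.to_numpy(float) * 1e9
            / (m.gene_length_bp.to_numpy(float)[:, None] * eff.to_numpy(float)[None, :]))
    with np.errstate(divide="ignore"):
        out = np.log(vals + pseudocount)
    if np.isneginf(out).any():
        warnings.warn("zero counts with zero pseudocount produced -inf log-RPKM")
    return ExpressionMatrix(values=pd.DataFrame(out, index=m.counts.index,
                                                columns=m.counts.columns),
                            stage="log_rpkm")


def standardize(e: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-scores: each row to mean 0, sample SD (n-1) 1.

    Constant or non-finite rows are dropped with a warning.  Idempotent on
    already-standardized input.
    """
    v = e.values
    finite = np.isfinite(v.to_numpy()).all(axis=1)
    sd = v.std(axis=1, ddof=1)
    ok = finite & (sd > 0).to_numpy()
    if not ok.all():
        dropped = v.index[~ok]
        warnings.warn(f"dropping {len(dropped)} constant or non-finite rows "
                      f"(e.g. {list(dropped[:3])})")
    v = v.loc[ok]
    z = v.sub(v.mean(axis=1), axis=0).div(v.std(axis=1, ddof=1), axis=0)
    return ExpressionMatrix(values=z, stage="standardized")


def normalcy_fraction(e: ExpressionMatrix, alpha: float = 0.05) -> float:
    """Fraction of genes whose per-row Shapiro-Wilk normality test does not
    reject at ``alpha`` — the QC summary supporting the Gaussian working
    assumption of the downstream models."""
    v = e.values.to_numpy(float)
    if v.shape[1] < 3:
        raise ValueError("need at least 3 species")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ps = np.array([stats.shapiro(row).pvalue for row in v])
    return float(np.mean(ps >= alpha))


# ----------------------------------------------------------------- file I/O

def read_counts_tsv(path) -> CountMatrix:
    """Read a counts TSV: gene rows, species columns, plus ``length_bp``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "length_bp" not in df.columns:
        raise ValueError("counts TSV must contain a length_bp column")
    lengths = df.pop("length_bp")
    return CountMatrix(counts=df.astype(int), gene_length_bp=lengths)


def write_counts_tsv(m: CountMatrix, path) -> None:
    out = m.counts.copy()
    out.insert(0, "length_bp", m.gene_length_bp)
    out.to_csv(path, sep="\t", index_label="gene")


def write_expression_tsv(e: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage: {e.stage}\n")
        e.values.to_csv(fh, sep="\t", index_label="gene")


def read_expression_tsv(path) -> ExpressionMatrix:
    stage = "log_rpkm"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# stage:"):
            stage = first.split(":", 1)[1].strip()
            df = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
    return ExpressionMatrix(values=df, stage=stage)
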