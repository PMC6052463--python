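"""Per-gene phylogenetic regression of standardized expression on a
log-transformed, standardized life-history trait, under four residual
models (Null, BM, Pagel's Lambda, OU) with ML model selection.

The slope p-value of the best-likelihood model ranks the genes; together
with Benjamini-Hochberg q-values and the correlation sign this is the
cross-species longevity signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .normalization import ExpressionMatrix
from .phylo import GLSFit, Phylogeny, gls_fit

__all__ = [
    "transform_trait",
    "GeneRegression",
    "fit_gene_all_models",
    "SignatureResult",
    "run_signature",
    "read_traits_tsv",
]

MODELS = ("null", "bm", "lambda", "ou")  # in order of increasing complexity


def transform_trait(traits: pd.DataFrame, column: str = "lifespan_days"
                    ) -> pd.Series:
    """Log-transform and standardize a positive trait across species."""
    x = traits[column].astype(float)
    if (x <= 0).any():
        raise ValueError("trait values must be positive")
    lx = np.log(x)
    return (lx - lx.mean()) / lx.std(ddof=1)


@dataclass
class GeneRegression:
    gene: str
    fits: dict                 # model -> GLSFit
    params: dict               # model -> fitted lambda/alpha (when any)
    best_model: str
    slope: float
    se: float
    tvalue: float
    pvalue: float
    sign: int

    @property
    def logliks(self) -> dict:
        return {m: f.loglik for m, f in self.fits.items()}


def _lambda_structure(tree: Phylogeny, lam: float) -> np.ndarray:
    V = tree.shared_path.copy()
    off = ~np.eye(tree.n_taxa, dtype=bool)
    V[off] *= lam
    return V


def _ou_structure(tree: Phylogeny, alpha: float) -> np.ndarray:
    return np.exp(-alpha * tree.patristic) / (2.0 * alpha)


def fit_gene_all_models(y: np.ndarray, trait_z: np.ndarray, tree: Phylogeny,
                        gene: str = "") -> GeneRegression:
    """Four GLS fits of one gene; lambda and alpha estimated jointly with
    the coefficients by ML (profiled scale, bounded scalar search).

    Best model = maximum log-likelihood, with ties within 1e-6 broken
    toward the simpler model (null < bm < lambda ~ ou).
    """
    y = np.asarray(y, float)
    n = tree.n_taxa
    X = np.column_stack([np.ones(n), np.asarray(trait_z, float)])
    fits: dict[str, GLSFit] = {}
    params: dict[str, float] = {}

    fits["null"] = gls_fit(y, X, np.eye(n))
    fits["bm"] = gls_fit(y, X, tree.shared_path)

    def nll_lam(lam):
        return -gls_fit(y, X, _lambda_structure(tree, lam)).loglik

    r = optimize.minimize_scalar(nll_lam, bounds=(0.0, 1.0), method="bounded",
                                 options={"xatol": 1e-8})
    cand = [(r.x, -r.fun), (0.0, -nll_lam(0.0)), (1.0, -nll_lam(1.0))]
    lam_hat, _ = max(cand, key=lambda c: c[1])
    fits["lambda"] = gls_fit(y, X, _lambda_structure(tree, lam_hat))
    params["lambda"] = float(lam_hat)

    T = tree.depth
    lo, hi = np.log(1e-6), np.log(50.0 / T)

    def nll_ou(log_a):
        return -gls_fit(y, X, _ou_structure(tree, np.exp(log_a))).loglik

    best_r = None
    for frac in (0.25, 0.5, 0.75):  # 3 restarts across the log-range
        b_lo = lo + (hi - lo) * max(0.0, frac - 0.5)
        b_hi = lo + (hi - lo) * min(1.0, frac + 0.5)
        rr = optimize.minimize_scalar(nll_ou, bounds=(b_lo, b_hi),
                                      method="bounded",
                                      options={"xatol": 1e-8})
        if best_r is None or rr.fun < best_r.fun:
            best_r = rr
    a_hat = float(np.exp(best_r.x))
    fits["ou"] = gls_fit(y, X, _ou_structure(tree, a_hat))
    params["ou"] = a_hat

    best = "null"
    for m in MODELS[1:]:
        if fits[m].loglik > fits[best].loglik + 1e-6:
            best = m
    f = fits[best]
    return GeneRegression(gene=gene, fits=fits, params=params, best_model=best,
                          slope=float(f.coef[1]), se=float(f.se[1]),
                          tvalue=float(f.tvalues[1]), pvalue=float(f.pvalues[1]),
                          sign=int(np.sign(f.coef[1]) or 1))


@dataclass
class SignatureResult:
    """Ranked longevity signature with FDR and optional exclusion variant."""

    table: pd.DataFrame          # gene, best_model, slope, se, p, q, sign
    p_threshold: float
    excluded: list
    retained_fraction: float | None = None   # of baseline hits still p < thr
    exclusion_table: pd.DataFrame | None = None

    @property
    def hits(self) -> pd.DataFrame:
        return self.table[self.table["p"] < self.p_threshold]

    @property
    def signs(self) -> pd.Series:
        """gene -> +1/-1 over the significant hits."""
        return self.hits.set_index("gene")["sign"]


def _signature_table(e: ExpressionMatrix, trait_z: pd.Series,
                     tree: Phylogeny) -> pd.DataFrame:
    taxa = list(e.values.columns)
    tr = tree.reorder(taxa) if tree.taxa != taxa else tree
    tz = trait_z.loc[taxa].to_numpy(float)
    rows = []
    vals = e.values.to_numpy(float)
    for gene, y in zip(e.values.index, vals):
        g = fit_gene_all_models(y, tz, tr, gene=gene)
        rows.append((gene, g.best_model, g.slope, g.se, g.pvalue, g.sign))
    df = pd.DataFrame(rows, columns=["gene", "best_model", "slope", "se",
                                     "p", "sign"])
    df["q"] = stats.false_discovery_control(df["p"], method="bh")
    return df


def run_signature(e: ExpressionMatrix, traits: pd.DataFrame, tree: Phylogeny,
                  trait_column: str = "lifespan_days",
                  exclude: list | None = None,
                  p_threshold: float = 0.05) -> SignatureResult:
    """Per-gene four-model PGLS against the transformed trait.

    With a nonempty ``exclude`` list the regression is repeated without
    those species and the fraction of baseline hits (p < ``p_threshold``)
    that remain significant is reported.
    """
    if e.stage != "standardized":
        raise ValueError("expression must be standardized")
    exclude = list(exclude or [])
    taxa = list(e.values.columns)
    if not set(taxa) <= set(tree.taxa):
        raise ValueError("expression columns missing from tree")
    if set(taxa) != set(tree.taxa):
        tree = tree.drop_taxa([t for t in tree.taxa if t not in set(taxa)])
    keep = [t for t in taxa if t not in set(exclude)]
    if len(keep) < 4:
        raise ValueError("fewer than 4 species after exclusion")
    trait_z = transform_trait(traits.loc[taxa], trait_column)
    base = _signature_table(e, trait_z, tree)
    retained = None
    sub = None
    if exclude:
        sub_e = ExpressionMatrix(e.values[keep], stage="standardized")
        sub_tree = tree.drop_taxa(exclude)
        sub_tz = transform_trait(traits.loc[keep], trait_column)
        sub = _signature_table(sub_e, sub_tz, sub_tree)
        base_hits = set(base.loc[base["p"] < p_threshold, "gene"])
        if base_hits:
            still = set(sub.loc[sub["p"] < p_threshold, "gene"]) & base_hits
            retained = len(still) / len(base_hits)
        else:
            retained = float("nan")
    return SignatureResult(table=base, p_threshold=p_threshold,
                           excluded=exclude, retained_fraction=retained,
                           exclusion_table=sub)


def read_traits_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "species" in df.columns:
        df = df.set_index("species")
    return df
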