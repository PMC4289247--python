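"""Rank-based signed co-expression networks from expression matrices.

Expression profiles (genes x conditions, e.g. developmental stages) are
log-transformed, standardized and correlated (Pearson).  Each gene then
nominates its top ``d`` partners by absolute correlation; the union of
nominations is the network, and each edge carries the sign of the underlying
correlation.  ``d`` is chosen as the smallest value for which the network is
a single connected component over all usable genes, keeping the network as
sparse as possible while still spanning the transcriptome.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .graph_core import SpeciesNetwork

logger = logging.getLogger(__name__)


def load_expression_tsv(path) -> pd.DataFrame:
    """Read a genes-by-conditions TSV with gene ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        raise ValueError(f"duplicate gene ids in {path}")
    return df


def correlation_matrix(
    expr: pd.DataFrame,
    log_transform: bool = False,
    standardize: bool = True,
    log_offset: float = 1.0,
) -> pd.DataFrame:
    """Gene-by-gene Pearson correlation of (optionally log2, z-scored) profiles.

    Genes with missing values are dropped beforehand; genes with zero
    variance get NaN rows/columns (excluded downstream).  Requires at least
    three conditions.
    """
    if expr.shape[1] < 3:
        raise ValueError(f"need >=3 conditions for correlation, got {expr.shape[1]}")
    x = expr.dropna(axis=0)
    n_drop = expr.shape[0] - x.shape[0]
    if n_drop:
        logger.warning("dropped %d gene(s) with missing expression values", n_drop)
    vals = x.to_numpy(dtype=float)
    if log_transform:
        if np.any(vals <= -log_offset):
            raise ValueError(f"log transform requires values > {-log_offset}")
        vals = np.log2(vals + log_offset)
    sd = vals.std(axis=1, ddof=0)
    if np.all(sd == 0):
        raise ValueError("all genes have constant expression")
    if standardize:
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(vals)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    corr[np.ix_(sd == 0, sd == 0)] = np.nan
    return pd.DataFrame(corr, index=x.index, columns=x.index)


def _usable(corr: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Drop genes whose off-diagonal correlations are all undefined."""
    c = corr.to_numpy(dtype=float, copy=True)
    np.fill_diagonal(c, np.nan)
    keep = ~np.all(np.isnan(c), axis=1)
    genes = [g for g, k in zip(corr.index, keep) if k]
    return c[np.ix_(keep, keep)], genes


def _nominations(c: np.ndarray, d: int) -> np.ndarray:
    """Boolean nomination matrix: row i marks i's top-d partners by |r|.

    Ties at the d-th rank break by (|r| descending, neighbor index ascending)
    for bit-reproducibility.
    """
    n = c.shape[0]
    absr = np.abs(c)
    absr[np.isnan(absr)] = -np.inf
    cols = np.arange(n)
    # lexsort: primary |r| desc, secondary column index asc
    order = np.lexsort((np.broadcast_to(cols, (n, n)), -absr), axis=1)
    nom = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), d)
    nom[rows, order[:, :d].ravel()] = True
    nom &= np.isfinite(c)  # never nominate an undefined correlation
    return nom

def rank_network(corr: pd.DataFrame, d: int, species_id: str = "species") -> SpeciesNetwork:
    """Top-``d`` nomination network: edge (i,j) iff i nominates j or j nominates i.

    Edge sign is the sign of the correlation (r = 0 counts as +1).  Each node
    nominates exactly ``d`` partners, so the mean degree lies in [d, 2d] and
    the edge count is at most n*d.
    """
    c, genes = _usable(corr)
    n = len(genes)
    if d < 1:
        raise ValueError("d must be >= 1")
    if d >= n:
        raise ValueError(f"d={d} too large for {n} usable genes")
    nom = _nominations(c, d)
    adj = nom | nom.T
    net = SpeciesNetwork(species_id, genes)
    iu, ju = np.where(np.triu(adj, k=1))
    for i, j in zip(iu, ju):
        sign = 1 if c[i, j] >= 0 else -1
        net.add_edge(genes[i], genes[j], sign)
    return net


def choose_d(corr: pd.DataFrame, d_max: int = 50, coverage: float = 1.0) -> int:
    """Smallest ``d`` whose rank network spans all usable genes in one component.

    ``coverage`` < 1 relaxes the criterion to a giant component covering at
    least that fraction of usable genes.  Falls back to ``d_max`` with a
    warning when no d connects the network.
    """
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    c, genes = _usable(corr)
    n = len(genes)
    for d in range(1, min(d_max, n - 1) + 1):
        nom = _nominations(c, d)
        adj = nom | nom.T
        iu, ju = np.where(adj)
        g = coo_matrix((np.ones(iu.size), (iu, ju)), shape=(n, n))
        ncomp, labels = connected_components(g, directed=False)
        largest = np.bincount(labels).max() if n else 0
        if (coverage >= 1.0 and ncomp == 1) or (coverage < 1.0 and largest >= coverage * n):
            return d
    logger.warning("no d <= %d connects the network; falling back to d_max", d_max)
    return d_max


def build_coexpression_layer(
    expr: pd.DataFrame,
    species_id: str,
    d: int | None = None,
    d_max: int = 50,
    log_transform: bool = False,
) -> tuple[SpeciesNetwork, int]:
    """Convenience: correlation -> automatic/explicit d -> rank network."""
    corr = correlation_matrix(expr, log_transform=log_transform)
    if d is None:
        d = choose_d(corr, d_max=d_max)
    return rank_network(corr, d, species_id=species_id), d
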