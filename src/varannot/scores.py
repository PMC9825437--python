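"""Annotation principal components and rank-based PHRED scaling.

An annotation principal component (aPC) summarises one functional category:
the per-category component scores are median-imputed, standardised
(mean 0, sample SD 1), projected onto the first principal component of
their sample covariance, and the resulting raw score is PHRED-scaled by
rank so that a value above 10 places the variant in the top 10% of the
ranking population.  The PHRED transform is ``-10 * log10(r / N)`` for a
score of descending rank ``r`` among ``N``; ties receive the PHRED of the
largest (worst) rank in their tie group, which makes the "top 10%" reading
conservative under ties.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


def standardize(matrix: np.ndarray, missing_mask: np.ndarray | None = None) -> np.ndarray:
    """Median-impute missing entries, then z-score each column.

    Columns end with mean 0 and sample (n-1 denominator) standard deviation 1
    over all entries; constant columns map to all-zero columns.  ``matrix``
    may carry NaNs instead of an explicit mask.
    """
    X = np.array(matrix, dtype=float, copy=True)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if X.shape[0] < 2:
        raise ValueError("standardization needs at least 2 rows")
    if missing_mask is not None:
        X[np.asarray(missing_mask, dtype=bool)] = np.nan
    for j in range(X.shape[1]):
        col = X[:, j]
        miss = np.isnan(col)
        if miss.all():
            X[:, j] = 0.0
            continue
        if miss.any():
            col[miss] = np.median(col[~miss])
        mu = col.mean()
        sd = col.std(ddof=1)
        X[:, j] = 0.0 if sd == 0 else (col - mu) / sd
    return X


def first_pc(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First principal component of a standardized matrix.

    Returns ``(loadings, scores)``: the unit eigenvector of the sample
    covariance matrix with the largest eigenvalue, sign-oriented so that
    ``sum(loadings) >= 0`` (on a zero sum, the first nonzero loading is made
    positive), and the per-row projections ``matrix @ loadings``.

    A degenerate all-zero matrix yields all-zero scores with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("first_pc needs a 2-D matrix with at least 2 rows")
    if not np.any(X):
        logger.warning("degenerate all-zero matrix: returning zero scores")
        k = X.shape[1]
        loadings = np.zeros(k)
        return loadings, np.zeros(X.shape[0])
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eigvals, eigvecs = np.linalg.eigh(cov)
    loadings = eigvecs[:, np.argmax(eigvals)]
    s = loadings.sum()
    if s < 0:
        loadings = -loadings
    elif s == 0:
        nz = np.nonzero(loadings)[0]
        if len(nz) and loadings[nz[0]] < 0:
            loadings = -loadings
    return loadings, X @ loadings


def phred_scale(raw_scores, higher_is_more_functional: bool = True) -> np.ndarray:
    """Rank-based PHRED transform: ``-10 * log10(rank / N)``.

    ``rank`` is the descending rank (1 = most functional).  Ties all receive
    the PHRED of the largest rank in their tie group; the lowest-ranked score
    maps to 0.  With ``higher_is_more_functional=False`` the ranking is
    reversed before scaling.
    """
    x = np.asarray(raw_scores, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("phred_scale expects a non-empty 1-D array")
    oriented = -x if higher_is_more_functional else x
    ranks = rankdata(oriented, method="max")  # descending rank, ties -> largest
    return -10.0 * np.log10(ranks / len(x))


def compute_apcs(store, registry=None) -> None:
    """Compute every configured aPC over the store's SNV partition, in place.

    For each grouping in ``registry.apc_components``: extract the component
    matrix over all SNV records, standardize, take the first PC, PHRED-scale
    the raw scores over the SNV population, and write the result into the
    ``apc_<grouping>`` field of every SNV record.  Indels receive no aPCs.

    A grouping whose components are entirely missing leaves the aPC column
    at its sentinel with a warning.  Groupings with fewer than two component
    fields are configuration errors.
    """
    registry = registry or store.registry
    snv = store.snv
    for grouping, components in registry.apc_components.items():
        if len(components) < 2:
            raise ValueError(
                f"aPC grouping {grouping!r} needs >= 2 component fields, "
                f"got {len(components)}"
            )
        target = f"apc_{grouping}"
        if target not in registry.by_name:
            raise ValueError(f"registry lacks the aPC output field {target!r}")
        if len(snv) < 2:
            logger.warning("fewer than 2 SNV records; skipping aPC %r", grouping)
            continue
        X = snv[components].to_numpy(dtype=float)
        if np.isnan(X).all():
            logger.warning(
                "aPC grouping %r has no observed component values; leaving sentinel",
                grouping,
            )
            continue
        Z = standardize(X)
        _, raw = first_pc(Z)
        store.set_snv_column(target, phred_scale(raw))
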