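"""Latent diet-healthiness factor via multiple correspondence analysis.

Indicator-matrix MCA: the n x J table of categorical diet items is expanded
into a 0/1 indicator matrix Z (one column per category), and correspondence
analysis is applied to Z. With P = Z / grand total, row masses r and column
masses c, the standardized residual matrix is

    S = D_r^{-1/2} (P - r c') D_c^{-1/2}

whose SVD gives the principal dimensions; dimension-1 row principal
coordinates are the factor scores. Scores are then sign-oriented so the
factor correlates positively with a designated healthy-coded anchor item
and standardized to mean 0, SD 1.

The Burt-matrix eigendecomposition route (principal inertias = eigenvalues
of the analogous Burt residual matrix) is mathematically equivalent on the
squared singular values and is used as an independent oracle in tests, not
here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DietFactor",
    "indicator_matrix",
    "mca_first_factor",
    "orient_standardize",
    "diet_factor",
]


@dataclass
class DietFactor:
    """First MCA dimension: row scores, category loadings, inertia share."""

    scores: np.ndarray                 # per retained row
    loadings: pd.Series                # per category column coordinate
    inertia_share: float               # dimension-1 share of total inertia
    standardized: bool = False
    principal_inertias: np.ndarray = field(default_factory=lambda: np.array([]))


def indicator_matrix(table: pd.DataFrame):
    """Expand categorical items into a 0/1 indicator matrix with masses.

    Rows must be complete (listwise deletion happens upstream). Returns
    ``(Z, column_labels, row_mass, col_mass)``; zero-frequency categories
    are dropped with a warning since they carry zero mass.
    """
    if table.isna().any().any():
        raise ValueError("indicator matrix requires complete rows "
                         "(listwise-delete incomplete rows first)")
    n, J = table.shape
    if J < 1 or n < 1:
        raise ValueError("need at least one row and one item")
    blocks, labels = [], []
    for col in table.columns:
        cats = np.unique(table[col].to_numpy())
        if len(cats) < 2:
            warnings.warn(f"item {col!r} has a single observed category; "
                          "it contributes no variation")
        block = (table[col].to_numpy()[:, None] == cats[None, :]).astype(float)
        blocks.append(block)
        labels.extend(f"{col}={c}" for c in cats)
    Z = np.hstack(blocks)
    row_mass = np.full(n, 1.0 / n)
    col_mass = Z.sum(axis=0) / (n * J)
    return Z, np.asarray(labels, dtype=object), row_mass, col_mass


def mca_first_factor(table: pd.DataFrame) -> DietFactor:
    """Correspondence analysis of the indicator matrix; dimension 1.

    Row principal coordinates on the first non-trivial dimension are the
    factor scores (unoriented, unstandardized); the inertia share is the
    first principal inertia over the total.
    """
    if table.shape[1] < 2:
        raise ValueError("MCA needs at least 2 items")
    Z, labels, r, c = indicator_matrix(table)
    n, J = table.shape
    if n <= len(labels):
        raise ValueError("MCA needs more rows than total categories")
    P = Z / Z.sum()
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    if sv[0] < 1e-12:
        raise ValueError("no non-trivial variation (all rows identical?)")
    # row principal coordinates: D_r^{-1/2} U Sigma
    scores = U[:, 0] * sv[0] / np.sqrt(r)
    col_coords = Vt[0] * sv[0] / np.sqrt(c)
    inertias = sv ** 2
    share = float(inertias[0] / inertias.sum())
    return DietFactor(scores=scores,
                      loadings=pd.Series(col_coords, index=labels),
                      inertia_share=share,
                      principal_inertias=inertias)


def orient_standardize(factor: DietFactor, anchor_values) -> DietFactor:
    """Orient the factor healthy-positive and scale to mean 0, SD 1.

    The sign is flipped if the score correlates negatively with the
    healthy-coded numeric order of the anchor item; a zero correlation is
    an error (pick a different anchor).
    """
    anchor = np.asarray(anchor_values, dtype=float)
    if len(anchor) != len(factor.scores):
        raise ValueError("anchor item length mismatch")
    sd_s, sd_a = np.std(factor.scores), np.std(anchor)
    if sd_s == 0:
        raise ValueError("degenerate factor (zero variance)")
    corr = 0.0 if sd_a == 0 else float(np.corrcoef(factor.scores, anchor)[0, 1])
    if corr == 0.0:
        raise ValueError("factor uncorrelated with anchor item; "
                         "choose a different anchor")
    sign = 1.0 if corr > 0 else -1.0
    scores = sign * factor.scores
    scores = (scores - scores.mean()) / scores.std()
    return DietFactor(scores=scores, loadings=sign * factor.loadings,
                      inertia_share=factor.inertia_share, standardized=True,
                      principal_inertias=factor.principal_inertias)


def diet_factor(table: pd.DataFrame, anchor_item: str) -> DietFactor:
    """Listwise-complete MCA factor, oriented on ``anchor_item``.

    Convenience wrapper: rows with any missing item are dropped before the
    MCA (scores align with ``table.dropna().index``).
    """
    complete = table.dropna()
    factor = mca_first_factor(complete)
    return orient_standardize(factor, complete[anchor_item].to_numpy())
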