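"""Library-size normalization and case-to-normal expression ratios (CNR).

Counts are normalized with the median-of-ratios size-factor procedure: each
sample's size factor is the median, over genes with a positive reference
level, of that sample's count divided by the per-gene geometric mean across
the reference samples. A tumor sample's CNR for gene n is its normalized,
pseudocount-regularized expression divided by the average (by default
geometric mean) expression of that gene in a normal-brain control group;
the natural log of the CNR is the elementary signal every downstream score
is built from.

Note on scale invariance: with a fixed reference (``fit`` on one matrix,
``transform`` on another) rescaling a sample's raw counts by k > 0 leaves
its normalized column exactly unchanged. When a matrix is normalized
against itself (``fit_transform``, the usual whole-cohort run), the rescaled
sample also perturbs the reference geometric means, so the normalized matrix
is reproduced only up to one global factor k^(1/m) — which cancels in any
ratio between samples, and in CNRs computed from a jointly normalized run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CNRMatrix, ExpressionMatrix

logger = logging.getLogger("gbpal")


@dataclass
class NormalReference:
    """Per-gene average normalized expression of the control group."""

    control_mean: pd.Series  # strictly positive, indexed by gene
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("a normal reference needs >= 2 control samples")
        if (self.control_mean <= 0).any():
            bad = self.control_mean.index[self.control_mean <= 0][0]
            raise ValueError(
                f"control mean must be positive for every gene (gene {bad!r} "
                "is <= 0; use a positive pseudocount)"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.control_mean.index)


class MedianOfRatiosNormalizer(BaseEstimator, TransformerMixin):
    """Median-of-ratios library-size normalization (DESeq2-style).

    ``fit`` learns the per-gene log geometric mean over the fitted samples
    (restricted to genes positive in every fitted sample); ``transform``
    divides each column by its size factor against that reference.

    Operates on samples-x-genes DataFrames (sklearn orientation).
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = self._as_frame(X)
        if X.shape[0] < 2:
            raise ValueError("need >= 2 samples to estimate size factors")
        values = X.to_numpy(dtype=float)
        all_positive = (values > 0).all(axis=0)
        if not all_positive.any():
            raise ValueError(
                "cannot estimate size factors: no gene has all-positive counts"
            )
        log_ref = np.full(X.shape[1], np.nan)
        log_ref[all_positive] = np.log(values[:, all_positive]).mean(axis=0)
        self.log_reference_ = pd.Series(log_ref, index=X.columns)
        self.reference_genes_ = X.columns[all_positive]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = self._as_frame(X)
        factors = self.size_factors(X)
        return X.div(factors, axis=0)

    def size_factors(self, X: pd.DataFrame) -> pd.Series:
        """Per-sample size factor against the fitted reference."""
        X = self._as_frame(X)
        ref = self.log_reference_.reindex(X.columns)
        usable = ref.notna().to_numpy()
        if not usable.any():
            raise ValueError("no reference gene present in the matrix")
        log_ratios = (
            np.log(X.to_numpy(dtype=float)[:, usable].clip(min=np.nextafter(0, 1)))
            - ref.to_numpy()[usable]
        )
        return pd.Series(
            np.exp(np.median(log_ratios, axis=1)), index=X.index, name="size_factor"
        )

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        return X


class CaseToNormalRatio(BaseEstimator, TransformerMixin):
    """Case-to-normal ratio transformer.

    ``fit`` builds the normal reference from a samples-x-genes matrix of
    normalized control expression; ``transform`` maps normalized tumor
    samples to strictly positive CNRs on the genes shared with the
    reference.

    Parameters
    ----------
    pseudocount : float
        Added to both the numerator sample values and the control values
        before averaging/dividing, so zero counts yield finite log ratios.
    mean : {"geometric", "arithmetic"}
        Control-averaging rule. The geometric mean centers ln CNR at 0 for
        null genes and is the default.
    """

    def __init__(self, pseudocount: float = 1.0, mean: str = "geometric"):
        self.pseudocount = pseudocount
        self.mean = mean

    def fit(self, X: pd.DataFrame, y=None):
        X = MedianOfRatiosNormalizer._as_frame(X)
        if X.shape[0] < 2:
            raise ValueError("need >= 2 control samples")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        shifted = X.to_numpy(dtype=float) + self.pseudocount
        if self.mean == "geometric":
            if (shifted <= 0).any():
                control_mean = np.zeros(X.shape[1])
                positive = (shifted > 0).all(axis=0)
                control_mean[positive] = np.exp(
                    np.log(shifted[:, positive]).mean(axis=0)
                )
            else:
                control_mean = np.exp(np.log(shifted).mean(axis=0))
        elif self.mean == "arithmetic":
            control_mean = shifted.mean(axis=0)
        else:
            raise ValueError("mean must be 'geometric' or 'arithmetic'")
        self.reference_ = NormalReference(
            pd.Series(control_mean, index=X.columns), n_controls=X.shape[0]
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = MedianOfRatiosNormalizer._as_frame(X)
        ref = self.reference_
        shared = X.columns.intersection(ref.control_mean.index)
        if len(shared) == 0:
            raise ValueError("no genes shared between samples and normal reference")
        dropped = len(X.columns) - len(shared)
        dropped_ref = len(ref.control_mean) - len(shared)
        if dropped or dropped_ref:
            logger.info(
                "CNR: dropped %d sample-only and %d reference-only genes",
                dropped, dropped_ref,
            )
        ratios = (X[shared] + self.pseudocount).div(ref.control_mean[shared], axis=1)
        return ratios


# ---------------------------------------------------------------------------
# spec-shaped wrapper functions (genes x samples orientation)


def normalize_counts(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios normalization of a raw count matrix."""
    if counts.is_normalized:
        raise ValueError("matrix is already normalized")
    normalized = MedianOfRatiosNormalizer().fit_transform(counts.data.T).T
    return ExpressionMatrix(normalized, is_normalized=True)


def build_normal_reference(
    normals: ExpressionMatrix, pseudocount: float = 1.0, mean: str = "geometric"
) -> NormalReference:
    """Average the normalized control group into a per-gene reference."""
    if not normals.is_normalized:
        raise ValueError("controls must be normalized before averaging")
    est = CaseToNormalRatio(pseudocount=pseudocount, mean=mean).fit(normals.data.T)
    return est.reference_


def compute_cnr(
    sample_expr: ExpressionMatrix, ref: NormalReference, pseudocount: float = 1.0
) -> CNRMatrix:
    """Per-gene case-to-normal ratios on the genes shared with the reference."""
    if not sample_expr.is_normalized:
        raise ValueError("samples must be normalized before CNR computation")
    est = CaseToNormalRatio(pseudocount=pseudocount)
    est.reference_ = ref
    return CNRMatrix(est.transform(sample_expr.data.T).T)
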