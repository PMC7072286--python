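"""Pathway activation levels (PAL).

For a pathway p and sample j, over the member genes n actually measured,

    PAL_pj = sum_n ARR_np * ln(CNR_nj) / sum_n |ARR_np|

where ARR_np in {-1, -0.5, 0, 0.5, 1} encodes the gene product's
activator/repressor role in the pathway and CNR is the case-to-normal
expression ratio. Positive PAL means the pathway's signal flow is
up-activated relative to normal tissue, negative means suppressed; a sample
identical to the normal reference scores 0 on every pathway. Genes absent
from the CNR matrix are excluded from numerator and denominator alike; the
normalizing sum runs over the pathway's own members only, so one pathway's
score never depends on another pathway's content.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CNRMatrix, PALMatrix, PathwayDB

logger = logging.getLogger("gbpal")


class PathwayActivationScorer(BaseEstimator, TransformerMixin):
    """Transform samples-x-genes CNRs into samples-x-pathways activation levels.

    Parameters
    ----------
    pathway_db : PathwayDB
        Signed pathway membership (ARR weights).
    min_coverage : int
        Minimum number of measured members with nonzero ARR a pathway needs
        to be scored; pathways below it are dropped and logged. Neutral
        (ARR = 0) members count toward the coverage report but not toward
        this threshold, since they carry zero weight in both sums.
    """

    def __init__(self, pathway_db: PathwayDB = None, min_coverage: int = 1):
        self.pathway_db = pathway_db
        self.min_coverage = min_coverage

    def fit(self, X: pd.DataFrame, y=None):
        if self.pathway_db is None:
            raise ValueError("pathway_db is required")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        genes = X.columns
        gene_pos = {g: i for i, g in enumerate(genes)}

        kept, weights, norms, coverage_rows = [], [], [], []
        for pw in self.pathway_db:
            measured = [g for g in pw.members if g in gene_pos]
            nonzero = [g for g in measured if pw.members[g] != 0]
            coverage_rows.append(
                (pw.pathway_id, len(pw.members), len(measured), len(nonzero))
            )
            abs_sum = sum(abs(pw.members[g]) for g in nonzero)
            if len(nonzero) < self.min_coverage or abs_sum == 0:
                logger.info(
                    "PAL: dropping pathway %s (%d measured nonzero-ARR members)",
                    pw.pathway_id, len(nonzero),
                )
                continue
            w = np.zeros(len(genes))
            for g in nonzero:
                w[gene_pos[g]] = pw.members[g]
            kept.append(pw.pathway_id)
            weights.append(w)
            norms.append(abs_sum)
        if not kept:
            raise ValueError("no scorable pathways: every pathway was dropped")

        self.pathway_ids_ = kept
        self.weights_ = np.column_stack(weights)  # genes x pathways
        self.norms_ = np.asarray(norms, dtype=float)
        self.feature_names_in_ = np.asarray(genes)
        self.coverage_ = pd.DataFrame(
            coverage_rows,
            columns=["pathway_id", "n_members", "n_measured", "n_measured_nonzero_arr"],
        ).set_index("pathway_id")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=self.feature_names_in_)
        X = X[list(self.feature_names_in_)]
        values = X.to_numpy(dtype=float)
        if (values <= 0).any() or not np.isfinite(values).all():
            raise ValueError("CNR values must be strictly positive and finite")
        pal = (np.log(values) @ self.weights_) / self.norms_
        return pd.DataFrame(pal, index=X.index, columns=self.pathway_ids_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.pathway_ids_)


def compute_pal(
    cnr: CNRMatrix, db: PathwayDB, min_coverage: int = 1
) -> PALMatrix:
    """Score every scorable pathway in ``db`` on every sample of ``cnr``."""
    scorer = PathwayActivationScorer(db, min_coverage=min_coverage).fit(cnr.data.T)
    pal = scorer.transform(cnr.data.T).T
    return PALMatrix(pal, coverage=scorer.coverage_)
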