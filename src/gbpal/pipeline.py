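"""End-to-end convenience chains over the scoring stages.

The canonical route from raw counts to pathway activations: tumor-side and
control counts are normalized jointly (one median-of-ratios run over the
combined matrix, so both sides share a scale), the control group is
averaged into the normal reference, case-to-normal ratios are taken for the
tumor-side samples, and pathways are scored.
"""

from __future__ import annotations

import pandas as pd

from .io import CNRMatrix, ExpressionMatrix, PALMatrix, PathwayDB
from .normalize import build_normal_reference, compute_cnr, normalize_counts
from .pal import compute_pal


def normalize_jointly(
    counts: ExpressionMatrix, normals: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Normalize tumor-side and control counts in one median-of-ratios run."""
    shared = counts.data.index.intersection(normals.data.index)
    if len(shared) == 0:
        raise ValueError("tumor and control matrices share no genes")
    combined = ExpressionMatrix(
        pd.concat([counts.data.loc[shared], normals.data.loc[shared]], axis=1),
        is_normalized=False,
    )
    normalized = normalize_counts(combined)
    return (
        ExpressionMatrix(normalized.data[counts.sample_ids], is_normalized=True),
        ExpressionMatrix(normalized.data[normals.sample_ids], is_normalized=True),
    )


def run_pal_pipeline(
    counts: ExpressionMatrix,
    normals: ExpressionMatrix,
    db: PathwayDB,
    pseudocount: float = 1.0,
    mean: str = "geometric",
    min_coverage: int = 1,
) -> tuple[CNRMatrix, PALMatrix]:
    """Raw counts + controls + pathway database -> (CNR, PAL)."""
    norm_counts, norm_controls = normalize_jointly(counts, normals)
    ref = build_normal_reference(norm_controls, pseudocount=pseudocount, mean=mean)
    cnr = compute_cnr(norm_counts, ref, pseudocount=pseudocount)
    pal = compute_pal(cnr, db, min_coverage=min_coverage)
    return cnr, pal
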