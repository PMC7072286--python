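"""Independent brute-force oracles used to check the vectorized implementations.

These deliberately re-derive each statistic from its definition with plain
Python loops, sharing no code with the package.
"""

import math


def pal_oracle(cnr_sample: dict[str, float], members: dict[str, float]) -> float:
    """Direct summation of the activation-level formula for one sample.

    PAL = sum_n ARR_n * ln(CNR_n) / sum_n |ARR_n| over measured members.
    """
    num = 0.0
    den = 0.0
    for gene, arr in members.items():
        if gene not in cnr_sample:
            continue
        num += arr * math.log(cnr_sample[gene])
        den += abs(arr)
    return num / den


def auc_oracle(pos, neg) -> float:
    """All-pairs AUC with the half-credit tie rule."""
    wins = sum(1.0 for a in pos for b in neg if a > b)
    ties = sum(1.0 for a in pos for b in neg if a == b)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def bh_oracle(pvals) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values by hand."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        value = pvals[i] * m / (rank_from_top + 1)
        running_min = min(running_min, value)
        adjusted[i] = min(running_min, 1.0)
    return adjusted
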