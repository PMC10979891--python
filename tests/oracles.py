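"""Brute-force nested-loop reimplementations used as independent oracles.

These deliberately avoid vectorization and share no code with the package.
"""

import math


def bf_sum_score(features, weights):
    """features: list of 4-tuples per position; weights: 4-tuple."""
    out = []
    for values in features:
        if any(math.isnan(v) for v in values):
            out.append(float("nan"))
        else:
            out.append(sum(w * v for w, v in zip(weights, values)))
    return out


def bf_min_score(features):
    out = []
    for values in features:
        if any(math.isnan(v) for v in values):
            out.append(float("nan"))
        else:
            out.append(min(values))
    return out


def bf_smooth(values, window):
    half = window // 2
    n = len(values)
    out = []
    for i in range(n):
        acc, count = 0.0, 0
        for j in range(max(0, i - half), min(n, i + half + 1)):
            if not math.isnan(values[j]):
                acc += values[j]
                count += 1
        out.append(acc / count if count else float("nan"))
    return out


def bf_rank_sites(scores, top_k, min_separation):
    """Greedy selection: repeated max (first index wins ties), then suppress
    every position within min_separation residues."""
    available = [not math.isnan(s) for s in scores]
    picked = []
    while len(picked) < top_k and any(available):
        best = None
        for i, score in enumerate(scores):
            if available[i] and (best is None or score > scores[best]):
                best = i
        picked.append(best + 1)  # 1-based
        for i in range(len(scores)):
            if abs(i - best) <= min_separation:
                available[i] = False
    return picked
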