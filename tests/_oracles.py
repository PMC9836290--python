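"""Independent brute-force oracles used to check the pipeline.

Deliberately naive: plain Python loops and lists, no shared code with the
package under test.
"""

from __future__ import annotations


def quantile_normalize_oracle(columns: list[list[float]]) -> list[list[float]]:
    """Brute-force rank-mean quantile normalization.

    ``columns`` is a list of equal-length per-sample value lists. Sort each
    sample, average across samples at each rank, then walk each sample's
    values in rank order reassigning the rank means; a run of tied input
    values receives the plain mean of the rank-means its ranks span.
    """
    n_samples = len(columns)
    n = len(columns[0])
    assert all(len(c) == n for c in columns)
    sorted_cols = [sorted(c) for c in columns]
    rank_means = [
        sum(sorted_cols[j][r] for j in range(n_samples)) / n_samples
        for r in range(n)
    ]
    result = []
    for col in columns:
        order = sorted(range(n), key=lambda i: col[i])
        out = [0.0] * n
        r = 0
        while r < n:
            # find the run of ties starting at rank r
            r2 = r
            while r2 + 1 < n and col[order[r2 + 1]] == col[order[r]]:
                r2 += 1
            tie_mean = sum(rank_means[r : r2 + 1]) / (r2 - r + 1)
            for k in range(r, r2 + 1):
                out[order[k]] = tie_mean
            r = r2 + 1
        result.append(out)
    return result
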