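"""Independent brute-force oracles, deliberately naive.

These re-derive the quantities the package computes via vectorized paths,
using plain Python loops and exhaustive search, so the two routes share no
code.
"""

from itertools import combinations


def brute_force_candidates(case_levels, ctrl_levels, genes):
    """Exhaustive triple loop over (ordered pair, subject).

    Returns {(num, den): (threshold, case_count)} for pairs with >= 1 case
    strictly above the control maximum.
    """
    out = {}
    for i, gi in enumerate(genes):
        for j, gj in enumerate(genes):
            if i == j:
                continue
            threshold = max(row[i] / row[j] for row in ctrl_levels)
            count = sum(1 for row in case_levels if row[i] / row[j] > threshold)
            if count >= 1:
                out[(gi, gj)] = (threshold, count)
    return out


def exhaustive_best_coverage(cover_sets):
    """Maximum case coverage achievable by any subset of candidate ratios,
    and the minimum subset size achieving it, by exhaustive search."""
    items = list(cover_sets)
    best_cover, best_size = 0, 0
    for r in range(len(items) + 1):
        for combo in combinations(items, r):
            covered = set().union(*combo) if combo else set()
            if len(covered) > best_cover:
                best_cover, best_size = len(covered), r
    # minimum size attaining best_cover
    min_size = None
    for r in range(len(items) + 1):
        for combo in combinations(items, r):
            covered = set().union(*combo) if combo else set()
            if len(covered) == best_cover:
                min_size = r
                break
        if min_size is not None:
            break
    return best_cover, min_size
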