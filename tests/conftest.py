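import pytest

from pyranoshift.subtype_rules import load_marker_table


@pytest.fixture(scope="session")
def marker_table():
    return load_marker_table()


def oracle_match_hungarian(query, reference, tolerance):
    """Independent matching oracle: Hungarian assignment with dummy padding.

    Real-real pairs within tolerance cost |diff| − P (P large), forbidden
    pairs a prohibitive constant, dummy pairings 0.  Minimizing total cost is
    then lexicographic: maximize matches first, minimize Σ|diff| second.
    Returns (n_matched, total_abs_diff).
    """
    import numpy as np
    from scipy.optimize import linear_sum_assignment

    n, m = len(query), len(reference)
    P, FORBID = 1.0e4, 1.0e9
    size = n + m
    cost = np.zeros((size, size))
    for i in range(n):
        for j in range(m):
            d = abs(query[i] - reference[j])
            cost[i, j] = d - P if d <= tolerance else FORBID
    rows, cols = linear_sum_assignment(cost)
    n_matched, total = 0, 0.0
    for i, j in zip(rows, cols):
        if i < n and j < m and cost[i, j] < FORBID / 2:
            n_matched += 1
            total += abs(query[i] - reference[j])
    return n_matched, total


def oracle_match_bruteforce(query, reference, tolerance):
    """Exhaustive enumeration over injective assignments (tiny inputs only)."""
    best = (0, 0.0)  # (matches, -total_diff), maximized

    def rec(i, used, matches, total):
        nonlocal best
        if i == len(query):
            best = max(best, (matches, -total))
            return
        rec(i + 1, used, matches, total)
        for j in range(len(reference)):
            d = abs(query[i] - reference[j])
            if j not in used and d <= tolerance:
                rec(i + 1, used | {j}, matches + 1, total + d)

    rec(0, frozenset(), 0, 0.0)
    return best[0], -best[1]
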