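"""Independent brute-force oracles used to validate the fast paths.

These deliberately re-derive results by exhaustive enumeration and never
call the implementations they check.
"""

from __future__ import annotations


def brute_force_best_window(site_counts: dict[int, int], L: int) -> tuple[int, int, int]:
    """Exhaustive scan over all O(sites^2) candidate windows.

    A candidate is any contiguous run of mutated sites whose minimal
    span fits in L. Maximize count; break ties by smaller span, then
    smaller start.
    """
    positions = sorted(site_counts)
    best = None
    for i in range(len(positions)):
        for j in range(i, len(positions)):
            span = positions[j] - positions[i] + 1
            if span > L:
                break
            count = sum(site_counts[p] for p in positions[i : j + 1])
            key = (count, -span, -positions[i])
            if best is None or key > best[0]:
                best = (key, (positions[i], positions[j], count))
    assert best is not None
    return best[1]


def brute_force_greedy(coverage: dict[str, frozenset], n_samples: int) -> list[tuple[str, int]]:
    """Maximum-marginal-coverage ordering by exhaustive per-step scan.

    Returns [(item_id, marginal_new_samples), ...]. Ties: larger total
    coverage, then lexicographically smallest id.
    """
    remaining = dict(coverage)
    covered: set = set()
    order = []
    while remaining:
        best_id, best_key = None, None
        for item_id in sorted(remaining):
            new = len(remaining[item_id] - covered)
            key = (new, len(remaining[item_id]))
            if best_key is None or key > best_key:
                best_id, best_key = item_id, key
        new_samples = remaining[best_id] - covered
        order.append((best_id, len(new_samples)))
        covered |= new_samples
        del remaining[best_id]
    return order


def union_coverage(coverage_sets, n_samples: int) -> float:
    """Direct set-union coverage fraction."""
    union = set()
    for s in coverage_sets:
        union |= set(s)
    return len(union) / n_samples


def k_coverage(sample_to_items: dict[str, set], n_samples: int, k: int) -> float:
    return sum(1 for items in sample_to_items.values() if len(items) >= k) / n_samples
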