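"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the production code paths: cluster averages are
recomputed from the raw leaf-to-leaf matrix at every step (O(N^3) overall),
entropies are evaluated per column with collections.Counter, and property
SDs with statistics.pstdev.
"""

from __future__ import annotations

import math
from collections import Counter


def brute_force_upgma(labels, d):
    """UPGMA by exhaustive recomputation.

    Returns (merges, partitions): merges as (leafset_a, leafset_b, height)
    with frozenset leaf-index sets, and partitions[k] (k = 1..N) as the set
    of frozensets obtained by undoing the last k-1 merges.
    """
    n = len(labels)
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for ai in range(len(clusters)):
            for bi in range(ai + 1, len(clusters)):
                a, b = clusters[ai], clusters[bi]
                avg = sum(d[i][j] for i in a for j in b) / (len(a) * len(b))
                fa = min(labels[i] for i in a)
                fb = min(labels[i] for i in b)
                tie = tuple(sorted((fa, fb)))
                if best is None or (avg, tie) < (best[0], best[1]):
                    best = (avg, tie, a, b)
        avg, _, a, b = best
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
        merges.append((a, b, avg / 2.0))
    partitions = {}
    active = [frozenset(range(n))]
    history = list(merges)
    for k in range(1, n + 1):
        partitions[k] = set(active)
        if k < n:
            a, b, _ = history.pop()
            active = [c for c in active if c != a | b] + [a, b]
    return merges, partitions


def column_entropy(column: str) -> float:
    """-sum p log2 p over standard residues of one column string."""
    counts = Counter(c for c in column if c in "ACDEFGHIKLMNPQRSTVWY")
    total = sum(counts.values())
    if total <= 1:
        return 0.0
    return -sum(
        (v / total) * math.log2(v / total) for v in counts.values()
    )


def level_average(columns: list[str], groups: list[list[int]]) -> list[float]:
    """Size-weighted within-group entropy per column, by direct slicing."""
    n = sum(len(g) for g in groups)
    out = []
    for col in columns:
        acc = 0.0
        for g in groups:
            acc += (len(g) / n) * column_entropy("".join(col[i] for i in g))
        out.append(acc)
    return out


def property_sd(column: str, values: dict[str, list[float]], ddof: int = 0):
    """Per-descriptor SD of one column via statistics module semantics."""
    import statistics

    obs = [values[c] for c in column if c in values]
    if len(obs) < 2:
        return [0.0] * len(next(iter(values.values())))
    ndesc = len(obs[0])
    out = []
    for k in range(ndesc):
        xs = [o[k] for o in obs]
        if ddof == 0:
            out.append(statistics.pstdev(xs))
        else:
            out.append(statistics.stdev(xs))
    return out
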