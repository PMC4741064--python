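"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: O(n^2) all-pairs scans and hand-rolled
rank arithmetic, sharing no code with the package paths they verify.
"""

from __future__ import annotations

import math
from typing import Sequence

from replicate_concord.model import IndelRecord, SnvCall, SnvKey


def brute_force_snv_proximity(calls: Sequence[SnvCall], window_bp: int) -> set[SnvKey]:
    """All-pairs scan: a call is removed iff any OTHER call is within the window."""
    removed = set()
    for i, a in enumerate(calls):
        for j, b in enumerate(calls):
            if i == j:
                continue
            if a.key.chrom == b.key.chrom and abs(a.key.pos - b.key.pos) <= window_bp:
                removed.add(a.key)
                break
    return removed


def brute_force_indel_proximity(
    calls: Sequence[SnvCall], indels: Sequence[IndelRecord], window_bp: int
) -> set[SnvKey]:
    """Per-call, per-indel gap-distance scan."""
    removed = set()
    for call in calls:
        for indel in indels:
            if call.key.chrom != indel.chrom:
                continue
            if indel.start <= call.key.pos <= indel.end:
                gap = 0
            else:
                gap = min(abs(call.key.pos - indel.start), abs(call.key.pos - indel.end))
            if gap <= window_bp:
                removed.add(call.key)
                break
    return removed


def average_ranks(values: Sequence[float]) -> list[float]:
    """Average ranks with ties, built from a plain sort."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2 + 1  # ranks are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def brute_force_spearman(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Pearson correlation of the explicit rank vectors."""
    rx = average_ranks(xs)
    ry = average_ranks(ys)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)
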