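"""Binary segmentation on the mean for photobleach step detection.

A candidate split tree is built greedily without any penalty (each
segment is split at the point maximizing the reduction in squared
error, recursively, to a fixed depth); the penalty is applied
afterwards by pruning: a split is accepted iff its gain exceeds the
threshold and all of its ancestors are accepted.  Because the tree does
not depend on the penalty, accepted change-point sets are nested in the
penalty, which guarantees that raising the penalty can never move a
detected bleach step earlier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["SplitNode", "build_split_tree", "accepted_changepoints", "robust_noise_sd"]


@dataclass(frozen=True)
class SplitNode:
    index: int  # first sample of the right-hand segment
    gain: float  # reduction in within-segment squared error
    parent: Optional[int]  # position of the parent node in the tree list


def robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD from the MAD of first differences (step-insensitive)."""
    x = np.asarray(x, float)
    if x.size < 3:
        return 0.0
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def build_split_tree(
    x: np.ndarray, min_size: int = 3, max_depth: int = 4
) -> list[SplitNode]:
    """Greedy penalty-free split tree of ``x`` (l2 cost on the mean)."""
    x = np.asarray(x, float)
    n = x.size
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def sse(a: int, b: int) -> float:
        m = b - a
        if m <= 0:
            return 0.0
        return (s2[b] - s2[a]) - (s1[b] - s1[a]) ** 2 / m

    nodes: list[SplitNode] = []

    def recurse(a: int, b: int, depth: int, parent: Optional[int]) -> None:
        if depth > max_depth or b - a < 2 * min_size:
            return
        ks = np.arange(a + min_size, b - min_size + 1)
        left_n = ks - a
        right_n = b - ks
        left_sum = s1[ks] - s1[a]
        right_sum = s1[b] - s1[ks]
        sse_left = (s2[ks] - s2[a]) - left_sum**2 / left_n
        sse_right = (s2[b] - s2[ks]) - right_sum**2 / right_n
        gains = sse(a, b) - sse_left - sse_right
        i = int(np.argmax(gains))
        if gains[i] <= 0:
            return
        k = int(ks[i])
        nodes.append(SplitNode(index=k, gain=float(gains[i]), parent=parent))
        me = len(nodes) - 1
        recurse(a, k, depth + 1, me)
        recurse(k, b, depth + 1, me)

    recurse(0, n, 1, None)
    return nodes


def accepted_changepoints(nodes: list[SplitNode], threshold: float) -> list[int]:
    """Indices of splits whose gain (and all ancestors' gains) exceed
    ``threshold``, in increasing order."""
    ok = [False] * len(nodes)
    out = []
    for i, node in enumerate(nodes):
        if node.gain > threshold and (node.parent is None or ok[node.parent]):
            ok[i] = True
            out.append(node.index)
    return sorted(out)
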