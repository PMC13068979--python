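"""Deterministic greedy graph coloring for multi-flip sweep scheduling.

Any proper coloring of the coupling graph yields color classes whose
member flips have independent energy changes; we use largest-degree-first
greedy with index tie-breaking so results are reproducible.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple


def greedy_coloring(
    nodes: Sequence[int], edges: Iterable[Tuple[int, int]]
) -> List[List[int]]:
    """Proper coloring as a list of color classes (each sorted).

    Nodes are colored in order of decreasing degree (ties by index) with
    the smallest color not used by a neighbor.
    """
    adj: Dict[int, set] = {v: set() for v in nodes}
    for i, j in edges:
        if i == j:
            continue
        adj[i].add(j)
        adj[j].add(i)
    order = sorted(adj, key=lambda v: (-len(adj[v]), v))
    color: Dict[int, int] = {}
    for v in order:
        used = {color[u] for u in adj[v] if u in color}
        c = 0
        while c in used:
            c += 1
        color[v] = c
    n_colors = max(color.values(), default=-1) + 1
    classes: List[List[int]] = [[] for _ in range(n_colors)]
    for v in sorted(color):
        classes[color[v]].append(v)
    return classes


def color_order(nodes: Sequence[int], edges: Iterable[Tuple[int, int]]) -> List[int]:
    """Flat visit order: variables grouped color class by color class."""
    return [v for cls in greedy_coloring(nodes, edges) for v in cls]
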