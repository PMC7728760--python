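"""Exhaustive reference for chain decomposition, shared by the tests.

Enumerates every bubble tiling by forward reachability over matched vertex
pairs and reports the (q1, q2, q3) split of the longest (leftmost) chain.
Independent of the production dynamic programme: no pruning, no early
breaks, straight from the definitions.
"""

from lcbkit.core import VWalk


def oracle_decompose(p_a: VWalk, p: VWalk, b: int):
    matches = [
        (i, j)
        for i, v in enumerate(p_a.vertices)
        for j, w in enumerate(p.vertices)
        if v == w
    ]

    def bubble(s, t):
        (i0, j0), (i1, j1) = s, t
        if i1 <= i0 or j1 <= j0:
            return False
        if (
            i1 == i0 + 1
            and j1 == j0 + 1
            and p_a.labels is not None
            and p.labels is not None
            and p_a.labels[i0] == p.labels[j0]
        ):
            return True  # parallel edges: a chain of unit bubbles
        if p_a.cum[i1] - p_a.cum[i0] > b or p.cum[j1] - p.cum[j0] > b:
            return False
        xa = p_a.vertices[i0 : i1 + 1]
        yb = p.vertices[j0 : j1 + 1]
        return set(xa) & set(yb) <= {xa[0], xa[-1]}

    reach: dict = {}

    def ends_from(s):
        if s in reach:
            return reach[s]
        out = set()
        for t in matches:
            if bubble(s, t):
                out.add(t)
                out |= ends_from(t)
        reach[s] = out
        return out

    total = p_a.length
    best = None  # (-q2, q1)
    for s in matches:
        for t in ends_from(s):
            q1 = p_a.cum[s[0]]
            q2 = p_a.cum[t[0]] - q1
            key = (-q2, q1)
            if best is None or key < best:
                best = key
    if best is None:
        return (0, 0, total)
    q2, q1 = -best[0], best[1]
    return (q1, q2, total - q1 - q2)
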