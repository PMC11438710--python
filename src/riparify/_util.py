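"""Small shared helpers: printed-precision rounding and union-find."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (the convention of printed tables).

    Python's builtin ``round`` uses banker's rounding; report tables here
    round 0.05 -> 0.1 and -0.05 -> -0.1.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class UnionFind:
    """Disjoint-set forest over integer indices 0..n-1."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:  # path compression
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1

    def groups(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for i in range(len(self.parent)):
            out.setdefault(self.find(i), []).append(i)
        return out
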