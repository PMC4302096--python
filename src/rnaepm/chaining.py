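"""Chaining: the best non-crossing, non-overlapping subset of EPMs.

Two EPMs are compatible — can occur in one alignment — iff their merged
matches still form a non-crossing matching and their merged structures
stay non-crossing on both sides.  Any compatible set then decomposes
into blocks that are either strictly sequential or nested inside one
another's *holes* (the rectangular gap regions between consecutive
matched positions of an EPM; every internal gap of a connected EPM is
bridged by one of its base pairs, so nesting is always hole-respecting).

The chaining algorithm exploits this: the weight of an EPM is its score
plus the optimal chain of every hole, computed recursively with one
chaining pass per distinct hole rectangle, and sequential blocks are
combined by classical sparse chaining.  Complexity is governed by the
number of holes times the per-region pass, with the optional per-end
pre-filter keeping the EPM count E in check.
"""

from __future__ import annotations

from dataclasses import dataclass

from .epm import Epm
from .sequence import InputError

__all__ = ["Chain", "chain_epms", "coverage", "compatible", "holes_of"]


@dataclass(frozen=True)
class Chain:
    epms: tuple
    total_score: float
    coverage: float = 0.0

    def __len__(self) -> int:
        return len(self.epms)

    @property
    def matches(self) -> frozenset:
        return frozenset(m for e in self.epms for m in e.M)


def compatible(e1: Epm, e2: Epm) -> bool:
    """Merged matching/non-crossing test on all Def-1 pairwise conditions."""
    if e1.positions_a() & e2.positions_a() or e1.positions_b() & e2.positions_b():
        return False  # overlapping matched positions (incl. shared matches)
    M = e1.M | e2.M
    ms = sorted(M)
    for t in range(len(ms) - 1):
        if ms[t][1] >= ms[t + 1][1]:
            return False
    for side in (0, 1):
        pairs = sorted(
            {(s[0 + 2 * side], s[1 + 2 * side]) for s in e1.S | e2.S}
        )
        pos = [p for pr in pairs for p in pr]
        if len(pos) != len(set(pos)):
            return False
        for x in range(len(pairs)):
            for y in range(x + 1, len(pairs)):
                (i, j), (a, b) = pairs[x], pairs[y]
                if i < a < j < b:
                    return False
    return True


def holes_of(epm: Epm) -> list:
    """Rectangular gap regions between consecutive matches of the EPM."""
    ms = sorted(epm.M)
    out = []
    for t in range(len(ms) - 1):
        (p, q), (p2, q2) = ms[t], ms[t + 1]
        if p2 - p > 1 and q2 - q > 1:
            out.append((p + 1, p2 - 1, q + 1, q2 - 1))
    return out


def coverage(chain: Chain, lenA: int, lenB: int) -> float:
    """Fraction of the shorter sequence matched by the chain."""
    if lenA <= 0 or lenB <= 0:
        raise InputError("coverage undefined for zero-length sequences")
    return sum(len(e.M) for e in chain.epms) / min(lenA, lenB)


def chain_epms(
    epms,
    n: int,
    m: int,
    *,
    e_cap: int | None = None,
) -> Chain:
    """Maximum-total-score compatible subset of the given EPMs.

    Ties prefer fewer EPMs, then the earliest candidates in canonical
    order.  When more than ``e_cap`` EPMs arrive (default 10*(n+m)) only
    the best EPM per end-position pair is kept first.
    """
    epms = list(epms)
    for e in epms:
        for (i, k) in e.M:
            if not (1 <= i <= n and 1 <= k <= m):
                raise InputError(f"EPM position {i}~{k} outside sequences")
    cap = e_cap if e_cap is not None else 10 * (n + m)
    if len(epms) > cap:
        best_per_end: dict = {}
        for e in epms:
            end = e.end()
            cur = best_per_end.get(end)
            if cur is None or e.score > cur.score:
                best_per_end[end] = e
        epms = list(best_per_end.values())
    epms.sort(key=lambda e: (sorted(e.M), sorted(e.S)))
    if not epms:
        return Chain(epms=(), total_score=0.0, coverage=0.0)

    spans = []
    for e in epms:
        ms = sorted(e.M)
        spans.append((ms[0][0], ms[-1][0], ms[0][1], ms[-1][1]))

    weight_memo: dict = {}
    region_memo: dict = {}

    def weight(idx: int):
        """(weight, selected-descendant indices) of EPM idx with holes filled."""
        got = weight_memo.get(idx)
        if got is None:
            total = epms[idx].score
            inside: list = []
            for hole in holes_of(epms[idx]):
                hv, hsel = chain_region(hole)
                total += hv
                inside.extend(hsel)
            got = (total, tuple(inside))
            weight_memo[idx] = got
        return got

    def chain_region(region):
        """Best chain of EPMs fully inside the rectangle (a1,a2,b1,b2)."""
        got = region_memo.get(region)
        if got is not None:
            return got
        a1, a2, b1, b2 = region
        cand = [
            t
            for t, (lo_a, hi_a, lo_b, hi_b) in enumerate(spans)
            if a1 <= lo_a and hi_a <= a2 and b1 <= lo_b and hi_b <= b2
        ]
        # sequential chaining over candidate blocks, holes filled via weight()
        best_end: dict = {}  # idx -> (score, -count, chosen tuple)
        order = sorted(cand, key=lambda t: (spans[t][1], spans[t][3], t))
        for t in order:
            w, inside = weight(t)
            base = (0.0, 0, ())
            for u in order:
                if u == t:
                    break
                if spans[u][1] < spans[t][0] and spans[u][3] < spans[t][2]:
                    val = best_end[u]
                    if (val[0], val[1]) > (base[0], base[1]):
                        base = val
            chosen = base[2] + (t,) + inside
            best_end[t] = (base[0] + w, base[1] - 1 - len(inside), chosen)
        best = (0.0, 0, ())
        for t in order:
            val = best_end[t]
            if (val[0], val[1]) > (best[0], best[1]):
                best = val
        region_memo[region] = (best[0], best[2])
        return region_memo[region]

    total, sel = chain_region((1, n, 1, m))
    chosen = sorted(set(sel), key=lambda t: sorted(epms[t].M))
    chain = Chain(
        epms=tuple(epms[t] for t in chosen),
        total_score=float(sum(epms[t].score for t in chosen)),
        coverage=0.0,
    )
    return Chain(
        epms=chain.epms,
        total_score=chain.total_score,
        coverage=coverage(chain, n, m),
    )


def anchor_matches(chain: Chain) -> list:
    """All matched position pairs of the chain, left to right."""
    return sorted(chain.matches)
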