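"""Sparsified dynamic programming over significant base-pair matches.

For every pair of significant base pairs (i,j) of A and (k,l) of B, a
family of contracted matrices scores the best EPM enclosed by the
base-pair match ij~kl:

* ``L``   — EPM connected to the left end (empty or containing i+1~k+1),
            ending at j'~l';
* ``G_A`` — the same after skipping (gapping) positions of A, B ending
            exactly at l';
* ``G_AB``— after additionally (or only) skipping positions of B;
* ``LR``  — two sub-EPMs separated by a gap, the second ending at j'~l'
            (finite entries are reachable only through the gap matrices);
* ``H``   — transient best-gap-state buffer, never stored;
* ``D``   — tau(i,j,k,l) plus the best completed inner combination;
* ``F``   — best significant EPM of the prefixes ending at j'~l'
            (external elements, so only theta1 applies).

Matrix rows/columns exist only at candidate positions: j' is a candidate
of (i,j) if it is a probable unpaired loop member (theta2) or the end of
a probable loop helix (theta3).  All other entries are provably -inf or
skippable, which bounds total work by the candidate counts (the
quadratic-complexity argument).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from .ensemble import EnsembleProbs
from .epm import tau
from .params import NEG_INF, Params, is_neg_inf
from .sequence import RnaSequence

__all__ = [
    "significant_pairs",
    "build_candidates",
    "CandidateIndex",
    "LoopMatrices",
    "SparseDpState",
    "fill_dp",
]


def significant_pairs(
    probs: EnsembleProbs, theta1: float, *, per_position_cap: int = 50
) -> list:
    """Base pairs with probability >= theta1, sorted.

    With theta1 = 0 every pair of nonzero probability qualifies; a
    per-position cap (best pairs first) then guards against the dense
    worst case of fully permissive settings.
    """
    idx = np.argwhere(
        probs.bpp >= theta1 if theta1 > 0 else probs.bpp > 0.0
    )
    pairs = [(int(i), int(j)) for i, j in idx if i < j]
    if theta1 == 0 and pairs:
        from collections import defaultdict

        count = defaultdict(int)
        kept = []
        for (i, j) in sorted(pairs, key=lambda p: -probs.bpp_at(*p)):
            if count[i] < per_position_cap and count[j] < per_position_cap:
                kept.append((i, j))
                count[i] += 1
                count[j] += 1
        pairs = kept
    return sorted(pairs)


@dataclass
class CandidateIndex:
    """Per significant pair: candidate positions and their reasons."""

    #: (i, j) -> sorted list of candidate positions j'
    positions: dict = field(default_factory=dict)
    #: (i, j) -> set of j' passing the unpaired (theta2) condition
    unpaired_ok: dict = field(default_factory=dict)
    #: (i, j) -> {j': [i', ...]} helix partners passing theta3
    helix_partners: dict = field(default_factory=dict)
    total_candidates: int = 0

    def of(self, pair) -> list:
        return self.positions.get(pair, [])


def build_candidates(
    probs: EnsembleProbs, theta1: float, theta2: float, theta3: float
) -> CandidateIndex:
    """Candidates of every significant pair, per the in-loop thresholds."""
    out = CandidateIndex()
    for pair in significant_pairs(probs, theta1):
        i, j = pair
        loop_u = probs.in_loop_unpaired.get(pair, {})
        loop_p = probs.in_loop_pair.get(pair, {})
        unp = {
            k
            for k, v in loop_u.items()
            if v >= theta2 and (theta2 > 0 or v > 0)
        }
        helix: dict = {}
        for (a, b), v in loop_p.items():
            if v >= theta3 and (theta3 > 0 or v > 0):
                helix.setdefault(b, []).append(a)
        for b in helix:
            helix[b].sort()
        cand = sorted(unp | set(helix))
        out.positions[pair] = cand
        out.unpaired_ok[pair] = unp
        out.helix_partners[pair] = helix
        out.total_candidates += len(cand)
    return out


# ---------------------------------------------------------------------------
# contracted matrices for one base-pair match


class LoopMatrices:
    """Contracted L / G_A / G_AB / LR for one base-pair match ij~kl.

    Rows are candidates of (i,j), columns candidates of (k,l); all other
    entries are provably -inf (a matched index must be a candidate) or
    pure skip states that resolve to the stored grid.  Lookups apply the
    empty-subsequence initialization implicitly:

    * ``L(i,k) = G_A(i,k) = G_AB(i,k) = 0``, ``LR(i,k) = -inf``;
    * first row: ``G_AB(i,l') = 0``, others -inf;
    * first column: ``G_A(j',k) = 0``, others -inf.

    ``G_A`` at any (x, y) is ``max(G_A, L)`` of the last candidate row
    before x; ``G_AB`` additionally takes the running maximum over the
    candidate columns before y (``glrun``), with the all-skipped state
    contributing 0.  ``H = max(G_A, G_AB)`` with the gapless origin (i,k)
    excluded, which is what forces every finite LR entry through a gap.
    """

    __slots__ = ("i", "j", "k", "l", "ca", "cb", "ia", "ib", "L", "GA", "LR", "glrun")

    def __init__(self, ij, kl, ca, cb):
        self.i, self.j = ij
        self.k, self.l = kl
        self.ca = ca
        self.cb = cb
        self.ia = {x: r for r, x in enumerate(ca)}
        self.ib = {y: c for c, y in enumerate(cb)}
        shape = (len(ca), len(cb))
        self.L = np.full(shape, NEG_INF)
        self.GA = np.full(shape, NEG_INF)
        self.LR = np.full(shape, NEG_INF)
        #: glrun[r, c] = max over c'' <= c of max(GA[r, c''], L[r, c''])
        self.glrun = np.full(shape, NEG_INF)

    # --- lookups with implicit initialization ---------------------------
    def l_at(self, x: int, y: int) -> float:
        if x == self.i and y == self.k:
            return 0.0
        r, c = self.ia.get(x), self.ib.get(y)
        if r is None or c is None:
            return NEG_INF
        return float(self.L[r, c])

    def lr_at(self, x: int, y: int) -> float:
        r, c = self.ia.get(x), self.ib.get(y)
        if r is None or c is None:
            return NEG_INF
        return float(self.LR[r, c])

    def _row_before(self, x: int):
        """Index of the last candidate row strictly before position x."""
        p = bisect_left(self.ca, x)
        return p - 1 if p else None

    def _col_before(self, y: int):
        p = bisect_left(self.cb, y)
        return p - 1 if p else None

    def ga_at(self, x: int, y: int) -> float:
        """G_A(x, y): left-anchored EPM, gap in A open, B ending at y."""
        if x < self.i or y < self.k:
            return NEG_INF
        if y == self.k:
            return 0.0  # empty B side: pure A-skip state
        c = self.ib.get(y)
        if c is None:
            return NEG_INF
        r = self._row_before(x)
        if r is None:
            return NEG_INF
        return float(max(self.GA[r, c], self.L[r, c]))

    def gab_at(self, x: int, y: int) -> float:
        """G_AB(x, y): gap in B open (possibly after a gap in A)."""
        if x < self.i or y <= self.k:
            return NEG_INF
        best = 0.0  # P1 empty, everything skipped
        c = self._col_before(y)
        if c is not None:
            r = self.ia.get(x)
            if r is None:
                r = self._row_before(x)
            if r is not None:
                best = max(best, float(self.glrun[r, c]))
        return best

    def h_at(self, x: int, y: int) -> float:
        """Best gap state at (x, y); the gapless origin (i, k) is excluded."""
        if x == self.i and y == self.k:
            return NEG_INF
        return max(self.ga_at(x, y), self.gab_at(x, y))

    def max_l(self) -> float:
        """Best left-anchored inner EPM, including the empty one (0)."""
        if self.L.size == 0:
            return 0.0
        return float(max(0.0, self.L.max()))

    @property
    def entries_written(self) -> int:
        # L, G_A, G_AB (as glrun) and LR per candidate pair
        return 4 * len(self.ca) * len(self.cb)


# ---------------------------------------------------------------------------
# DP state and fill


@dataclass
class SparseDpState:
    seqA: RnaSequence
    seqB: RnaSequence
    probsA: EnsembleProbs
    probsB: EnsembleProbs
    params: Params
    sig_a: list = field(default_factory=list)
    sig_b: list = field(default_factory=list)
    cand_a: CandidateIndex = None
    cand_b: CandidateIndex = None
    D: dict = field(default_factory=dict)  # ((i,j),(k,l)) -> score
    matrices: dict = field(default_factory=dict)
    F: np.ndarray = None
    entries_written: int = 0
    #: base-pair matches allowed through D (tau finite, both pairs significant)
    pairs_by_right_a: dict = field(default_factory=dict)
    pairs_by_right_b: dict = field(default_factory=dict)

    @property
    def max_f(self) -> float:
        return float(self.F.max()) if self.F is not None else 0.0

    def sparsity_ratio(self) -> float:
        return self.entries_written / (len(self.seqA) * len(self.seqB))

    def d_at(self, ij, kl) -> float:
        return self.D.get((ij, kl), NEG_INF)


def fill_dp(
    probsA: EnsembleProbs, probsB: EnsembleProbs, params: Params
) -> SparseDpState:
    """Fill all contracted loop matrices, D, and the final matrix F."""
    seqA = RnaSequence("A", probsA.residues)
    seqB = RnaSequence("B", probsB.residues)
    dp = SparseDpState(seqA, seqB, probsA, probsB, params)
    dp.sig_a = significant_pairs(probsA, params.theta1)
    dp.sig_b = significant_pairs(probsB, params.theta1)
    dp.cand_a = build_candidates(probsA, params.theta1, params.theta2, params.theta3)
    dp.cand_b = build_candidates(probsB, params.theta1, params.theta2, params.theta3)
    for (i, j) in dp.sig_a:
        dp.pairs_by_right_a.setdefault(j, []).append(i)
    for (k, l) in dp.sig_b:
        dp.pairs_by_right_b.setdefault(l, []).append(k)

    combos = [
        (pa, pb)
        for pa in dp.sig_a
        for pb in dp.sig_b
    ]
    combos.sort(key=lambda c: (c[0][1] - c[0][0]) + (c[1][1] - c[1][0]))
    for pa, pb in combos:
        _fill_one(dp, pa, pb)
    _fill_f(dp)
    return dp


def _fill_one(dp: SparseDpState, pa, pb) -> None:
    params = dp.params
    i, j = pa
    k, l = pb
    t = tau(i, j, k, l, dp.probsA, dp.probsB, params)
    if is_neg_inf(t):
        dp.D[(pa, pb)] = NEG_INF
        return
    ca = dp.cand_a.of(pa)
    cb = dp.cand_b.of(pb)
    mat = LoopMatrices(pa, pb, ca, cb)
    unp_a = dp.cand_a.unpaired_ok[pa]
    unp_b = dp.cand_b.unpaired_ok[pb]
    hel_a = dp.cand_a.helix_partners[pa]
    hel_b = dp.cand_b.helix_partners[pb]
    for r, x in enumerate(ca):
        pr = mat._row_before(x)
        if pr is not None:
            np.maximum(mat.GA[pr], mat.L[pr], out=mat.GA[r])
        for c, y in enumerate(cb):
            # L and LR: sequence-match case (theta2 on both sides)
            best_l = NEG_INF
            best_lr = NEG_INF
            if x in unp_a and y in unp_b and dp.seqA[x] == dp.seqB[y]:
                prev_l = mat.l_at(x - 1, y - 1)
                if not is_neg_inf(prev_l):
                    best_l = prev_l + 1.0
                gap_prev = max(mat.lr_at(x - 1, y - 1), mat.h_at(x - 1, y - 1))
                if not is_neg_inf(gap_prev):
                    best_lr = gap_prev + 1.0
            # structure-match case (theta3 on both sides, theta1 via D)
            for a in hel_a.get(x, ()):
                for b in hel_b.get(y, ()):
                    d = dp.D.get(((a, x), (b, y)), NEG_INF)
                    if is_neg_inf(d):
                        continue
                    prev_l = mat.l_at(a - 1, b - 1)
                    if not is_neg_inf(prev_l):
                        best_l = max(best_l, prev_l + d)
                    gap_prev = max(mat.lr_at(a - 1, b - 1), mat.h_at(a - 1, b - 1))
                    if not is_neg_inf(gap_prev):
                        best_lr = max(best_lr, gap_prev + d)
            mat.L[r, c] = best_l
            mat.LR[r, c] = best_lr
        np.maximum.accumulate(np.maximum(mat.GA[r], mat.L[r]), out=mat.glrun[r])
    inner = max(mat.max_l(), mat.lr_at(j - 1, l - 1))
    # stacking case: directly nested base-pair match completes the loop
    nested = dp.D.get(((i + 1, j - 1), (k + 1, l - 1)), NEG_INF)
    if (
        not is_neg_inf(nested)
        and (i + 1) in hel_a.get(j - 1, ())
        and (k + 1) in hel_b.get(l - 1, ())
    ):
        c_sta = dp.probsA.stacked_at(i, j) + dp.probsB.stacked_at(k, l)
        inner = max(inner, nested + params.alpha3 * c_sta)
    dp.D[(pa, pb)] = t + max(inner, 0.0)
    dp.matrices[(pa, pb)] = mat
    dp.entries_written += mat.entries_written


def _fill_f(dp: SparseDpState) -> None:
    n, m = len(dp.seqA), len(dp.seqB)
    F = np.zeros((n + 1, m + 1))
    ra, rb = dp.pairs_by_right_a, dp.pairs_by_right_b
    A, B = dp.seqA.residues, dp.seqB.residues
    for x in range(1, n + 1):
        lefts_a = ra.get(x, ())
        for y in range(1, m + 1):
            best = F[x - 1, y - 1] + 1.0 if A[x - 1] == B[y - 1] else 0.0
            if lefts_a:
                for a in lefts_a:
                    for b in rb.get(y, ()):
                        d = dp.D.get(((a, x), (b, y)), NEG_INF)
                        if not is_neg_inf(d):
                            v = F[a - 1, b - 1] + d
                            if v > best:
                                best = v
            F[x, y] = best
    dp.F = F
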