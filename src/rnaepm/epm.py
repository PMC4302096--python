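"""Exact pattern matchings (EPMs): the matched motifs themselves.

An EPM is a pair (M, S): position matches ``i ~ k`` between sequences A
and B together with base-pair matches ``ij ~ kl``.  It must be a
matching, non-crossing on both sides, contain the endpoints of every
base-pair match, keep both induced structures non-crossing, and be
connected through backbone adjacency or base-pair bonds.  Strict EPMs
require all matched bases identical; relaxed EPMs allow mismatches at
structure-match positions only (compensatory mutations).

The score sums sigma over sequence matches and tau over base-pair
matches; the stacking reward enters tau only when the directly nested
base-pair match is itself part of the EPM.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .ensemble import EnsembleProbs, psi
from .params import NEG_INF, Params, is_neg_inf, sadd
from .sequence import RnaSequence

__all__ = [
    "Epm",
    "sigma",
    "tau",
    "epm_score",
    "validate_epm",
    "ValidationReport",
    "is_significant",
    "includes",
    "parent_map",
    "extension_exists",
]

BpMatch = tuple  # (i, j, k, l): base pair (i, j) in A matched to (k, l) in B
Match = tuple  # (i, k): position i in A matched to k in B


@dataclass(frozen=True)
class Epm:
    """A pattern matching with mode and score; hashable and canonical."""

    M: frozenset
    S: frozenset
    mode: str = "strict"
    score: float = 0.0

    @property
    def structure_matches(self) -> frozenset:
        return frozenset(
            m for (i, j, k, l) in self.S for m in ((i, k), (j, l))
        )

    @property
    def sequence_matches(self) -> frozenset:
        return self.M - self.structure_matches

    def positions_a(self) -> frozenset:
        return frozenset(i for (i, _) in self.M)

    def positions_b(self) -> frozenset:
        return frozenset(k for (_, k) in self.M)

    def end(self) -> Match:
        """Rightmost match (simultaneously rightmost in A and B)."""
        return max(self.M)

    def key(self):
        """Canonical identity ignoring mode and score."""
        return (tuple(sorted(self.M)), tuple(sorted(self.S)))

    def sort_key(self):
        """Deterministic output order: score desc, then leftmost ends."""
        return (-self.score, tuple(sorted(self.M)), tuple(sorted(self.S)))

    def with_score(self, score: float) -> "Epm":
        return replace(self, score=score)

    def __len__(self) -> int:
        return len(self.M)


# ---------------------------------------------------------------------------
# scoring


def sigma(seqA: RnaSequence, seqB: RnaSequence, i: int, k: int) -> float:
    """Sequence-match score: 1 for identical bases, forbidden otherwise."""
    return 1.0 if seqA[i] == seqB[k] else NEG_INF


def tau(
    i: int,
    j: int,
    k: int,
    l: int,
    probsA: EnsembleProbs,
    probsB: EnsembleProbs,
    params: Params,
    *,
    with_stacking: bool = False,
) -> float:
    """Base-pair-match score.

    alpha1 weighs the two end matches (str_mm per mismatched end; -inf in
    strict mode, which forbids mismatches entirely), alpha2 the base-pair
    probabilities, and alpha3 the stacked-pair probabilities — the latter
    only when the directly nested base-pair match belongs to the EPM
    (``with_stacking``).
    """
    seqA, seqB = probsA.residues, probsB.residues

    def c_seq(x: int, y: int) -> float:
        return 1.0 if seqA[x - 1] == seqB[y - 1] else params.str_mm

    left, right = c_seq(i, k), c_seq(j, l)
    if is_neg_inf(left) or is_neg_inf(right):
        return NEG_INF
    score = params.alpha1 * (left + right) + params.alpha2 * (
        probsA.bpp_at(i, j) + probsB.bpp_at(k, l)
    )
    if with_stacking:
        score += params.alpha3 * (
            probsA.stacked_at(i, j) + probsB.stacked_at(k, l)
        )
    return score


def epm_score(
    epm: Epm, probsA: EnsembleProbs, probsB: EnsembleProbs, params: Params
) -> float:
    """Total EPM score: sigma over sequence matches, tau over S."""
    seqA = RnaSequence("A", probsA.residues)
    seqB = RnaSequence("B", probsB.residues)
    total = 0.0
    for (i, k) in epm.sequence_matches:
        total = sadd(total, sigma(seqA, seqB, i, k))
    for (i, j, k, l) in epm.S:
        stacked = (i + 1, j - 1, k + 1, l - 1) in epm.S
        total = sadd(
            total, tau(i, j, k, l, probsA, probsB, params, with_stacking=stacked)
        )
    return total


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    violated: str | None = None

    def __bool__(self) -> bool:
        return self.ok


def _structure_noncrossing(pairs) -> bool:
    pos = [p for pr in pairs for p in pr]
    if len(pos) != len(set(pos)):
        return False
    ps = sorted(pairs)
    for x in range(len(ps)):
        for y in range(x + 1, len(ps)):
            (i, j), (a, b) = ps[x], ps[y]
            if i < a < j < b:
                return False
    return True


def validate_epm(
    M, S, seqA: RnaSequence, seqB: RnaSequence, mode: str = "strict"
) -> ValidationReport:
    """Check all pattern-matching conditions plus the mode's base identity.

    Returns a report naming the first violated condition; an empty EPM is
    valid (and scores 0).
    """
    M = frozenset(tuple(m) for m in M)
    S = frozenset(tuple(s) for s in S)
    for (i, k) in M:
        if not (1 <= i <= len(seqA) and 1 <= k <= len(seqB)):
            return ValidationReport(False, "position out of range")
    # 1: matching
    for (i, k) in M:
        for (j, l) in M:
            if (i == j) != (k == l):
                return ValidationReport(False, "not a matching")
    # 2: non-crossing matches
    for (i, k) in M:
        for (j, l) in M:
            if i < j and not k < l:
                return ValidationReport(False, "crossing matches")
    # 3: S endpoints contained in M
    for (i, j, k, l) in S:
        if not (i < j and k < l):
            return ValidationReport(False, "degenerate base-pair match")
        if (i, k) not in M or (j, l) not in M:
            return ValidationReport(False, "base-pair match ends not matched")
    # 4: induced structures non-crossing
    if not _structure_noncrossing({(i, j) for (i, j, _, _) in S}):
        return ValidationReport(False, "crossing structure in A")
    if not _structure_noncrossing({(k, l) for (_, _, k, l) in S}):
        return ValidationReport(False, "crossing structure in B")
    # 5: connectivity
    if M and not _connected(M, S):
        return ValidationReport(False, "not connected")
    # base identity per mode
    struct = frozenset(m for (i, j, k, l) in S for m in ((i, k), (j, l)))
    for (i, k) in M:
        if seqA[i] != seqB[k]:
            if mode == "strict" or (i, k) not in struct:
                return ValidationReport(False, f"base mismatch at {i}~{k}")
    return ValidationReport(True)


def _connected(M: frozenset, S: frozenset) -> bool:
    adj = {m: set() for m in M}
    for (i, k) in M:
        if (i + 1, k + 1) in adj:
            adj[(i, k)].add((i + 1, k + 1))
            adj[(i + 1, k + 1)].add((i, k))
    for (i, j, k, l) in S:
        adj[(i, k)].add((j, l))
        adj[(j, l)].add((i, k))
    start = next(iter(M))
    seen = {start}
    stack = [start]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(M)


# ---------------------------------------------------------------------------
# parents, significance, inclusion order


def parent_map(epm: Epm, n: int, m: int) -> dict:
    """Parent base-pair match of every match and base-pair match.

    The parent of a match i~k is the smallest-span base-pair match whose
    A-pair satisfies i' <= i <= j' (an endpoint's parent is its own
    base-pair match); the parent of a base-pair match requires strict
    enclosure.  The pseudo match psi = (0, n+1, 0, m+1) covers the rest.
    """
    psi_match = (0, n + 1, 0, m + 1)
    by_span = sorted(epm.S, key=lambda s: s[1] - s[0])
    parents = {}
    for (i, k) in epm.M:
        parents[(i, k)] = next(
            (s for s in by_span if s[0] <= i <= s[1]), psi_match
        )
    for (i, j, k, l) in epm.S:
        parents[(i, j, k, l)] = next(
            (s for s in by_span if s[0] < i and j < s[1]), psi_match
        )
    return parents


def is_significant(
    epm: Epm, probsA: EnsembleProbs, probsB: EnsembleProbs, params: Params
) -> bool:
    """Re-check all significance thresholds directly against the ensembles."""
    n, m = probsA.n, probsB.n
    psi_match = (0, n + 1, 0, m + 1)
    parents = parent_map(epm, n, m)
    for (i, j, k, l) in epm.S:
        if probsA.bpp_at(i, j) < params.theta1 or probsB.bpp_at(k, l) < params.theta1:
            return False
        par = parents[(i, j, k, l)]
        if par != psi_match:
            pi, pj, pk, pl = par
            if probsA.loop_pair((i, j), (pi, pj)) < params.theta3:
                return False
            if probsB.loop_pair((k, l), (pk, pl)) < params.theta3:
                return False
    struct = epm.structure_matches
    for (i, k) in epm.M:
        if (i, k) in struct:
            continue
        par = parents[(i, k)]
        if par != psi_match:
            pi, pj, pk, pl = par
            if probsA.loop_unpaired(i, (pi, pj)) < params.theta2:
                return False
            if probsB.loop_unpaired(k, (pk, pl)) < params.theta2:
                return False
    return True


def includes(p: Epm, q: Epm, n: int, m: int, pp=None, pq=None) -> bool:
    """Inclusion order: p is included in q (p 'sqsubseteq' q).

    Requires M_p a subset of M_q with every shared match keeping the same
    parent base-pair match.  Precomputed parent maps may be passed for
    bulk comparisons.
    """
    if not p.M <= q.M:
        return False
    pp = pp if pp is not None else parent_map(p, n, m)
    pq = pq if pq is not None else parent_map(q, n, m)
    return all(pp[mt] == pq[mt] for mt in p.M)


# ---------------------------------------------------------------------------
# single-step extensions (maximality witness search)


def extension_exists(
    epm: Epm,
    seqA: RnaSequence,
    seqB: RnaSequence,
    probsA: EnsembleProbs,
    probsB: EnsembleProbs,
    params: Params,
    *,
    exact_only: bool = True,
) -> bool:
    """Is there a valid, significant one-step extension including this EPM?

    Candidate steps: one exact sequence match backbone-adjacent to the
    EPM, or one base-pair match (with its endpoint matches) attached to
    the EPM, that leaves every existing match's parent unchanged.  For a
    non-maximal EPM such a witness always exists: the elements of any
    strictly larger comparable EPM can be added outermost-first without
    re-parenting, so the first added element is itself a witness.
    ``exact_only`` restricts base-pair-match steps to identical end bases
    (the strict-mode test, and step one of the relaxed filter).
    """
    n, m = len(seqA), len(seqB)
    posA, posB = epm.positions_a(), epm.positions_b()
    mode = epm.mode  # existing mismatches stay legal; exact_only governs
    # only the bases of the added element

    def try_ext(M2, S2) -> bool:
        if not validate_epm(M2, S2, seqA, seqB, mode):
            return False
        cand = Epm(M=frozenset(M2), S=frozenset(S2), mode=mode)
        if not is_significant(cand, probsA, probsB, params):
            return False
        return includes(epm, cand, n, m)

    # (a) adjacent exact sequence match
    for (i, k) in epm.M:
        for (x, y) in ((i + 1, k + 1), (i - 1, k - 1)):
            if not (1 <= x <= n and 1 <= y <= m):
                continue
            if x in posA or y in posB:
                continue
            if seqA[x] != seqB[y]:
                continue
            if try_ext(epm.M | {(x, y)}, epm.S):
                return True
    # (b) a base-pair match whose endpoints are in, or adjacent to, the EPM
    def endpoint_ok(x: int, y: int):
        """(usable, attaches) for one prospective endpoint match x~y."""
        if (x, y) in epm.M:
            return True, True
        if x in posA or y in posB:
            return False, False  # collides with a different match
        adjacent = (x + 1, y + 1) in epm.M or (x - 1, y - 1) in epm.M
        return True, adjacent

    sig_a = _sig_pairs(probsA, params.theta1)
    sig_b = _sig_pairs(probsB, params.theta1)
    for (i, j) in sig_a:
        for (k, l) in sig_b:
            if (i, j, k, l) in epm.S:
                continue
            if exact_only and (seqA[i] != seqB[k] or seqA[j] != seqB[l]):
                continue
            ok_l, att_l = endpoint_ok(i, k)
            ok_r, att_r = endpoint_ok(j, l)
            if not (ok_l and ok_r and (att_l or att_r)):
                continue
            if try_ext(epm.M | {(i, k), (j, l)}, epm.S | {(i, j, k, l)}):
                return True
    return False


def _sig_pairs(probs: EnsembleProbs, theta1: float):
    import numpy as np

    idx = np.argwhere(probs.bpp >= max(theta1, 1e-300))
    return [(int(i), int(j)) for i, j in idx if i < j]
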