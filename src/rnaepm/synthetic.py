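"""Seeded generators and exhaustive oracles.

Everything here exists so the matcher is testable without external data:
random sequences, implanted hairpin motifs with known ground truth, and
brute-force enumeration of EPMs and chains at small problem sizes.  The
oracles restate the definitions by exhaustive search and share nothing
with the dynamic program except the pure scoring functions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .ensemble import EnsembleProbs, legal_pairs
from .epm import Epm, epm_score, includes, is_significant, validate_epm
from .params import Params, is_neg_inf
from .sequence import InputError, RnaSequence

__all__ = [
    "random_sequence",
    "MotifSpec",
    "implant_motif",
    "enumerate_epms",
    "maximal_strict",
    "maximal_relaxed",
    "brute_force_chain",
]

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def random_sequence(
    length: int, gc_content: float = 0.5, seed: int = 0, id: str = "random"
) -> RnaSequence:
    """Uniformly random sequence with the given expected GC content."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must lie in [0, 1]")
    rng = random.Random(seed)
    g = gc_content / 2.0
    a = (1.0 - gc_content) / 2.0
    bases = rng.choices("GCAU", weights=[g, g, a, a], k=length)
    return RnaSequence(id, "".join(bases))


@dataclass(frozen=True)
class MotifSpec:
    """A hairpin motif: stem of ``stem`` base pairs enclosing a loop."""

    stem: int = 6
    loop: int = 4
    loop_policy: str = "fixed"  # "fixed" (GAAA-style) or "random"
    offset_a: int = 10
    offset_b: int = 10

    @property
    def length(self) -> int:
        return 2 * self.stem + self.loop


def implant_motif(
    seqA: RnaSequence, seqB: RnaSequence, spec: MotifSpec, seed: int = 0
):
    """Implant one identical hairpin motif into both sequences.

    Returns the modified sequences and the ground-truth position matches
    (1-based) for downstream recovery scoring.
    """
    rng = random.Random(seed)
    if spec.loop_policy == "fixed":
        loop_seq = ("GAAA" * (spec.loop // 4 + 1))[: spec.loop]
    else:
        loop_seq = "".join(rng.choice("ACGU") for _ in range(spec.loop))
    stem5 = "".join(rng.choice("ACGU") for _ in range(spec.stem))
    stem3 = "".join(_COMP[b] for b in reversed(stem5))
    motif = stem5 + loop_seq + stem3
    for off, seq in ((spec.offset_a, seqA), (spec.offset_b, seqB)):
        if off < 0 or off + spec.length > len(seq):
            raise ValueError("motif does not fit at the given offset")
    resA = seqA.residues[: spec.offset_a] + motif + seqA.residues[
        spec.offset_a + spec.length:
    ]
    resB = seqB.residues[: spec.offset_b] + motif + seqB.residues[
        spec.offset_b + spec.length:
    ]
    truth = frozenset(
        (spec.offset_a + t + 1, spec.offset_b + t + 1) for t in range(spec.length)
    )
    return RnaSequence(seqA.id, resA), RnaSequence(seqB.id, resB), truth


# ---------------------------------------------------------------------------
# exhaustive EPM enumeration


def enumerate_epms(
    seqA: RnaSequence,
    seqB: RnaSequence,
    probsA: EnsembleProbs,
    probsB: EnsembleProbs,
    params: Params,
    *,
    cap: int = 12,
    max_epms: int = 500_000,
) -> list:
    """All significant relaxed-valid EPMs with scores (exhaustive oracle).

    Grows connected matchings one unit at a time — an exact adjacent
    sequence match, or a base-pair match together with its endpoint
    matches — starting from all single-unit seeds; every connected EPM is
    reachable this way because the units of any EPM can be added in a
    spanning-tree order.  Then filters by Def-5 significance under the
    given thresholds and scores the survivors.

    Returns a list of `Epm` (mode "relaxed"); strict EPMs are the subset
    with all matched bases identical (`maximal_strict` handles that).
    """
    n, m = len(seqA), len(seqB)
    if n > cap or m > cap:
        raise InputError(f"sequence lengths {n},{m} above oracle cap {cap}")
    # exact prefilter: a significant EPM can only use pairs with
    # bpp >= theta1 (Def-5 condition 1 is parent-independent)
    pa = [
        p for p in legal_pairs(seqA, probsA.model)
        if probsA.bpp_at(*p) >= params.theta1
    ]
    pb = [
        p for p in legal_pairs(seqB, probsB.model)
        if probsB.bpp_at(*p) >= params.theta1
    ]
    exact = [
        (i, k)
        for i in range(1, n + 1)
        for k in range(1, m + 1)
        if seqA[i] == seqB[k]
    ]

    def crossing_ok(M, x, y) -> bool:
        return all((i < x) == (k < y) and i != x and k != y for (i, k) in M)

    def pairs_ok(S_a, i, j) -> bool:
        for (a, b) in S_a:
            if len({a, b, i, j}) < 4:
                return False
            if a < i < b < j or i < a < j < b:
                return False
        return True

    seen = set()
    frontier = []

    def push(M, S):
        key = (frozenset(M), frozenset(S))
        if key not in seen:
            seen.add(key)
            frontier.append(key)
            if len(seen) > max_epms:
                raise InputError("EPM enumeration exploded beyond max_epms")

    for (i, k) in exact:
        push({(i, k)}, set())
    for (i, j) in pa:
        for (k, l) in pb:
            if crossing_ok({(i, k)}, j, l):
                push({(i, k), (j, l)}, {(i, j, k, l)})

    idx = 0
    while idx < len(frontier):
        M, S = frontier[idx]
        idx += 1
        posA = {i for (i, _) in M}
        posB = {k for (_, k) in M}
        # (a) adjacent exact sequence match
        for (i, k) in M:
            for (x, y) in ((i + 1, k + 1), (i - 1, k - 1)):
                if 1 <= x <= n and 1 <= y <= m and (x, y) in _free(
                    exact, posA, posB
                ) and crossing_ok(M, x, y):
                    push(M | {(x, y)}, S)
        # (b) one base-pair unit
        s_a = {(i, j) for (i, j, _, _) in S}
        s_b = {(k, l) for (_, _, k, l) in S}
        for (i, j) in pa:
            for (k, l) in pb:
                if (i, j, k, l) in S:
                    continue
                new = []
                anchored = False
                ok = True
                for (x, y) in ((i, k), (j, l)):
                    if (x, y) in M:
                        anchored = True
                        continue
                    if x in posA or y in posB or not crossing_ok(M, x, y):
                        ok = False
                        break
                    if (x + 1, y + 1) in M or (x - 1, y - 1) in M:
                        anchored = True
                    new.append((x, y))
                if not ok or not anchored:
                    continue
                if len(new) == 2 and (
                    not ((new[0][0] < new[1][0]) == (new[0][1] < new[1][1]))
                ):
                    continue
                if not pairs_ok(s_a, i, j) or not pairs_ok(s_b, k, l):
                    continue
                push(M | {(i, k), (j, l)}, S | {(i, j, k, l)})

    out = []
    for (M, S) in seen:
        epm = Epm(M=M, S=S, mode="relaxed")
        assert validate_epm(M, S, seqA, seqB, "relaxed")
        if not is_significant(epm, probsA, probsB, params):
            continue
        score = epm_score(epm, probsA, probsB, params)
        if is_neg_inf(score):
            continue
        out.append(epm.with_score(score))
    out.sort(key=lambda e: e.sort_key())
    return out


def _free(exact, posA, posB):
    return {(x, y) for (x, y) in exact if x not in posA and y not in posB}


def _is_strict(epm: Epm, seqA: RnaSequence, seqB: RnaSequence) -> bool:
    return all(seqA[i] == seqB[k] for (i, k) in epm.M)


def maximal_strict(epms, seqA, seqB, n=None, m=None) -> list:
    """Maximal significant strict EPMs by pairwise inclusion (Def-6 style)."""
    from .epm import parent_map

    n = n or len(seqA)
    m = m or len(seqB)
    strict = [e for e in epms if _is_strict(e, seqA, seqB)]
    parents = [parent_map(e, n, m) for e in strict]
    out = []
    for a, e in enumerate(strict):
        dominated = False
        for b, f in enumerate(strict):
            if b == a or len(f.M) <= len(e.M):
                continue
            if includes(e, f, n, m, pp=parents[a], pq=parents[b]):
                dominated = True
                break
        if not dominated:
            out.append(e)
    return out


def maximal_relaxed(epms, n, m) -> list:
    """Maximal relaxed EPMs under the score-inclusion order (Def-7 style)."""
    from .epm import parent_map

    epms = list(epms)
    parents = [parent_map(e, n, m) for e in epms]
    out = []
    for a, e in enumerate(epms):
        dominated = False
        for b, f in enumerate(epms):
            if f.score > e.score and (
                includes(e, f, n, m, pp=parents[a], pq=parents[b])
                or includes(f, e, n, m, pp=parents[b], pq=parents[a])
            ):
                dominated = True
                break
        if not dominated:
            out.append(e)
    return out


# ---------------------------------------------------------------------------
# exhaustive chaining


def _merged_ok(e1: Epm, e2: Epm) -> bool:
    """Can both EPMs occur in one alignment? (matching, non-crossing)."""
    if e1.positions_a() & e2.positions_a() or e1.positions_b() & e2.positions_b():
        return False  # overlap in matched positions (shared matches included)
    M = e1.M | e2.M
    ms = sorted(M)
    for t in range(len(ms) - 1):
        if ms[t][1] >= ms[t + 1][1]:
            return False
    for side in (0, 1):
        pairs = sorted(
            {(s[0 + 2 * side], s[1 + 2 * side]) for s in e1.S | e2.S}
        )
        seen_pos = [p for pr in pairs for p in pr]
        if len(seen_pos) != len(set(seen_pos)):
            return False
        for x in range(len(pairs)):
            for y in range(x + 1, len(pairs)):
                (i, j), (a, b) = pairs[x], pairs[y]
                if i < a < j < b:
                    return False
    return True


def brute_force_chain(epms, cap: int = 12):
    """Best compatible subset by exhaustive search (oracle).

    Returns (best_score, best_subset as tuple of Epm).
    """
    if len(epms) > cap:
        raise InputError(f"{len(epms)} EPMs above brute-force cap {cap}")
    epms = list(epms)
    compat = {
        (a, b): _merged_ok(epms[a], epms[b])
        for a in range(len(epms))
        for b in range(a + 1, len(epms))
    }
    best = (0.0, ())
    chosen: list = []

    def rec(idx: int, score: float):
        nonlocal best
        if score > best[0]:
            best = (score, tuple(epms[t] for t in chosen))
        if idx == len(epms):
            return
        for nxt in range(idx, len(epms)):
            if all(compat[(p, nxt)] for p in chosen):
                chosen.append(nxt)
                rec(nxt + 1, score + epms[nxt].score)
                chosen.pop()

    rec(0, 0.0)
    return best
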