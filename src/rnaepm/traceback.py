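"""Enumerating EPMs from the filled DP.

The suboptimal traceback enumerates every significant EPM whose score
lies in the band ``[max(min_epm_score, opt - max_score_diff), opt]`` by
band-limited backtracking: an F-level skeleton fixes the external
matches and the enclosing base-pair matches (with their optimal D values
as placeholders), then each pending D matrix is expanded into its local
traces with the remaining slack shared along the way.  Tracebacks start
only from cells F(j', l') with A[j'+1] != B[l'+1] (or at a sequence
boundary): for strict EPMs this end condition is necessary and
sufficient for maximality, and for relaxed EPMs it is still necessary.

Maximality filtering is per mode: strict EPMs are kept iff no exact
one-step extension exists (decided independently per EPM); relaxed EPMs
pass the same exact-extension test first and the surviving set is then
thinned by the score-inclusion order (a higher-scoring comparable EPM
discards a lower-scoring one; equal scores keep both).
"""

from __future__ import annotations

from .dp import SparseDpState
from .epm import (
    Epm,
    epm_score,
    extension_exists,
    includes,
    is_significant,
    tau,
    validate_epm,
)
from .params import NEG_INF, Params, TracebackControls, is_neg_inf

__all__ = [
    "trace_suboptimal",
    "trace_heuristic",
    "is_maximal_strict",
    "filter_relaxed_maximal",
]

EPS = 1e-9


class TracebackError(RuntimeError):
    """An emitted EPM failed independent re-verification."""


# ---------------------------------------------------------------------------
# low-level enumeration


def _real_best_at(dp: SparseDpState, x: int, y: int) -> float:
    """Best score of an actual EPM ending at (x, y) (F without the 0 case)."""
    best = NEG_INF
    if dp.seqA[x] == dp.seqB[y]:
        best = float(dp.F[x - 1, y - 1]) + 1.0
    for a in dp.pairs_by_right_a.get(x, ()):
        for b in dp.pairs_by_right_b.get(y, ()):
            d = dp.D.get(((a, x), (b, y)), NEG_INF)
            if not is_neg_inf(d):
                best = max(best, float(dp.F[a - 1, b - 1]) + d)
    return best


def _skeletons_from(dp: SparseDpState, x: int, y: int, thr: float) -> list:
    """All F-level skeletons of EPMs ending at (x, y) with upper bound >= thr.

    A skeleton carries the external matches, the chosen outermost
    base-pair matches (as pending D references at their optimal value),
    and the resulting score upper bound.
    """
    out = []

    def rec(x, y, right, matches, smatches, pending):
        if dp.seqA[x] == dp.seqB[y]:
            r2 = right + 1.0
            m2 = matches | {(x, y)}
            if r2 >= thr - EPS:
                out.append((m2, smatches, pending, r2))
            if x > 1 and y > 1 and r2 + dp.F[x - 1, y - 1] >= thr - EPS:
                rec(x - 1, y - 1, r2, m2, smatches, pending)
        for a in dp.pairs_by_right_a.get(x, ()):
            for b in dp.pairs_by_right_b.get(y, ()):
                d = dp.D.get(((a, x), (b, y)), NEG_INF)
                if is_neg_inf(d):
                    continue
                r2 = right + d
                if r2 < thr - EPS and r2 + dp.F[a - 1, b - 1] < thr - EPS:
                    continue
                m2 = matches | {(a, b), (x, y)}
                s2 = smatches | {(a, x, b, y)}
                p2 = pending + (((a, x), (b, y)),)
                if r2 >= thr - EPS:
                    out.append((m2, s2, p2, r2))
                if a > 1 and b > 1 and r2 + dp.F[a - 1, b - 1] >= thr - EPS:
                    rec(a - 1, b - 1, r2, m2, s2, p2)
        return

    rec(x, y, 0.0, frozenset(), frozenset(), ())
    return out


def _l_paths(dp: SparseDpState, mat, x: int, y: int, need: float) -> list:
    """Decompositions of L(x, y): left-anchored inner EPMs ending at (x, y)."""
    pa, pb = (mat.i, mat.j), (mat.k, mat.l)
    unp_a = dp.cand_a.unpaired_ok[pa]
    unp_b = dp.cand_b.unpaired_ok[pb]
    hel_a = dp.cand_a.helix_partners[pa]
    hel_b = dp.cand_b.helix_partners[pb]
    out = []
    if x in unp_a and y in unp_b and dp.seqA[x] == dp.seqB[y]:
        prev = (x - 1, y - 1)
        if prev == (mat.i, mat.k):
            if 1.0 >= need - EPS:
                out.append((frozenset({(x, y)}), frozenset(), (), 1.0))
        elif 1.0 + mat.l_at(*prev) >= need - EPS:
            for (pm, ps, pp, psc) in _l_paths(dp, mat, *prev, need - 1.0):
                out.append((pm | {(x, y)}, ps, pp, psc + 1.0))
    for a in hel_a.get(x, ()):
        for b in hel_b.get(y, ()):
            d = dp.D.get(((a, x), (b, y)), NEG_INF)
            if is_neg_inf(d):
                continue
            unit_m = frozenset({(a, b), (x, y)})
            unit_s = frozenset({(a, x, b, y)})
            unit_p = (((a, x), (b, y)),)
            prev = (a - 1, b - 1)
            if prev == (mat.i, mat.k):
                if d >= need - EPS:
                    out.append((unit_m, unit_s, unit_p, d))
            elif d + mat.l_at(*prev) >= need - EPS:
                for (pm, ps, pp, psc) in _l_paths(dp, mat, *prev, need - d):
                    out.append((pm | unit_m, ps | unit_s, pp + unit_p, psc + d))
    return out


def _h_sources(mat, x: int, y: int):
    """P1 end candidates for a gap state at (x, y): (i,k) or an L entry
    at (x'', y'') <= (x, y) with at least one side strictly smaller."""
    yield (mat.i, mat.k)
    for xx in mat.ca:
        if xx > x:
            break
        for yy in mat.cb:
            if yy > y:
                break
            if (xx, yy) != (x, y) and not is_neg_inf(mat.l_at(xx, yy)):
                yield (xx, yy)


def _lr_paths(dp: SparseDpState, mat, x: int, y: int, need: float) -> list:
    """Decompositions of LR(x, y): gap-separated inner EPM pairs."""
    pa, pb = (mat.i, mat.j), (mat.k, mat.l)
    unp_a = dp.cand_a.unpaired_ok[pa]
    unp_b = dp.cand_b.unpaired_ok[pb]
    hel_a = dp.cand_a.helix_partners[pa]
    hel_b = dp.cand_b.helix_partners[pb]
    out = []

    def after_gap(prev, unit_m, unit_s, unit_p, unit_score):
        """P2 starts right after the gap state at `prev`."""
        if mat.h_at(*prev) + unit_score < need - EPS:
            return
        for src in _h_sources(mat, *prev):
            if src == (mat.i, mat.k):
                if unit_score >= need - EPS:
                    out.append((unit_m, unit_s, unit_p, unit_score))
            elif mat.l_at(*src) + unit_score >= need - EPS:
                for (pm, ps, pp, psc) in _l_paths(
                    dp, mat, *src, need - unit_score
                ):
                    out.append(
                        (pm | unit_m, ps | unit_s, pp + unit_p, psc + unit_score)
                    )

    if x in unp_a and y in unp_b and dp.seqA[x] == dp.seqB[y]:
        prev = (x - 1, y - 1)
        unit = (frozenset({(x, y)}), frozenset(), (), 1.0)
        if 1.0 + mat.lr_at(*prev) >= need - EPS:
            for (pm, ps, pp, psc) in _lr_paths(dp, mat, *prev, need - 1.0):
                out.append((pm | unit[0], ps, pp, psc + 1.0))
        after_gap(prev, *unit)
    for a in hel_a.get(x, ()):
        for b in hel_b.get(y, ()):
            d = dp.D.get(((a, x), (b, y)), NEG_INF)
            if is_neg_inf(d):
                continue
            unit = (
                frozenset({(a, b), (x, y)}),
                frozenset({(a, x, b, y)}),
                (((a, x), (b, y)),),
                d,
            )
            prev = (a - 1, b - 1)
            if d + mat.lr_at(*prev) >= need - EPS:
                for (pm, ps, pp, psc) in _lr_paths(dp, mat, *prev, need - d):
                    out.append((pm | unit[0], ps | unit[1], pp + unit[2], psc + d))
            after_gap(prev, *unit)
    return out


def _local_traces(dp: SparseDpState, pa, pb, need: float) -> list:
    """Inner decompositions of D(pa, pb) with score >= need.

    Each trace carries the closing base-pair match with its endpoint
    matches, the directly traced inner sequence matches, pending nested
    D references, and the trace score tau + sigma-sum + nested D values.
    """
    (i, j), (k, l) = pa, pb
    params = dp.params
    t0 = tau(i, j, k, l, dp.probsA, dp.probsB, params)
    if is_neg_inf(t0):
        return []
    base_m = frozenset({(i, k), (j, l)})
    base_s = frozenset({(i, j, k, l)})
    mat = dp.matrices.get((pa, pb))
    out = []
    if t0 >= need - EPS:
        out.append((base_m, base_s, (), t0))
    if mat is None:
        return out
    hel_a = dp.cand_a.helix_partners[pa]
    hel_b = dp.cand_b.helix_partners[pb]
    # stacking: the directly nested base-pair match closes the whole loop
    nested = ((i + 1, j - 1), (k + 1, l - 1))
    dnest = dp.D.get(nested, NEG_INF)
    if (
        not is_neg_inf(dnest)
        and (i + 1) in hel_a.get(j - 1, ())
        and (k + 1) in hel_b.get(l - 1, ())
    ):
        ts = tau(i, j, k, l, dp.probsA, dp.probsB, params, with_stacking=True)
        if ts + dnest >= need - EPS:
            out.append(
                (
                    base_m | {(i + 1, k + 1), (j - 1, l - 1)},
                    base_s | {(i + 1, j - 1, k + 1, l - 1)},
                    (nested,),
                    ts + dnest,
                )
            )
    # left-anchored inner EPM ending at any candidate entry
    for r, x in enumerate(mat.ca):
        for c, y in enumerate(mat.cb):
            lv = float(mat.L[r, c])
            if not is_neg_inf(lv) and t0 + lv >= need - EPS:
                for (pm, ps, pp, psc) in _l_paths(dp, mat, x, y, need - t0):
                    out.append((base_m | pm, base_s | ps, pp, t0 + psc))
    # gapped inner pair ending flush at (j-1, l-1)
    lrv = mat.lr_at(j - 1, l - 1)
    if not is_neg_inf(lrv) and t0 + lrv >= need - EPS:
        for (pm, ps, pp, psc) in _lr_paths(dp, mat, j - 1, l - 1, need - t0):
            out.append((base_m | pm, base_s | ps, pp, t0 + psc))
    return out


def _expand(dp: SparseDpState, skeletons, thr: float, *, collect) -> None:
    """Replace pending D placeholders by their local traces, sharing slack."""

    def rec(matches, smatches, pending, total):
        if not pending:
            collect(matches, smatches, total)
            return
        (pa, pb), rest = pending[0], pending[1:]
        dval = dp.D[(pa, pb)]
        need = dval - (total - thr)
        for (lm, ls, lp, lscore) in _local_traces(dp, pa, pb, need):
            rec(matches | lm, smatches | ls, rest + lp, total - dval + lscore)

    for (matches, smatches, pending, total) in skeletons:
        rec(matches, smatches, pending, total)


# ---------------------------------------------------------------------------
# public tracebacks


def _eligible_end(dp: SparseDpState, x: int, y: int) -> bool:
    """Lemma-style end condition: no exact match can follow at (x+1, y+1)."""
    n, m = len(dp.seqA), len(dp.seqB)
    if x == n or y == m:
        return True
    return dp.seqA[x + 1] != dp.seqB[y + 1]


def _verify(dp: SparseDpState, epm: Epm) -> Epm:
    """Independent re-verification of every emitted EPM."""
    report = validate_epm(epm.M, epm.S, dp.seqA, dp.seqB, epm.mode)
    if not report:
        raise TracebackError(f"traced EPM invalid: {report.violated}")
    if not is_significant(epm, dp.probsA, dp.probsB, dp.params):
        raise TracebackError("traced EPM fails significance re-check")
    true_score = epm_score(epm, dp.probsA, dp.probsB, dp.params)
    if abs(true_score - epm.score) > 1e-6:
        raise TracebackError(
            f"trace score {epm.score} != recomputed score {true_score}"
        )
    return epm


def trace_suboptimal(
    dp: SparseDpState,
    controls: TracebackControls | None = None,
    params: Params | None = None,
) -> list:
    """Enumerate maximal significant EPMs within the score band.

    Strict mode returns exactly the maximal EPMs in the band; relaxed
    mode returns all maximal ones and only rarely a non-maximal extra
    (one whose higher-scoring comparable partner lies outside the traced
    set), which downstream chaining tolerates.
    """
    params = params or dp.params
    controls = controls or params.traceback
    opt = dp.max_f
    thr = max(controls.min_epm_score, opt - controls.max_score_diff)
    n, m = len(dp.seqA), len(dp.seqB)
    found: dict = {}

    def collect(matches, smatches, total):
        epm = Epm(
            M=frozenset(matches),
            S=frozenset(smatches),
            mode=params.mode,
            score=total,
        )
        key = epm.key()
        prev = found.get(key)
        if prev is None or total > prev.score:
            found[key] = epm

    for x in range(1, n + 1):
        for y in range(1, m + 1):
            if not _eligible_end(dp, x, y):
                continue
            if _real_best_at(dp, x, y) < thr - EPS:
                continue
            _expand(dp, _skeletons_from(dp, x, y, thr), thr, collect=collect)

    epms = [_verify(dp, e) for e in found.values() if e.score >= thr - EPS]
    epms = _maximality_filter(dp, epms, params)
    epms.sort(key=lambda e: e.sort_key())
    return epms[: controls.max_epms]


def trace_heuristic(
    dp: SparseDpState,
    controls: TracebackControls | None = None,
    params: Params | None = None,
) -> list:
    """One optimal EPM per eligible end match (fast, non-exhaustive)."""
    params = params or dp.params
    controls = controls or params.traceback
    n, m = len(dp.seqA), len(dp.seqB)
    results = []
    cells = []
    for x in range(1, n + 1):
        for y in range(1, m + 1):
            if not _eligible_end(dp, x, y):
                continue
            best = _real_best_at(dp, x, y)
            if best >= max(controls.min_epm_score, EPS) - EPS:
                cells.append((best, x, y))
    cells.sort(key=lambda t: (-t[0], t[1], t[2]))
    for best, x, y in cells[: controls.max_epms]:
        got: list = []

        def collect(matches, smatches, total, _got=got, _best=best):
            if not _got and total >= _best - EPS:
                _got.append(
                    Epm(
                        M=frozenset(matches),
                        S=frozenset(smatches),
                        mode=params.mode,
                        score=total,
                    )
                )

        _expand(dp, _skeletons_from(dp, x, y, best), best, collect=collect)
        if got:
            results.append(_verify(dp, got[0]))
    results.sort(key=lambda e: e.sort_key())
    return results[: controls.max_epms]


# ---------------------------------------------------------------------------
# maximality


def is_maximal_strict(epm: Epm, dp: SparseDpState, seqA=None, seqB=None) -> bool:
    """No exact one-step extension with unchanged parents exists."""
    if epm.mode != "strict":
        raise ValueError("is_maximal_strict expects a strict EPM")
    seqA = seqA or dp.seqA
    seqB = seqB or dp.seqB
    return not extension_exists(
        epm, seqA, seqB, dp.probsA, dp.probsB, dp.params, exact_only=True
    )


def filter_relaxed_maximal(epms, n: int, m: int) -> list:
    """Drop EPMs dominated under the score-inclusion order within the group."""
    out = []
    for e in epms:
        dominated = any(
            f.score > e.score + EPS and (includes(e, f, n, m) or includes(f, e, n, m))
            for f in epms
        )
        if not dominated:
            out.append(e)
    return out


def _maximality_filter(dp: SparseDpState, epms, params: Params) -> list:
    n, m = len(dp.seqA), len(dp.seqB)
    kept = [
        e
        for e in epms
        if not extension_exists(
            e, dp.seqA, dp.seqB, dp.probsA, dp.probsB, params, exact_only=True
        )
    ]
    if params.mode == "relaxed":
        kept = filter_relaxed_maximal(kept, n, m)
    return kept
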