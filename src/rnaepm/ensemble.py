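"""Ensemble probabilities of a single RNA sequence.

Computes, under a lightweight loop-decomposed energy model, the Boltzmann
ensemble quantities that pattern matching needs:

* base-pair probabilities ``Pr[(i,j)]``,
* stacked-pair probabilities ``Pr[(i,j) and (i+1,j-1)]``,
* joint in-loop probabilities ``Pr[k in loop(i,j)]`` and
  ``Pr[(i',j') in loop(i,j)]`` — the probability that a structure contains
  the element *and* that its innermost enclosing ("parent") base pair is
  (i,j); the pseudo pair ``psi = (0, n+1)`` closes the exterior loop.

The inside recursion decomposes the region partition function into the
pair-closed part ``Qb`` and multiloop parts ``M`` (at least one outermost
helix), ``M1`` (exactly one helix) and the auxiliary ``M2`` (at least two
helices, needed to price multiloop closing constants correctly).  The
outside pass inverts this decomposition so that every loop's content can
be split around a distinguished element, which yields the joint in-loop
probabilities at no more than cubic time and quadratic space.

An exhaustive structure enumerator (`enumerate_structures`,
`probs_by_enumeration`) serves as the independent oracle for small n.
"""

from __future__ import annotations

import gzip
import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from .params import EnergyModel
from .sequence import InputError, RnaSequence

__all__ = [
    "psi",
    "EnsembleProbs",
    "compute_ensemble",
    "enumerate_structures",
    "count_structures",
    "structure_energy",
    "probs_by_enumeration",
    "cache_write",
    "cache_read",
    "CacheError",
]


def psi(n: int) -> tuple:
    """Pseudo base pair closing the exterior loop of a length-n sequence."""
    return (0, n + 1)


def _dp_dtype(n: int, model: EnergyModel):
    """Array dtype for partition functions.

    Weights grow like exp(c * n); when the worst-case exponent nears the
    float64 range the inside/outside pass runs in extended precision
    (x86 80-bit longdouble, ~1e4932) instead of rescaling the recursions.
    """
    if model.mode == "uniform":
        worst = n * math.log(2.0)  # structure count < 2^n
    else:
        emax = max(abs(v) for v in model.pair_energy.values()) + abs(model.stack_bonus)
        emax += max(
            abs(model.hairpin_const),
            abs(model.interior_const),
            abs(model.multiloop_const),
        )
        worst = (n / 2.0) * emax / model.RT
    return np.longdouble if worst > 600.0 else np.float64


def legal_pairs(seq: RnaSequence, model: EnergyModel) -> list:
    """All (i, j) that can pair: complementary with span > min_hairpin."""
    n = len(seq)
    return [
        (i, j)
        for i in range(1, n + 1)
        for j in range(i + model.min_hairpin + 1, n + 1)
        if seq.can_pair(i, j)
    ]


# ---------------------------------------------------------------------------
# container


@dataclass
class EnsembleProbs:
    """Sparse per-sequence ensemble probabilities (1-based coordinates).

    ``in_loop_unpaired[(i, j)][k]`` and ``in_loop_pair[(i, j)][(i', j')]``
    are keyed by parent pair, with the exterior parent stored under
    ``psi = (0, n+1)``.  Entries below the drop tolerance are absent and
    read as 0.
    """

    n: int
    residues: str
    model: EnergyModel
    bpp: np.ndarray  # (n+1, n+1), bpp[i, j] for i < j
    stacked: np.ndarray
    unpaired: np.ndarray  # (n+1,)
    in_loop_unpaired: dict = field(default_factory=dict)
    in_loop_pair: dict = field(default_factory=dict)
    parent_min_bpp: float = 0.0
    drop_tol: float = 1e-12

    @property
    def psi_pair(self) -> tuple:
        return psi(self.n)

    def bpp_at(self, i: int, j: int) -> float:
        return float(self.bpp[i, j])

    def stacked_at(self, i: int, j: int) -> float:
        return float(self.stacked[i, j])

    def loop_unpaired(self, k: int, parent: tuple) -> float:
        return self.in_loop_unpaired.get(parent, {}).get(k, 0.0)

    def loop_pair(self, inner: tuple, parent: tuple) -> float:
        return self.in_loop_pair.get(parent, {}).get(inner, 0.0)

    def parents(self) -> list:
        """All parent pairs with stored in-loop maps (psi included)."""
        keys = set(self.in_loop_unpaired) | set(self.in_loop_pair)
        return sorted(keys)


# ---------------------------------------------------------------------------
# inside / outside


class _Inside:
    """Inside matrices over 1-based inclusive regions.

    Qb[i, j]  pair-closed partition function of i..j with (i, j) paired.
    M[i, j]   region content with >= 1 outermost helix, rest unpaired.
    M1[i, j]  exactly one helix.
    M2[i, j]  >= 2 helices (the multiloop auxiliary matrix).
    Regions with j < i read as 0 (all matrices) — the empty region's
    weight 1 is added explicitly where needed (Qreg = 1 + M).
    """

    def __init__(self, seq: RnaSequence, model: EnergyModel):
        n = len(seq)
        self.n = n
        self.seq = seq
        self.model = model
        self.dtype = _dp_dtype(n, model)
        N = n + 2
        self.Qb = np.zeros((N, N), dtype=self.dtype)
        self.M = np.zeros((N, N), dtype=self.dtype)
        self.M1 = np.zeros((N, N), dtype=self.dtype)
        self.M2 = np.zeros((N, N), dtype=self.dtype)
        self._fill()
        self.Z = self.dtype(1.0) + self.M[1, n]

    def _fill(self) -> None:
        n, seq, model = self.n, self.seq, self.model
        Qb, M, M1, M2 = self.Qb, self.M, self.M1, self.M2
        wh, wi, wm, ws = (
            model.w_hairpin,
            model.w_interior,
            model.w_multi,
            model.w_stack,
        )
        wp_row = np.zeros(n + 2)
        for j in range(1, n + 1):
            # pair-closed entries ending at j
            hi = j - model.min_hairpin - 1  # largest admissible i
            for i in range(1, max(hi, 0) + 1):
                wp = model.w_pair(seq[i], seq[j])
                if wp == 0.0:
                    continue
                interior = M1[i + 1, j - 1] + (ws - 1.0) * Qb[i + 1, j - 1]
                Qb[i, j] = wp * (wh + wi * interior + wm * M2[i + 1, j - 1])
            # multiloop-part columns j (vectorized over i)
            col = Qb[1:j + 1, j]  # Qb[h, j], h = 1..j
            suffix = np.cumsum(col[::-1])[::-1]  # sum_{h >= i} Qb[h, j]
            # t[i] = sum_h M[i, h-1] * Qb[h, j]
            t = M[1:j + 1, 0:j] @ col
            M1[1:j + 1, j] = M1[1:j + 1, j - 1] + suffix
            M2[1:j + 1, j] = M2[1:j + 1, j - 1] + t
            M[1:j + 1, j] = M[1:j + 1, j - 1] + suffix + t

    def Qreg(self, i: int, j: int) -> float:
        """Region partition function; 1 for an empty region."""
        if j < i:
            return 1.0
        return 1.0 + self.M[i, j]


class _Outside:
    """Outside weights O[i, j] for every legal pair, by decreasing span.

    O[i, j] sums, over structures containing (i, j), the weight of all
    parts outside the pair including the loop (i, j) lies in; then
    ``Pr[(i,j)] = O[i,j] * Qb[i,j] / Z``.  The parent sum is expanded into
    prefix/suffix cumulatives so the whole pass stays within cubic time.
    """

    def __init__(self, ins: _Inside):
        n, model = ins.n, ins.model
        N = n + 2
        dt = ins.dtype
        self.inside = ins
        self.O = np.zeros((N, N), dtype=dt)
        wi, wm, ws = model.w_interior, model.w_multi, model.w_stack
        M = ins.M
        Qb = ins.Qb
        seq = ins.seq

        wp = np.zeros((N, N), dtype=dt)
        for i in range(1, n + 1):
            for j in range(i + model.min_hairpin + 1, n + 1):
                wp[i, j] = model.w_pair(seq[i], seq[j])
        self.wp = wp
        legal = wp > 0.0

        # shifted views of M used throughout the parent-sum expansion
        # Mp1[i, p] = M[p+1, i-1]; Mq1[j, q] = M[j+1, q-1]
        Mp1 = np.zeros((N, N), dtype=dt)
        Mq1 = np.zeros((N, N), dtype=dt)
        for a in range(1, n + 1):
            Mp1[a, 1:a] = M[2:a + 1, a - 1]
            Mq1[a, a + 1:n + 1] = M[a + 1, a:n]
        # T[p, j] = sum_q OB[p, q] * M[j+1, q-1], maintained incrementally
        T = np.zeros((N, N), dtype=dt)
        OB = np.zeros((N, N), dtype=dt)

        ext = np.zeros((N, N), dtype=dt)
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                ext[i, j] = ins.Qreg(1, i - 1) * ins.Qreg(j + 1, n)

        for d in range(n - 1, model.min_hairpin, -1):
            # incorporate the pairs of span d + 1 finalized last iteration
            s = d + 1
            for p in range(1, n - s + 1):
                q = p + s
                if OB[p, q] != 0.0:
                    T[p, 1:n + 1] += OB[p, q] * Mq1[1:n + 1, q]
            # prefix/suffix cumulatives over all finalized parents
            Rq = np.zeros((N, N), dtype=dt)  # Rq[p, j] = sum_{q > j} OB[p, q]
            Rq[:, :n + 1] = np.cumsum(OB[:, :0:-1], axis=1)[:, ::-1]
            Cq = np.cumsum(OB, axis=0)  # Cq[i, q] = sum_{p <= i} OB[p, q]

            iv = np.arange(1, n - d + 1)
            jv = iv + d
            sub = legal[iv, jv]
            if not sub.any():
                continue
            iv, jv = iv[sub], jv[sub]
            # S0 = sum_{p<i, q>j} OB[p,q]
            S0 = np.cumsum(Rq, axis=0)[iv - 1, jv]
            # S1 = sum OB[p,q] M[p+1, i-1]
            S1 = np.einsum("xp,xp->x", Mp1[iv, 1:n + 1], Rq[1:n + 1, jv].T)
            # S2 = sum OB[p,q] M[j+1, q-1]
            S2 = np.einsum("xq,xq->x", Mq1[jv, 1:n + 1], Cq[iv - 1, 1:n + 1])
            # S3 = sum OB[p,q] M[p+1,i-1] M[j+1,q-1]
            S3 = np.einsum("xp,xp->x", Mp1[iv, 1:n + 1], T[1:n + 1, jv].T)
            stack_par = OB[iv - 1, jv + 1]
            Ovals = ext[iv, jv] + wi * S0 + wi * (ws - 1.0) * stack_par + wm * (
                S1 + S2 + S3
            )
            self.O[iv, jv] = Ovals
            OB[iv, jv] = Ovals * wp[iv, jv]


def compute_ensemble(
    seq: RnaSequence,
    model: EnergyModel | None = None,
    *,
    parent_min_bpp: float = 0.0,
    drop_tol: float = 1e-12,
) -> EnsembleProbs:
    """Compute all ensemble probabilities of one sequence.

    ``parent_min_bpp`` restricts the stored in-loop maps to parent pairs
    whose base-pair probability reaches that floor (psi always kept);
    passing the matching significance threshold keeps memory proportional
    to the pairs the sparsified matcher can use.  ``drop_tol`` drops
    individual entries below the tolerance.
    """
    if model is None:
        model = EnergyModel()
    n = len(seq)
    ins = _Inside(seq, model)
    out = _Outside(ins)
    Z = ins.Z
    wp, O, Qb, M, M1 = out.wp, out.O, ins.Qb, ins.M, ins.M1
    wh, wi, wm, ws = model.w_hairpin, model.w_interior, model.w_multi, model.w_stack

    bpp = np.zeros((n + 1, n + 1))
    bpp[1:, 1:] = (O[1:n + 1, 1:n + 1] * Qb[1:n + 1, 1:n + 1] / Z).astype(np.float64)
    stacked = np.zeros((n + 1, n + 1))
    unpaired = np.ones(n + 1)
    unpaired[0] = 0.0
    for k in range(1, n + 1):
        unpaired[k] = 1.0 - float(bpp[k, :].sum() + bpp[:, k].sum())

    probs = EnsembleProbs(
        n=n,
        residues=seq.residues,
        model=model,
        bpp=bpp,
        stacked=stacked,
        unpaired=unpaired,
        parent_min_bpp=parent_min_bpp,
        drop_tol=drop_tol,
    )

    def Qreg(a: int, b: int) -> float:
        return 1.0 if b < a else 1.0 + M[a, b]

    # exterior (psi) parent
    psi_key = psi(n)
    up_psi = {}
    ip_psi = {}
    for k in range(1, n + 1):
        v = float(Qreg(1, k - 1) * Qreg(k + 1, n) / Z)
        if v >= drop_tol:
            up_psi[k] = v
    for (i, j) in legal_pairs(seq, model):
        v = float(Qreg(1, i - 1) * Qb[i, j] * Qreg(j + 1, n) / Z)
        if v >= drop_tol:
            ip_psi[(i, j)] = v
    probs.in_loop_unpaired[psi_key] = up_psi
    probs.in_loop_pair[psi_key] = ip_psi

    # proper parents
    for (i, j) in legal_pairs(seq, model):
        if bpp[i, j] <= 0.0:
            continue
        base = O[i, j] * wp[i, j] / Z
        # stacked-pair probability (inner pair (i+1, j-1) as only helix)
        if wp[i + 1, j - 1] > 0.0:
            stacked[i, j] = float(base * wi * ws * Qb[i + 1, j - 1])
        if bpp[i, j] < parent_min_bpp:
            continue
        span = j - i - 1
        if span <= 0:
            continue
        up = {}
        ip = {}
        # unpaired members of loop (i, j): split the loop content around k
        ml = M[i + 1, i:j - 1]  # M[i+1, k-1], k = i+1 .. j-1
        mr = M[i + 2:j + 1, j - 1]  # M[k+1, j-1]
        m1l = M1[i + 1, i:j - 1]
        m1r = M1[i + 2:j + 1, j - 1]
        U = wh + wi * (m1l + m1r) + wm * (
            (1.0 + ml) * (1.0 + mr) - 1.0 - m1l - m1r
        )
        vals = base * U
        for off in range(span):
            v = float(vals[off])
            if v >= drop_tol:
                up[i + 1 + off] = v
        # base-pair members: (i', j') as an outermost helix of the loop
        onepl = 1.0 + M[i + 1, i:j - 1]  # per i': M[i+1, i'-1]
        onepr = 1.0 + M[i + 2:j + 1, j - 1]  # per j': M[j'+1, j-1]
        Cmat = wi + wm * (np.outer(onepl, onepr) - 1.0)
        Cmat[0, -1] += wi * (ws - 1.0)  # stacked helix (i+1, j-1)
        Vm = base * Cmat * Qb[i + 1:j, i + 1:j]
        mask = (wp[i + 1:j, i + 1:j] > 0.0) & (Vm >= drop_tol)
        for a, b in zip(*np.nonzero(mask)):
            ip[(i + 1 + int(a), i + 1 + int(b))] = float(Vm[a, b])
        if up or ip:
            probs.in_loop_unpaired[(i, j)] = up
            probs.in_loop_pair[(i, j)] = ip
    return probs


# ---------------------------------------------------------------------------
# exhaustive oracle


def enumerate_structures(
    seq: RnaSequence, model: EnergyModel | None = None, cap: int = 18
) -> list:
    """Every non-crossing structure with its Boltzmann weight.

    Exponential enumeration, refused above the length cap.  The weights
    are computed from scratch per structure (`structure_energy`), fully
    independent of the inside/outside pass.
    """
    if model is None:
        model = EnergyModel()
    n = len(seq)
    if n > cap:
        raise InputError(f"sequence length {n} above enumeration cap {cap}")
    pairs = legal_pairs(seq, model)
    by_i = {}
    for (i, j) in pairs:
        by_i.setdefault(i, []).append(j)

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def structs(i: int, j: int) -> tuple:
        if i > j:
            return (frozenset(),)
        out = []
        for s in structs(i + 1, j):
            out.append(s)
        for h in by_i.get(i, ()):
            if h > j:
                continue
            for s1 in structs(i + 1, h - 1):
                for s2 in structs(h + 1, j):
                    out.append(s1 | s2 | {(i, h)})
        return tuple(out)

    result = []
    for s in structs(1, n):
        if model.mode == "uniform":
            w = 1.0
        else:
            w = math.exp(-structure_energy(seq, model, s) / model.RT)
        result.append((s, w))
    return result


def structure_energy(seq: RnaSequence, model: EnergyModel, pairs) -> float:
    """Energy of one structure under the lightweight loop model."""
    e = 0.0
    pair_set = set(pairs)
    for (i, j) in pair_set:
        e += model.pair_energy[seq[i] + seq[j]]
        if (i + 1, j - 1) in pair_set:
            e += model.stack_bonus
        children = [
            (a, b)
            for (a, b) in pair_set
            if i < a < b < j
            and not any(
                i < x < a and b < y < j for (x, y) in pair_set if (x, y) != (i, j)
            )
        ]
        if len(children) == 0:
            e += model.hairpin_const
        elif len(children) == 1:
            e += model.interior_const
        else:
            e += model.multiloop_const
    return e


def count_structures(seq: RnaSequence, model: EnergyModel | None = None) -> int:
    """Independent non-crossing structure counter (interval DP)."""
    if model is None:
        model = EnergyModel()
    n = len(seq)

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def cnt(i: int, j: int) -> int:
        if i > j:
            return 1
        total = cnt(i + 1, j)
        for h in range(i + model.min_hairpin + 1, j + 1):
            if seq.can_pair(i, h):
                total += cnt(i + 1, h - 1) * cnt(h + 1, j)
        return total

    return cnt(1, n)


def _parents_of_structure(n: int, pairs) -> dict:
    """Map each position and pair to its parent pair (psi for external)."""
    parent = {}
    psi_key = psi(n)
    sorted_pairs = sorted(pairs, key=lambda p: p[1] - p[0])
    for k in range(1, n + 1):
        par = psi_key
        best = None
        for (a, b) in sorted_pairs:
            if a < k < b and (best is None or b - a < best):
                par, best = (a, b), b - a
        parent[k] = par
    for (i, j) in pairs:
        par = psi_key
        best = None
        for (a, b) in pairs:
            if a < i and j < b and (best is None or b - a < best):
                par, best = (a, b), b - a
        parent[(i, j)] = par
    return parent


def probs_by_enumeration(
    seq: RnaSequence, model: EnergyModel | None = None, cap: int = 18
) -> EnsembleProbs:
    """Exact ensemble probabilities from exhaustive enumeration (oracle)."""
    if model is None:
        model = EnergyModel()
    n = len(seq)
    structures = enumerate_structures(seq, model, cap=cap)
    Z = sum(w for _, w in structures)
    bpp = np.zeros((n + 1, n + 1))
    stacked = np.zeros((n + 1, n + 1))
    unpaired = np.zeros(n + 1)
    ilu: dict = {}
    ilp: dict = {}
    for s, w in structures:
        paired_pos = {p for pr in s for p in pr}
        parent = _parents_of_structure(n, s)
        for (i, j) in s:
            bpp[i, j] += w
            if (i + 1, j - 1) in s:
                stacked[i, j] += w
            key = parent[(i, j)]
            ilp.setdefault(key, {})
            ilp[key][(i, j)] = ilp[key].get((i, j), 0.0) + w
        for k in range(1, n + 1):
            if k not in paired_pos:
                unpaired[k] += w
                key = parent[k]
                ilu.setdefault(key, {})
                ilu[key][k] = ilu[key].get(k, 0.0) + w
    bpp /= Z
    stacked /= Z
    unpaired /= Z
    for d in (ilu, ilp):
        for key in d:
            for e in d[key]:
                d[key][e] /= Z
    psi_key = psi(n)
    ilu.setdefault(psi_key, {})
    ilp.setdefault(psi_key, {})
    return EnsembleProbs(
        n=n,
        residues=seq.residues,
        model=model,
        bpp=bpp,
        stacked=stacked,
        unpaired=unpaired,
        in_loop_unpaired=ilu,
        in_loop_pair=ilp,
    )


# ---------------------------------------------------------------------------
# cache


CACHE_FORMAT_VERSION = "1"


class CacheError(RuntimeError):
    """Unusable ensemble cache (wrong version, parameters, or truncated)."""


def _model_stamp(model: EnergyModel) -> str:
    pe = ";".join(f"{k}={model.pair_energy[k]:g}" for k in sorted(model.pair_energy))
    return (
        f"pairs:{pe}|stack:{model.stack_bonus:g}|hairpin:{model.hairpin_const:g}"
        f"|interior:{model.interior_const:g}|multi:{model.multiloop_const:g}"
        f"|RT:{model.RT:g}|min_hairpin:{model.min_hairpin}|mode:{model.mode}"
    )


def _checksum(residues: str) -> str:
    return hashlib.sha256(residues.encode()).hexdigest()[:16]


def _open(path, mode):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def cache_write(probs: EnsembleProbs, path) -> None:
    """Write probabilities as a versioned, parameter-stamped TSV."""
    with _open(path, "w") as fh:
        fh.write(f"#version\t{CACHE_FORMAT_VERSION}\n")
        fh.write(f"#model\t{_model_stamp(probs.model)}\n")
        fh.write(f"#checksum\t{_checksum(probs.residues)}\n")
        fh.write(f"#n\t{probs.n}\n")
        fh.write(f"#parent_min_bpp\t{probs.parent_min_bpp!r}\n")
        fh.write(f"#drop_tol\t{probs.drop_tol!r}\n")
        for i in range(1, probs.n + 1):
            fh.write(f"unpaired\t{i}\t{float(probs.unpaired[i])!r}\n")
            for j in range(i + 1, probs.n + 1):
                if probs.bpp[i, j] != 0.0:
                    fh.write(f"bpp\t{i}\t{j}\t{float(probs.bpp[i, j])!r}\n")
                if probs.stacked[i, j] != 0.0:
                    fh.write(f"stacked\t{i}\t{j}\t{float(probs.stacked[i, j])!r}\n")
        for (pi, pj), entries in sorted(probs.in_loop_unpaired.items()):
            for k, v in sorted(entries.items()):
                fh.write(f"inloop_u\t{pi}\t{pj}\t{k}\t{v!r}\n")
        for (pi, pj), entries in sorted(probs.in_loop_pair.items()):
            for (a, b), v in sorted(entries.items()):
                fh.write(f"inloop_p\t{pi}\t{pj}\t{a}\t{b}\t{v!r}\n")
        fh.write("#end\n")


def cache_read(path, seq: RnaSequence, model: EnergyModel) -> EnsembleProbs:
    """Read a cache, verifying version, model parameters and sequence."""
    header = {}
    rows = []
    complete = False
    try:
        with _open(path, "r") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line == "#end":
                    complete = True
                    break
                if line.startswith("#"):
                    key, _, val = line[1:].partition("\t")
                    header[key] = val
                else:
                    rows.append(line.split("\t"))
    except OSError as exc:
        raise CacheError(f"cannot read cache {path}: {exc}") from exc
    if header.get("version") != CACHE_FORMAT_VERSION:
        raise CacheError(
            f"cache version {header.get('version')!r} != {CACHE_FORMAT_VERSION!r}"
        )
    if header.get("model") != _model_stamp(model):
        raise CacheError("cache was generated with different model parameters")
    if header.get("checksum") != _checksum(seq.residues):
        raise CacheError("cache does not belong to this sequence")
    if not complete:
        raise CacheError("truncated cache file (missing #end marker)")
    n = int(header["n"])
    probs = EnsembleProbs(
        n=n,
        residues=seq.residues,
        model=model,
        bpp=np.zeros((n + 1, n + 1)),
        stacked=np.zeros((n + 1, n + 1)),
        unpaired=np.zeros(n + 1),
        parent_min_bpp=float(header.get("parent_min_bpp", "0.0")),
        drop_tol=float(header.get("drop_tol", "1e-12")),
    )
    for row in rows:
        kind = row[0]
        if kind == "unpaired":
            probs.unpaired[int(row[1])] = float(row[2])
        elif kind == "bpp":
            probs.bpp[int(row[1]), int(row[2])] = float(row[3])
        elif kind == "stacked":
            probs.stacked[int(row[1]), int(row[2])] = float(row[3])
        elif kind == "inloop_u":
            par = (int(row[1]), int(row[2]))
            probs.in_loop_unpaired.setdefault(par, {})[int(row[3])] = float(row[4])
        elif kind == "inloop_p":
            par = (int(row[1]), int(row[2]))
            probs.in_loop_pair.setdefault(par, {})[
                (int(row[3]), int(row[4]))
            ] = float(row[5])
        else:
            raise CacheError(f"unknown cache row kind {kind!r}")
    probs.in_loop_unpaired.setdefault(psi(n), {})
    probs.in_loop_pair.setdefault(psi(n), {})
    return probs
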