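"""End-to-end run: ensembles (cached) -> DP -> traceback -> chaining."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

from .chaining import Chain, chain_epms
from .dp import SparseDpState, fill_dp
from .ensemble import CacheError, cache_read, cache_write, compute_ensemble
from .params import EnergyModel, Params
from .sequence import RnaSequence
from .traceback import trace_heuristic, trace_suboptimal

log = logging.getLogger("rnaepm")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    epms: list
    chain: Chain | None
    dp: SparseDpState
    timings: dict


def _ensemble_cached(seq: RnaSequence, model: EnergyModel, params: Params, cache_dir):
    if cache_dir is None:
        return compute_ensemble(
            seq, model, parent_min_bpp=params.theta1,
            drop_tol=min(params.theta2, params.theta3, 1e-12) or 1e-12,
        )
    import hashlib

    tag = hashlib.sha256(
        f"{seq.residues}|{params.theta1}|{params.theta2}|{params.theta3}".encode()
    ).hexdigest()[:16]
    path = Path(cache_dir) / f"{tag}.ens.tsv"
    if path.exists():
        try:
            return cache_read(path, seq, model)
        except CacheError as exc:
            log.warning("ignoring unusable cache %s: %s", path, exc)
    probs = compute_ensemble(
        seq, model, parent_min_bpp=params.theta1,
        drop_tol=min(params.theta2, params.theta3, 1e-12) or 1e-12,
    )
    Path(cache_dir).mkdir(parents=True, exist_ok=True)
    cache_write(probs, path)
    return probs


def run_pipeline(
    seqA: RnaSequence,
    seqB: RnaSequence,
    params: Params | None = None,
    model: EnergyModel | None = None,
    *,
    chain: bool = True,
    cache_dir=None,
) -> PipelineResult:
    params = params or Params()
    model = model or EnergyModel()
    timings = {}
    t0 = time.perf_counter()
    probsA = _ensemble_cached(seqA, model, params, cache_dir)
    probsB = _ensemble_cached(seqB, model, params, cache_dir)
    timings["ensembles"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    dp = fill_dp(probsA, probsB, params)
    timings["dp"] = time.perf_counter() - t0
    log.info(
        "dp: %d x %d significant pairs, %d entries written, sparsity %.3f",
        len(dp.sig_a), len(dp.sig_b), dp.entries_written, dp.sparsity_ratio(),
    )

    t0 = time.perf_counter()
    if params.traceback.strategy == "heuristic":
        epms = trace_heuristic(dp)
    else:
        epms = trace_suboptimal(dp)
    timings["traceback"] = time.perf_counter() - t0
    log.info("traceback: %d EPMs (max F %.3f)", len(epms), dp.max_f)

    best_chain = None
    if chain:
        t0 = time.perf_counter()
        best_chain = chain_epms(epms, len(seqA), len(seqB))
        timings["chaining"] = time.perf_counter() - t0
        log.info(
            "chain: %d EPMs, score %.3f, coverage %.3f",
            len(best_chain), best_chain.total_score, best_chain.coverage,
        )
    return PipelineResult(epms=epms, chain=best_chain, dp=dp, timings=timings)
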