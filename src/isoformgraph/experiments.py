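"""End-to-end simulation experiments: simulate a gene cluster, run the
reconstruction pipeline, and score the predictions.

Used by the test suite and the reproduction script; also reachable from
the CLI via ``simulate`` + ``run`` + ``evaluate``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bubbles import PopParams
from .isoforms import OutputParams, run_batch_pipeline
from .seeding import SeedingParams
from .simeval import EvalResult, SimConfig, evaluate, simulate_isoforms, simulate_reads

logger = logging.getLogger(__name__)

__all__ = ["ReplicateResult", "run_replicate", "completeness_experiment"]


@dataclass
class ReplicateResult:
    config: SimConfig
    truths: list[tuple[str, str]]
    abundances: list[int]
    predictions: list[tuple[str, str]]
    evaluation: EvalResult


def run_replicate(
    config: SimConfig,
    seeding_params: SeedingParams | None = None,
    pop_params: PopParams | None = None,
    output_params: OutputParams | None = None,
) -> ReplicateResult:
    """Simulate one cluster under ``config``, reconstruct, evaluate."""
    rng = np.random.default_rng(config.seed)
    truths, _exons = simulate_isoforms(config, rng=rng)
    abundances = [int(rng.choice(config.abundance_choices)) for _ in truths]
    reads, _truth_of = simulate_reads(
        truths,
        abundances,
        config.error_rate,
        rng,
        error_mix=config.error_mix,
        polyA_length=config.polyA_length,
        cluster_id=f"sim{config.seed}",
    )
    result = run_batch_pipeline(
        reads,
        seeding_params=seeding_params,
        pop_params=pop_params,
        output_params=output_params,
        cluster_id=f"sim{config.seed}",
    )
    predictions = [(p.isoform_id, p.consensus) for p in result.predictions]
    evaluation = evaluate(predictions, truths)
    logger.info(
        "replicate seed=%d n=%d: %d predictions, TP=%d FP=%d FN=%d",
        config.seed,
        config.n_isoforms,
        len(predictions),
        evaluation.tp,
        evaluation.fp,
        evaluation.fn,
    )
    return ReplicateResult(
        config=config,
        truths=truths,
        abundances=abundances,
        predictions=predictions,
        evaluation=evaluation,
    )


def completeness_experiment(
    ns: tuple[int, ...] = (3, 5, 8),
    replicates: int = 10,
    seed: int = 1,
    error_rate: float = 0.01,
    reference_length: int = 800,
) -> list[ReplicateResult]:
    """The simulated-data experiment: ``replicates`` seeded replicates per
    isoform count in ``ns``, post-correction error regime by default."""
    results: list[ReplicateResult] = []
    for n in ns:
        for rep in range(replicates):
            config = SimConfig(
                reference_length=reference_length,
                n_isoforms=n,
                error_rate=error_rate,
                seed=(seed * 10_000 + n * 100 + rep) % (2**31),
            )
            results.append(run_replicate(config))
    return results
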