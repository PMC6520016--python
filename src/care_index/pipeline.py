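"""End-to-end discovery -> validation workflow glue.

One call chains the full analysis: harmonize panels, fit event models on
the discovery cohort, search for the optimal event sequence, stage both
cohorts, pick the Youden-optimal expected-stage cutoff in discovery, and
transfer it unchanged to validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier_eval import (
    ContingencyMetrics,
    RocCurve,
    optimal_threshold,
    roc_curve,
    transfer_threshold,
)
from .data_model import CohortTable, shared_panel
from .event_models import EventModelSet, fit_event_models
from .sequence_search import (
    EventSequence,
    SequenceFitResult,
    fit_progression_model,
)
from .staging import StagingOutput, stage_cohort


@dataclass
class TransferResult:
    shared_names: list[str]
    models: EventModelSet
    sequence_fit: SequenceFitResult
    discovery_staging: StagingOutput
    validation_staging: StagingOutput
    discovery_roc: RocCurve
    threshold: float
    discovery_metrics: ContingencyMetrics
    validation_metrics: ContingencyMetrics


def run_transfer_pipeline(
    discovery: CohortTable,
    validation: CohortTable,
    n_starts: int = 10,
    seed: int = 0,
    sequence: EventSequence | None = None,
    threshold: float | None = None,
) -> TransferResult:
    """Fit on discovery, evaluate on validation.

    ``sequence`` and ``threshold`` may be supplied to reuse a frozen
    ordering or cutoff instead of re-estimating them.
    """
    names = shared_panel(discovery, validation)
    if not names:
        raise ValueError("cohorts share no biomarkers")
    disc = discovery.restrict_panel(names)
    valid = validation.restrict_panel(names)

    if sequence is None:
        models, seq_fit = fit_progression_model(
            disc, marginal_starts=n_starts, seed=seed
        )
    else:
        from .sequence_search import sequence_loglik

        models = fit_event_models(disc)
        seq_fit = SequenceFitResult(
            sequence=sequence,
            loglik=sequence_loglik(disc, models, sequence),
            seed=seed,
            n_starts=0,
        )
    seq = seq_fit.sequence

    disc_staging = stage_cohort(disc, models, seq)
    valid_staging = stage_cohort(valid, models, seq)

    disc_scores = disc_staging.table["expected_stage"].to_numpy()
    disc_labels = disc_staging.table["group"].to_numpy()
    curve = roc_curve(disc_scores, disc_labels)
    thr = float(threshold) if threshold is not None else optimal_threshold(curve)

    disc_metrics = transfer_threshold(thr, disc_scores, disc_labels)
    valid_metrics = transfer_threshold(
        thr,
        valid_staging.table["expected_stage"].to_numpy(),
        valid_staging.table["group"].to_numpy(),
    )
    return TransferResult(
        shared_names=names,
        models=models,
        sequence_fit=seq_fit,
        discovery_staging=disc_staging,
        validation_staging=valid_staging,
        discovery_roc=curve,
        threshold=thr,
        discovery_metrics=disc_metrics,
        validation_metrics=valid_metrics,
    )
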