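"""Maximum-likelihood patient staging: the CARE index.

Given the optimal event ordering and fitted event models, each subject's
stage likelihood L(k) is the probability of their measurements assuming
exactly the first k events have occurred.  The CARE index is the stage
maximizing the posterior under a uniform stage prior (lowest stage on
ties); the expected stage is the posterior mean, a continuous score used
for ROC analysis since it can take the non-integer threshold values a
discrete ML stage cannot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import CohortTable, GROUP_LABELS
from .event_models import EventModelSet, log_likelihood_arrays
from .sequence_search import EventSequence, stage_log_matrix


@dataclass
class StageResult:
    subject_id: str
    log_likelihoods: np.ndarray  # L(k), k = 0..N, on the log scale
    posterior: np.ndarray
    ml_stage: int
    expected_stage: float
    n_missing: int
    uninformative: bool = False

    def __post_init__(self) -> None:
        assert abs(self.posterior.sum() - 1.0) < 1e-9


@dataclass
class StagingOutput:
    results: list[StageResult]
    table: pd.DataFrame  # subject_id, group, ml_stage, expected_stage, n_missing, posterior_k
    histogram: pd.DataFrame  # rows = stage 0..N, columns = group labels

    def write(self, stages_path: str | Path, histogram_path: str | Path | None = None) -> None:
        self.table.to_csv(stages_path, index=False)
        if histogram_path is not None:
            self.histogram.to_csv(histogram_path)


def _stage_from_logliks(log_L: np.ndarray) -> tuple[np.ndarray, int, float]:
    shifted = log_L - log_L.max()
    post = np.exp(shifted)
    post /= post.sum()
    # argmax returns the lowest index on exact ties; guard against float fuzz
    best = post.max()
    ml = int(np.flatnonzero(post >= best - 1e-12)[0])
    expected = float(np.arange(len(post)) @ post)
    return post, ml, expected


def stage_subject(
    values: Mapping[str, float],
    models: EventModelSet,
    seq: EventSequence,
    subject_id: str = "",
) -> StageResult:
    """Stage one subject from a biomarker-name -> value mapping.

    Missing biomarkers (absent, None, or NaN) are marginalized (factor 1 in
    every stage term).  A subject with no informative biomarker gets a
    uniform posterior and the ``uninformative`` flag.
    """
    N = len(seq)
    log_L = np.zeros(N + 1)
    n_missing = 0
    for pos, name in enumerate(seq.events, start=1):
        x = values.get(name)
        if x is None or (isinstance(x, float) and math.isnan(x)):
            n_missing += 1
            continue
        m = models[name]
        from scipy.stats import norm

        le = norm.logpdf(float(x), m.mu_event, m.sigma_event)
        ln = norm.logpdf(float(x), m.mu_nonevent, m.sigma_nonevent)
        log_L[pos:] += le
        log_L[:pos] += ln
    post, ml, expected = _stage_from_logliks(log_L)
    return StageResult(
        subject_id=subject_id,
        log_likelihoods=log_L,
        posterior=post,
        ml_stage=ml,
        expected_stage=expected,
        n_missing=n_missing,
        uninformative=(n_missing == N),
    )


def stage_cohort(
    table: CohortTable,
    models: EventModelSet,
    seq: EventSequence,
) -> StagingOutput:
    """Stage every subject and cross-tabulate ML stages by conversion group."""
    names = [b.name for b in table.panel]
    if set(seq.events) != set(names):
        raise ValueError("sequence and cohort panel order different biomarker sets")
    log_e, log_n = log_likelihood_arrays(models, table, names)
    order = np.array([names.index(ev) for ev in seq.events])
    log_L = stage_log_matrix(log_e, log_n, order)
    N = len(seq)
    missing = (~np.isfinite(table.biomarker_matrix(names))).sum(axis=1)

    results = []
    rows = []
    for i in range(table.n_subjects):
        post, ml, expected = _stage_from_logliks(log_L[i])
        sid = str(table.data.loc[i, "subject_id"])
        res = StageResult(
            subject_id=sid,
            log_likelihoods=log_L[i],
            posterior=post,
            ml_stage=ml,
            expected_stage=expected,
            n_missing=int(missing[i]),
            uninformative=(int(missing[i]) == N),
        )
        results.append(res)
        row = {
            "subject_id": sid,
            "group": table.data.loc[i, "group"],
            "ml_stage": ml,
            "expected_stage": expected,
            "n_missing": int(missing[i]),
            "uninformative": res.uninformative,
        }
        row.update({f"posterior_{k}": post[k] for k in range(N + 1)})
        rows.append(row)
    out = pd.DataFrame(rows)

    hist = pd.DataFrame(
        0, index=pd.RangeIndex(N + 1, name="stage"), columns=list(GROUP_LABELS)
    )
    for res, group in zip(results, table.data["group"]):
        hist.loc[res.ml_stage, group] += 1
    return StagingOutput(results=results, table=out, histogram=hist)
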