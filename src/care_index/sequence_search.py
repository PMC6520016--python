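"""Event-sequence likelihood and search for the optimal ordering.

The event-based model assumes all subjects accumulate biomarker
abnormality events in a single common order S.  A subject at (unknown)
stage k has experienced exactly the first k events of S.  With a uniform
prior over the N+1 stages, the likelihood of a subject's measurements x
under an ordering S is

    P(x | S) = 1/(N+1) * sum_{k=0..N} prod_{i<=k} p(x_{S(i)} | E)
                                       * prod_{i>k} p(x_{S(i)} | not E)

and the data log-likelihood is the sum of log P(x | S) over subjects.
Missing measurements contribute factor 1 (marginalized).  The optimal
sequence is found by multi-start steepest-ascent over pairwise swaps and
single-element insertions; an optional Metropolis sampler over
permutations summarizes positional uncertainty.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .data_model import CohortTable
from .event_models import EventModelSet, log_likelihood_arrays


@dataclass(frozen=True)
class EventSequence:
    """An ordering of biomarker events: a permutation of the panel."""

    events: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.events)) != len(self.events):
            raise ValueError(f"sequence is not a permutation: {self.events}")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def position(self, name: str) -> int:
        """1-based position of an event in the ordering."""
        return self.events.index(name) + 1


@dataclass
class SequenceFitResult:
    sequence: EventSequence
    loglik: float
    start_logliks: list[float] = field(default_factory=list)
    #: rows = events (sequence's panel order), cols = positions; rows sum to 1
    position_frequencies: np.ndarray | None = None
    seed: int | None = None
    n_starts: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sequence": list(self.sequence.events),
            "loglik": self.loglik,
            "start_logliks": self.start_logliks,
            "seed": self.seed,
            "n_starts": self.n_starts,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SequenceFitResult":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            sequence=EventSequence(tuple(payload["sequence"])),
            loglik=payload["loglik"],
            start_logliks=payload.get("start_logliks", []),
            seed=payload.get("seed"),
            n_starts=payload.get("n_starts", 0),
        )


def _check_permutation(seq: EventSequence, names: Sequence[str]) -> None:
    if set(seq.events) != set(names) or len(seq) != len(names):
        raise ValueError(
            f"sequence {seq.events} is not a permutation of the panel {tuple(names)}"
        )


def stage_log_matrix(log_e: np.ndarray, log_n: np.ndarray, order: np.ndarray) -> np.ndarray:
    """log L(k) for k = 0..N per subject, shape (n_subjects, N+1).

    log L(k) = sum of event log-densities over the first k positions of the
    ordering plus non-event log-densities over the rest.
    """
    le = log_e[:, order]
    ln = log_n[:, order]
    n, N = le.shape
    pref_e = np.concatenate([np.zeros((n, 1)), np.cumsum(le, axis=1)], axis=1)
    pref_n = np.concatenate([np.zeros((n, 1)), np.cumsum(ln, axis=1)], axis=1)
    total_n = pref_n[:, -1][:, None]
    return pref_e + (total_n - pref_n)


def _loglik_orders(log_e: np.ndarray, log_n: np.ndarray, orders: np.ndarray) -> np.ndarray:
    """Data log-likelihood for a batch of orderings, shape (n_orders,)."""
    le = log_e[:, orders]  # (n_subj, n_orders, N)
    ln = log_n[:, orders]
    pref_e = np.cumsum(le, axis=2)
    pref_n = np.cumsum(ln, axis=2)
    total_n = pref_n[:, :, -1][:, :, None]
    # stage terms k = 0..N: prepend the k=0 (all non-event) column
    stage0 = total_n[:, :, 0][:, :, None]
    terms = np.concatenate([stage0, pref_e + (total_n - pref_n)], axis=2)
    N = le.shape[2]
    subj_ll = logsumexp(terms, axis=2) - math.log(N + 1)
    return subj_ll.sum(axis=0)


def sequence_loglik(
    table: CohortTable, models: EventModelSet, seq: EventSequence
) -> float:
    """Log-likelihood of the cohort under one event ordering.

    Computed with log-sum-exp over stages; a subject with every biomarker
    missing contributes exactly 0 (its likelihood is 1 after the uniform
    stage prior normalizes away).
    """
    names = [b.name for b in table.panel]
    _check_permutation(seq, names)
    log_e, log_n = log_likelihood_arrays(models, table, names)
    order = np.array([names.index(ev) for ev in seq.events])
    return float(_loglik_orders(log_e, log_n, order[None, :])[0])


def _neighborhood(order: np.ndarray) -> np.ndarray:
    """All pairwise swaps then all single-element insertions of ``order``,
    in deterministic enumeration order (ties in the search break toward the
    first-encountered move)."""
    N = len(order)
    moves = []
    for i, j in itertools.combinations(range(N), 2):
        cand = order.copy()
        cand[i], cand[j] = cand[j], cand[i]
        moves.append(cand)
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            cand = np.delete(order, i)
            cand = np.insert(cand, j, order[i])
            moves.append(cand)
    if not moves:
        return np.empty((0, N), dtype=int)
    return np.array(moves, dtype=int)


def _greedy_ascent(
    log_e: np.ndarray, log_n: np.ndarray, order: np.ndarray
) -> tuple[np.ndarray, float]:
    current = order.copy()
    current_ll = float(_loglik_orders(log_e, log_n, current[None, :])[0])
    while True:
        cands = _neighborhood(current)
        if len(cands) == 0:
            return current, current_ll
        lls = _loglik_orders(log_e, log_n, cands)
        best = int(np.argmax(lls))
        if lls[best] > current_ll + 1e-12:
            current = cands[best]
            current_ll = float(lls[best])
        else:
            return current, current_ll


def find_optimal_sequence(
    table: CohortTable,
    models: EventModelSet,
    n_starts: int = 25,
    seed: int = 0,
    mcmc_steps: int = 0,
    mcmc_burn_in: int = 0,
) -> SequenceFitResult:
    """Multi-start greedy search for the maximum-likelihood event ordering.

    Each start begins at a random permutation drawn under ``seed`` (the
    first start at the panel order) and ascends by the best of all pairwise
    swaps and insertions until no move improves.  If ``mcmc_steps`` > 0, a
    Metropolis sampler over permutations (random transpositions at the data
    likelihood) is run from the best ordering and an event-by-position
    frequency matrix is attached as a diagnostic; the reported optimum is
    always the greedy one.
    """
    names = [b.name for b in table.panel]
    N = len(names)
    if N < 1:
        raise ValueError("panel must contain at least one biomarker")
    log_e, log_n = log_likelihood_arrays(models, table, names)
    rng = np.random.default_rng(seed)

    best_order: np.ndarray | None = None
    best_ll = -np.inf
    start_lls: list[float] = []
    for s in range(max(1, n_starts)):
        start = np.arange(N) if s == 0 else rng.permutation(N)
        order, ll = _greedy_ascent(log_e, log_n, start)
        start_lls.append(ll)
        if ll > best_ll:
            best_ll = ll
            best_order = order

    assert best_order is not None
    freq = None
    if mcmc_steps > 0:
        freq = _mcmc_position_frequencies(
            log_e, log_n, best_order, rng, mcmc_steps, mcmc_burn_in
        )
    return SequenceFitResult(
        sequence=EventSequence(tuple(names[i] for i in best_order)),
        loglik=best_ll,
        start_logliks=start_lls,
        position_frequencies=freq,
        seed=seed,
        n_starts=max(1, n_starts),
    )


def _mcmc_position_frequencies(
    log_e: np.ndarray,
    log_n: np.ndarray,
    start: np.ndarray,
    rng: np.random.Generator,
    steps: int,
    burn_in: int,
) -> np.ndarray:
    N = len(start)
    counts = np.zeros((N, N))
    order = start.copy()
    ll = float(_loglik_orders(log_e, log_n, order[None, :])[0])
    for t in range(steps):
        i, j = rng.choice(N, size=2, replace=False)
        cand = order.copy()
        cand[i], cand[j] = cand[j], cand[i]
        cand_ll = float(_loglik_orders(log_e, log_n, cand[None, :])[0])
        if math.log(rng.random()) < cand_ll - ll:
            order, ll = cand, cand_ll
        if t >= burn_in:
            counts[order, np.arange(N)] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def _stage_posteriors(log_e: np.ndarray, log_n: np.ndarray, order: np.ndarray) -> np.ndarray:
    logL = stage_log_matrix(log_e, log_n, order)
    shifted = logL - logL.max(axis=1, keepdims=True)
    q = np.exp(shifted)
    return q / q.sum(axis=1, keepdims=True)


def _refine_from_order(
    table: CohortTable,
    models: EventModelSet,
    order: np.ndarray,
    names: list[str],
    directions: dict[str, str],
    n_iter: int,
    variance_floor_frac: float,
) -> tuple[EventModelSet, np.ndarray, float]:
    """Stage-informed joint EM from one starting ordering.

    E-step: stage posteriors under the current models and ordering give
    each subject a soft event indicator per biomarker, P(stage >= its
    position).  M-step: event/non-event means and the shared scale are
    re-estimated from those responsibilities — pooling strength across
    biomarkers, which is what identifies events that occur in almost all
    (or almost no) subjects.  Each iteration ends with a greedy ordering
    ascent from the current ordering.
    """
    from .event_models import EventModel

    X = table.biomarker_matrix(names)
    ll = -np.inf
    for _ in range(n_iter):
        log_e, log_n = log_likelihood_arrays(models, table, names)
        q = _stage_posteriors(log_e, log_n, order)
        # P(stage >= k) per subject, k = 0..N
        cum = np.cumsum(q[:, ::-1], axis=1)[:, ::-1]
        pos = np.empty(len(names), dtype=int)
        for j_seq, j_col in enumerate(order):
            pos[j_col] = j_seq + 1
        new: dict[str, EventModel] = {}
        for j, name in enumerate(names):
            col = X[:, j]
            obs = np.isfinite(col)
            xo = col[obs]
            r = cum[obs, pos[j]]
            n_e, n_n = float(r.sum()), float((1 - r).sum())
            prev = models[name]
            if n_e < 0.5 or n_n < 0.5:
                new[name] = prev
                continue
            mu_e = float(r @ xo) / n_e
            mu_n = float((1 - r) @ xo) / n_n
            var = (float(r @ (xo - mu_e) ** 2) + float((1 - r) @ (xo - mu_n) ** 2)) / len(xo)
            sd = float(np.std(xo, ddof=1))
            sigma = max(math.sqrt(var), math.sqrt(variance_floor_frac) * sd)
            bad = mu_e <= mu_n if directions[name] == "increase" else mu_e >= mu_n
            if bad:  # keep the previous model rather than violate the direction
                new[name] = prev
                continue
            w = min(max(n_e / len(xo), 1e-6), 1 - 1e-6)
            new[name] = EventModel(
                biomarker=name, direction=directions[name],
                mu_nonevent=mu_n, sigma_nonevent=sigma,
                mu_event=mu_e, sigma_event=sigma, w=w,
                n_obs=len(xo),
            )
        models = EventModelSet(new)
        log_e, log_n = log_likelihood_arrays(models, table, names)
        order, ll = _greedy_ascent(log_e, log_n, order)
    return models, order, ll


def fit_progression_model(
    table: CohortTable,
    panel=None,
    marginal_starts: int = 10,
    refine_iters: int = 4,
    seed: int = 0,
    variance_floor_frac: float = 1e-2,
) -> tuple[EventModelSet, SequenceFitResult]:
    """Jointly estimate event densities and the optimal event sequence.

    Purely marginal mixture fits can mis-place components for events that
    have occurred in nearly every subject or nearly none, and a sequence
    search on such fits inherits the error.  This canonical fitting path
    therefore (1) fits marginal mixtures, (2) finds the best greedy
    ordering, (3) reruns the stage-informed joint EM from a set of
    diversified starting orderings — the greedy optimum plus that optimum
    with each single event relocated to the opposite end, the targeted
    escape for a mis-placed-event basin — and (4) returns the candidate
    with the highest joint likelihood.  Deterministic given seed and data.
    """
    from .event_models import fit_event_models

    table = table if panel is None else table.restrict_panel([b.name for b in panel])
    names = [b.name for b in table.panel]
    directions = {b.name: b.direction for b in table.panel}
    N = len(names)

    models = fit_event_models(table, variance_floor_frac=variance_floor_frac)
    log_e, log_n = log_likelihood_arrays(models, table, names)
    rng = np.random.default_rng(seed)
    best0: tuple[float, np.ndarray] | None = None
    for s in range(max(1, marginal_starts)):
        start = np.arange(N) if s == 0 else rng.permutation(N)
        order, ll = _greedy_ascent(log_e, log_n, start)
        if best0 is None or ll > best0[0]:
            best0 = (ll, order)
    assert best0 is not None
    base = best0[1]

    starts = [base]
    for p in range(N):
        moved = np.delete(base, p)
        target = N - 1 if p < N // 2 else 0
        starts.append(np.insert(moved, target, base[p]))

    best: tuple[EventModelSet, np.ndarray, float] | None = None
    trajectory: list[float] = []
    for start in starts:
        cand = _refine_from_order(
            table, models, start, names, directions, refine_iters, variance_floor_frac
        )
        trajectory.append(cand[2])
        if best is None or cand[2] > best[2]:
            best = cand
    assert best is not None
    fit = SequenceFitResult(
        sequence=EventSequence(tuple(names[i] for i in best[1])),
        loglik=best[2],
        start_logliks=trajectory,
        seed=seed,
        n_starts=len(starts),
    )
    return best[0], fit


def exhaustive_optimal_sequence(
    table: CohortTable, models: EventModelSet
) -> tuple[EventSequence, float]:
    """Global optimum by enumerating all N! orderings (small panels only)."""
    names = [b.name for b in table.panel]
    N = len(names)
    if N > 8:
        raise ValueError(f"exhaustive search over {N}! orderings is not sensible")
    log_e, log_n = log_likelihood_arrays(models, table, names)
    best: tuple[EventSequence, float] | None = None
    for perm in itertools.permutations(range(N)):
        ll = float(_loglik_orders(log_e, log_n, np.array(perm)[None, :])[0])
        if best is None or ll > best[1]:
            best = (EventSequence(tuple(names[i] for i in perm)), ll)
    assert best is not None
    return best


def kendall_tau_sequences(a: EventSequence, b: EventSequence) -> float:
    """Kendall rank correlation between two orderings of the same events."""
    from scipy.stats import kendalltau

    if set(a.events) != set(b.events):
        raise ValueError("sequences order different event sets")
    pos_b = {name: i for i, name in enumerate(b.events)}
    ranks_b = [pos_b[name] for name in a.events]
    tau, _ = kendalltau(range(len(a)), ranks_b)
    return float(tau)
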