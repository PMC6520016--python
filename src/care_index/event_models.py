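"""Per-biomarker event / non-event measurement models.

Each biomarker's abnormality is treated as a binary latent *event*.  The
measurement x is modelled as a two-component Gaussian mixture

    p(x) = (1 - w) N(x; mu_n, sigma_n^2) + w N(x; mu_e, sigma_e^2)

where the event component's mean is constrained to lie on the biomarker's
declared abnormal side of the non-event mean.  The two conditional
densities p(x | event) and p(x | no event) are the inputs to the
event-based sequence likelihood and to patient staging; a missing
measurement contributes the neutral factor 1 to both (marginalization).

Fitting is plain EM on all non-missing values of the pooled sample, with a
variance floor against component collapse.  It is deterministic: the
initialization is quantile-based, so no randomness enters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

from .data_model import BiomarkerSpec, CohortTable, panel_names

logger = logging.getLogger(__name__)

MIN_OBSERVATIONS = 10


class FittingError(ValueError):
    """EM cannot run on this biomarker (too few values, zero spread)."""


class LookupError_(KeyError):
    """Biomarker not present in the model set."""


@dataclass
class EventModel:
    """Fitted mixture for one biomarker: non-event and event Gaussians
    plus the mixing weight w = P(event component)."""

    biomarker: str
    direction: str
    mu_nonevent: float
    sigma_nonevent: float
    mu_event: float
    sigma_event: float
    w: float
    n_obs: int = 0
    loglik: float = math.nan
    n_iter: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.sigma_nonevent > 0 and self.sigma_event > 0):
            raise ValueError("component scales must be positive")
        if not 0.0 < self.w < 1.0:
            raise ValueError(f"mixing weight must be in (0,1), got {self.w}")
        displaced = (
            self.mu_event > self.mu_nonevent
            if self.direction == "increase"
            else self.mu_event < self.mu_nonevent
        )
        if not displaced:
            raise ValueError(
                f"{self.biomarker}: event mean {self.mu_event} is not displaced "
                f"in the abnormal ({self.direction}) direction from {self.mu_nonevent}"
            )

    def density_event(self, x: float) -> float:
        return float(stats.norm.pdf(x, self.mu_event, self.sigma_event))

    def density_nonevent(self, x: float) -> float:
        return float(stats.norm.pdf(x, self.mu_nonevent, self.sigma_nonevent))


@dataclass
class EventModelSet:
    """Event models for a biomarker panel; dict-like access by name."""

    models: dict[str, EventModel]

    def __getitem__(self, name: str) -> EventModel:
        try:
            return self.models[name]
        except KeyError:
            raise LookupError_(f"no event model for biomarker {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.models

    @property
    def names(self) -> list[str]:
        return list(self.models)

    def restrict(self, names: Sequence[str]) -> "EventModelSet":
        return EventModelSet({n: self[n] for n in names})

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "family": "gaussian",
            "biomarkers": {
                name: {
                    "direction": m.direction,
                    "mu_nonevent": m.mu_nonevent,
                    "sigma_nonevent": m.sigma_nonevent,
                    "mu_event": m.mu_event,
                    "sigma_event": m.sigma_event,
                    "w": m.w,
                    "n_obs": m.n_obs,
                    "loglik": None if math.isnan(m.loglik) else m.loglik,
                    "n_iter": m.n_iter,
                    "converged": m.converged,
                }
                for name, m in self.models.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EventModelSet":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if payload.get("family") != "gaussian":
            raise ValueError(f"unsupported density family: {payload.get('family')!r}")
        models = {}
        for name, d in payload["biomarkers"].items():
            models[name] = EventModel(
                biomarker=name,
                direction=d["direction"],
                mu_nonevent=d["mu_nonevent"],
                sigma_nonevent=d["sigma_nonevent"],
                mu_event=d["mu_event"],
                sigma_event=d["sigma_event"],
                w=d["w"],
                n_obs=d.get("n_obs", 0),
                loglik=d["loglik"] if d.get("loglik") is not None else math.nan,
                n_iter=d.get("n_iter", 0),
                converged=d.get("converged", True),
            )
        return cls(models)


def _em_loglik(x: np.ndarray, w: float, mu: np.ndarray, sigma: np.ndarray) -> float:
    from scipy.special import logsumexp

    comp = np.stack(
        [
            np.log1p(-w) + stats.norm.logpdf(x, mu[0], sigma[0]),
            math.log(w) + stats.norm.logpdf(x, mu[1], sigma[1]),
        ]
    )
    return float(logsumexp(comp, axis=0).sum())


#: deterministic EM initialization grid: (lower, upper) quantile pairs for
#: the component means, crossed with starting mixing weights
_INIT_QUANTILES = ((5, 50), (10, 60), (25, 75), (40, 90), (50, 95))
_INIT_WEIGHTS = (0.2, 0.5, 0.8)


def _em_run(
    x: np.ndarray,
    direction: str,
    mu0: tuple[float, float],
    sigma0: float,
    w0: float,
    floor: float,
    mu_lo: float,
    mu_hi: float,
    equal_scales: bool,
    tol: float,
    max_iter: int,
    trace: list | None = None,
) -> tuple[np.ndarray, np.ndarray, float, float, int, bool, bool]:
    """One EM run from one initialization.

    Constrained M-steps: component means are boxed to the inner data
    quantiles (the constrained maximizer of the quadratic Q is the clipped
    weighted mean), scales floored, and the event component relabeled onto
    the abnormal side whenever the ordering constraint is violated.
    """
    from scipy.special import logsumexp

    mu = np.array(mu0, dtype=float)
    sigma = np.array([sigma0, sigma0], dtype=float)
    w = w0
    prev_ll = -np.inf
    floored = False
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_r = np.stack(
            [
                np.log1p(-w) + stats.norm.logpdf(x, mu[0], sigma[0]),
                math.log(w) + stats.norm.logpdf(x, mu[1], sigma[1]),
            ]
        )
        norm = logsumexp(log_r, axis=0)
        r = np.exp(log_r - norm)
        ll = float(norm.sum())
        if trace is not None:
            trace.append(ll)

        nk = np.clip(r.sum(axis=1), 1e-12, None)
        mu = np.clip((r @ x) / nk, mu_lo, mu_hi)
        if equal_scales:
            var = (r[0] @ (x - mu[0]) ** 2 + r[1] @ (x - mu[1]) ** 2) / x.size
            sigma = np.array([math.sqrt(var), math.sqrt(var)])
        else:
            var = np.array([(r[k] @ (x - mu[k]) ** 2) / nk[k] for k in range(2)])
            sigma = np.sqrt(var)
        if np.any(sigma < floor):
            floored = True
            sigma = np.maximum(sigma, floor)
        w = min(max(float(nk[1] / x.size), 1e-6), 1 - 1e-6)

        violated = mu[1] <= mu[0] if direction == "increase" else mu[1] >= mu[0]
        if violated:
            mu = mu[::-1].copy()
            sigma = sigma[::-1].copy()
            w = 1.0 - w

        if ll - prev_ll < tol and n_iter > 1:
            converged = True
            break
        prev_ll = ll
    final_ll = _em_loglik(x, w, mu, sigma)
    return mu, sigma, w, final_ll, n_iter, converged, floored


def fit_single_biomarker(
    values: np.ndarray,
    spec: BiomarkerSpec,
    tol: float = 1e-6,
    max_iter: int = 500,
    variance_floor_frac: float = 1e-2,
    equal_scales: bool = True,
) -> EventModel:
    """Constrained two-component Gaussian EM for one biomarker.

    The fit is the best (by final log-likelihood) of a deterministic grid
    of initializations: component means at several quantile pairs, ordered
    so the event component starts on the abnormal side, crossed with three
    starting mixing weights.  Three constraints keep the mixture
    identifiable on modest samples where unconstrained ML is degenerate:

    * the two components share one scale by default (``equal_scales``),
      removing the classic unbounded-likelihood spike solutions;
    * component means are boxed to the 1st-99th percentile range, so an
      idle component cannot latch onto a single outlier;
    * scales are floored at sqrt(variance_floor_frac) x sample sd.

    No randomness enters: the fit is a deterministic function of the data.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < MIN_OBSERVATIONS:
        raise FittingError(
            f"{spec.name}: need >= {MIN_OBSERVATIONS} non-missing values, got {x.size}"
        )
    sample_sd = float(np.std(x, ddof=1))
    if sample_sd <= 1e-10 * max(1.0, abs(float(np.mean(x)))):
        raise FittingError(f"{spec.name}: all values identical (degenerate scale)")
    floor = math.sqrt(variance_floor_frac) * sample_sd
    mu_lo, mu_hi = (float(q) for q in np.percentile(x, [1, 99]))

    best = None
    for q_lo, q_hi in _INIT_QUANTILES:
        lo, hi = np.percentile(x, [q_lo, q_hi])
        mu0 = (lo, hi) if spec.direction == "increase" else (hi, lo)
        for w0 in _INIT_WEIGHTS:
            run = _em_run(
                x, spec.direction, mu0, 0.5 * sample_sd, w0,
                floor, mu_lo, mu_hi, equal_scales, tol, max_iter,
            )
            if best is None or run[3] > best[3]:
                best = run
    assert best is not None
    mu, sigma, w, final_ll, n_iter, converged, floored = best
    if floored:
        logger.warning("%s: variance floor applied during EM", spec.name)
    return EventModel(
        biomarker=spec.name,
        direction=spec.direction,
        mu_nonevent=float(mu[0]),
        sigma_nonevent=float(sigma[0]),
        mu_event=float(mu[1]),
        sigma_event=float(sigma[1]),
        w=w,
        n_obs=int(x.size),
        loglik=final_ll,
        n_iter=n_iter,
        converged=converged,
    )


def fit_event_models(
    table: CohortTable,
    panel: Sequence[BiomarkerSpec] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    variance_floor_frac: float = 1e-2,
    equal_scales: bool = True,
) -> EventModelSet:
    """Fit event/non-event densities for every biomarker in the panel,
    pooling all subjects' non-missing values."""
    panel = list(panel) if panel is not None else table.panel
    models = {}
    for spec in panel:
        values = table.data[spec.name].to_numpy(dtype=float)
        models[spec.name] = fit_single_biomarker(
            values, spec, tol=tol, max_iter=max_iter,
            variance_floor_frac=variance_floor_frac, equal_scales=equal_scales,
        )
    return EventModelSet(models)


def event_likelihoods(
    models: EventModelSet, x: float | None, biomarker: str
) -> tuple[float, float]:
    """(p(x | event), p(x | no event)) for one measurement.

    A missing x (None or NaN) returns (1, 1): the biomarker is marginalized
    out of any product it enters.
    """
    m = models[biomarker]
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return (1.0, 1.0)
    return (m.density_event(float(x)), m.density_nonevent(float(x)))


def log_likelihood_arrays(
    models: EventModelSet,
    table: CohortTable,
    names: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-by-biomarker log-density matrices (log p(x|E), log p(x|not E)).

    Missing cells carry 0.0 (= log 1), implementing the marginalization
    contract once for both sequence search and staging.  Columns follow
    ``names`` (default: the model set's order).
    """
    names = list(names) if names is not None else models.names
    X = table.biomarker_matrix(names)
    log_e = np.zeros_like(X)
    log_n = np.zeros_like(X)
    for j, name in enumerate(names):
        m = models[name]
        col = X[:, j]
        obs = np.isfinite(col)
        log_e[obs, j] = stats.norm.logpdf(col[obs], m.mu_event, m.sigma_event)
        log_n[obs, j] = stats.norm.logpdf(col[obs], m.mu_nonevent, m.sigma_nonevent)
    return log_e, log_n
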