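"""Two-component Gaussian mixture fit by EM, and bona fide element calls.

The genome-wide distribution of a motif's best promoter scores is modelled
as a mixture of a "low" component (promoters matching the matrix only by
chance) and a "high" component (promoters carrying a real element):

    f(x) = pi_low N(x; mu_low, sigma_low^2) + pi_high N(x; mu_high, sigma_high^2)

fitted by standard EM.  A promoter is called a bona fide element when the
posterior probability of the high-mean component at its score exceeds the
confidence level (default 0.95, strict inequality).

Numerical safeguards: a variance floor of max(1e-6, 1e-4 * data variance)
in every M-step prevents singular collapse on duplicated scores, and the
default initialisation is deterministic (component means at the 25th/75th
percentiles, equal mixing weights, pooled standard deviation); random
restarts run only when requested, under an explicit seed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import norm

from .scan import ScoreTable

logger = logging.getLogger(__name__)


@dataclass
class MixtureModel:
    """A fitted two-component univariate Gaussian mixture (mu_low <= mu_high)."""

    motif_id: str
    mu_low: float
    mu_high: float
    sigma_low: float
    sigma_high: float
    pi_low: float
    pi_high: float
    log_likelihood: float
    n_iter: int
    converged: bool
    n_points: int
    loglik_trace: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.mu_low > self.mu_high:
            raise ValueError("components must be ordered: mu_low <= mu_high")
        if self.sigma_low <= 0 or self.sigma_high <= 0:
            raise ValueError("sigmas must be positive")
        if abs(self.pi_low + self.pi_high - 1.0) > 1e-9:
            raise ValueError("mixing weights must sum to 1")


@dataclass
class BonaFideCalls:
    """Genes assigned to the high-scoring component above the confidence level."""

    motif_id: str
    confidence: float
    called: set[str]
    N: int  # scored universe size for this motif
    threshold: float | None = None  # unique posterior-crossing score, if any
    monotone: bool = True

    @property
    def K(self) -> int:
        return len(self.called)


def _loglik(x: np.ndarray, mu, sigma, pi) -> tuple[float, np.ndarray]:
    """Total log-likelihood and per-point component log densities (n, 2)."""
    comp = np.stack(
        [
            np.log(pi[c]) + norm.logpdf(x, mu[c], sigma[c])
            for c in range(2)
        ],
        axis=1,
    )
    per_point = logsumexp(comp, axis=1)
    return float(per_point.sum()), comp


def fit_two_component_em(
    scores,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 0,
    seed: int | None = None,
    motif_id: str = "",
) -> MixtureModel:
    """Fit the two-component mixture by EM.

    Requires at least 10 finite scores with nonzero spread.  With
    ``n_restarts > 0`` additional EM runs start from random pairs of data
    points (requires ``seed``) and the best log-likelihood wins.
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError(f"need >= 10 finite scores, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("scores have zero spread; mixture fit is undefined")
    if n_restarts > 0 and seed is None:
        raise ValueError("random restarts require a seed")

    var_floor = max(1e-6, 1e-4 * float(x.var()))
    pooled_sd = max(float(x.std()), math.sqrt(var_floor))

    inits = [
        (
            np.percentile(x, [25.0, 75.0]).astype(float),
            np.array([pooled_sd, pooled_sd]),
            np.array([0.5, 0.5]),
        )
    ]
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            mu0 = np.sort(rng.choice(x, size=2, replace=False))
            inits.append(
                (mu0.astype(float), np.array([pooled_sd, pooled_sd]),
                 np.array([0.5, 0.5]))
            )

    best: MixtureModel | None = None
    for mu, sigma, pi in inits:
        model = _em_single(
            x, mu.copy(), sigma.copy(), pi.copy(),
            tol=tol, max_iter=max_iter, var_floor=var_floor,
            motif_id=motif_id,
        )
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    assert best is not None
    if not best.converged:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations "
            f"(motif {motif_id!r})",
            RuntimeWarning,
            stacklevel=2,
        )
    return best


def _em_single(
    x, mu, sigma, pi, *, tol, max_iter, var_floor, motif_id
) -> MixtureModel:
    n = x.size
    ll_prev = -np.inf
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, comp = _loglik(x, mu, sigma, pi)
        trace.append(ll)
        # E-step: responsibilities
        gamma = np.exp(comp - logsumexp(comp, axis=1, keepdims=True))
        # M-step: weighted moments with variance floor
        nk = gamma.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        mu = (gamma * x[:, None]).sum(axis=0) / nk
        var = (gamma * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        sigma = np.sqrt(np.maximum(var, var_floor))
        pi = nk / n
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            converged = True
            break
        ll_prev = ll
    ll_final, _ = _loglik(x, mu, sigma, pi)
    trace.append(ll_final)
    order = np.argsort(mu, kind="stable")
    mu, sigma, pi = mu[order], sigma[order], pi[order]
    return MixtureModel(
        motif_id=motif_id,
        mu_low=float(mu[0]), mu_high=float(mu[1]),
        sigma_low=float(sigma[0]), sigma_high=float(sigma[1]),
        pi_low=float(pi[0]), pi_high=float(pi[1]),
        log_likelihood=ll_final, n_iter=it, converged=converged,
        n_points=n, loglik_trace=trace,
    )


def component_posterior(model: MixtureModel, score) -> np.ndarray | float:
    """Posterior probability of the high-mean component at the given score(s)."""
    x = np.asarray(score, dtype=float)
    lo = math.log(max(model.pi_low, 1e-300)) + norm.logpdf(
        x, model.mu_low, model.sigma_low
    )
    hi = math.log(max(model.pi_high, 1e-300)) + norm.logpdf(
        x, model.mu_high, model.sigma_high
    )
    post = np.exp(hi - np.logaddexp(lo, hi))
    return float(post) if np.isscalar(score) else post


def _posterior_threshold(
    model: MixtureModel, confidence: float, lo: float, hi: float
) -> float | None:
    """Unique score where the posterior crosses the confidence, if any.

    For equal component sigmas the posterior is monotone increasing in the
    score and the crossing is found by bisection on [lo, hi]; ``None`` when
    the posterior never crosses inside the bracket.
    """
    f = lambda s: component_posterior(model, s) - confidence
    a, b = lo, hi
    if f(a) >= 0:  # everything above confidence already at the low end
        return a
    if f(b) <= 0:
        return None
    return float(optimize.brentq(f, a, b, xtol=1e-12))


def _posterior_is_monotone(model: MixtureModel, lo: float, hi: float) -> bool:
    grid = np.linspace(lo, hi, 512)
    post = component_posterior(model, grid)
    return bool(np.all(np.diff(post) >= -1e-12))


def call_bona_fide(
    model: MixtureModel,
    table: ScoreTable,
    confidence: float = 0.95,
    use_raw: bool = False,
) -> BonaFideCalls:
    """Call genes whose posterior of the high component strictly exceeds
    the confidence level.

    Genes with no score for this motif are never called.  When the
    posterior is monotone over the observed score range (always true for
    equal sigmas) the implied score threshold is reported; otherwise the
    calls still follow the pointwise posterior rule and the record is
    flagged non-monotone.
    """
    if not (0 < confidence < 1):
        raise ValueError("confidence must lie strictly between 0 and 1")
    if model.mu_low == model.mu_high:
        raise ValueError(
            f"motif {model.motif_id!r}: mixture collapsed "
            "(mu_low == mu_high); bona fide calls are not meaningful"
        )
    col = "raw_score" if use_raw else "norm_score"
    sub = table.motif_hits(model.motif_id)
    if sub.empty:
        raise ValueError(f"score table has no hits for motif {model.motif_id!r}")
    scores = sub[col].to_numpy()
    genes = sub["gene_id"].to_numpy()
    post = component_posterior(model, scores)
    called = set(genes[post > confidence])
    lo, hi = float(scores.min()), float(scores.max())
    monotone = _posterior_is_monotone(model, lo, hi)
    threshold = (
        _posterior_threshold(model, confidence, lo, hi) if monotone else None
    )
    if not monotone:
        logger.warning(
            "motif %s: posterior is non-monotone over the score range; "
            "calls follow the pointwise posterior rule",
            model.motif_id,
        )
    return BonaFideCalls(
        motif_id=model.motif_id, confidence=confidence, called=called,
        N=len(sub), threshold=threshold, monotone=monotone,
    )


def mixture_report(
    models: list[MixtureModel], calls: list[BonaFideCalls]
) -> pd.DataFrame:
    """One-row-per-motif summary of fits and calls (serialisable as TSV)."""
    by_motif = {c.motif_id: c for c in calls}
    rows = []
    for m in models:
        c = by_motif.get(m.motif_id)
        rows.append(
            {
                "motif_id": m.motif_id,
                "mu_low": m.mu_low, "mu_high": m.mu_high,
                "sigma_low": m.sigma_low, "sigma_high": m.sigma_high,
                "pi_low": m.pi_low, "pi_high": m.pi_high,
                "log_likelihood": m.log_likelihood,
                "n_iter": m.n_iter, "converged": m.converged,
                "n_points": m.n_points,
                "K_called": c.K if c else None,
                "threshold": c.threshold if c else None,
                "posterior_monotone": c.monotone if c else None,
            }
        )
    return pd.DataFrame(rows)
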