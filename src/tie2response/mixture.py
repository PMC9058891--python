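"""Two-component univariate Gaussian mixture fitted by expectation-maximization.

The on-treatment log2 changes of plasma Tie2 in a VEGF-inhibitor-treated arm
are modelled as a mixture of two normal densities: a *responder* component in
which the marker falls under drug pressure, and a *placebo-like* component
whose changes match what cytotoxic chemotherapy alone produces.  Deconvoluting
the observed change distribution into these two components is the basis for
the confidence-bound response thresholds in :mod:`tie2response.response`.

The EM fit is written out explicitly (rather than delegated) because the
deconvolution is the core statistical step of the package and its behaviour —
labeling rule, degeneracy flags, restart policy, log-likelihood trace — is part
of the contract.  ``sklearn.mixture.GaussianMixture`` agrees with it on
non-degenerate data and serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

_SD_FLOOR = 1e-6  # numerical floor during iteration; degeneracy is flagged at 1e-3


class InsufficientDataError(ValueError):
    """Raised when fewer than the minimum number of finite changes is supplied."""


@dataclass(frozen=True)
class MixtureFit:
    """Maximum-likelihood two-component Gaussian fit of log2 changes.

    The component with the larger mean is labeled *placebo_like* (the marker
    does not fall without an effective anti-vascular drug); the other is the
    *responder* component.  ``degenerate`` is set when a component collapses
    (weight < 0.05 or SD < 1e-3), in which case the thresholds derived from
    the fit should not be trusted and a fallback source is preferred.
    """

    weight_responder: float
    weight_placebo_like: float
    mean_responder: float
    mean_placebo_like: float
    sd_responder: float
    sd_placebo_like: float
    loglik: float
    converged: bool
    degenerate: bool
    n_iter: int = 0
    loglik_path: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if abs(self.weight_responder + self.weight_placebo_like - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if self.mean_placebo_like < self.mean_responder:
            raise ValueError("labeling rule: mean_placebo_like >= mean_responder")


def _em(x: np.ndarray, w: float, mu: np.ndarray, sd: np.ndarray,
        max_iter: int, tol: float) -> tuple[float, np.ndarray, np.ndarray, float, bool, list[float]]:
    """Run EM from one starting point; returns (w1, means, sds, loglik, converged, path)."""
    n = x.size
    path: list[float] = []
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        log_r = np.column_stack([
            np.log(w) + norm.logpdf(x, mu[0], sd[0]),
            np.log1p(-w) + norm.logpdf(x, mu[1], sd[1]),
        ])
        log_norm = np.logaddexp(log_r[:, 0], log_r[:, 1])
        ll = float(log_norm.sum())
        path.append(ll)
        resp = np.exp(log_r - log_norm[:, None])  # responsibilities, rows sum to 1
        nk = resp.sum(axis=0)
        nk = np.clip(nk, 1e-12, None)
        w = float(np.clip(nk[0] / n, 1e-12, 1 - 1e-12))
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, _SD_FLOOR**2))
        if abs(ll - ll_old) <= tol * (1.0 + abs(ll)):
            converged = True
            break
        ll_old = ll
    return w, mu, sd, path[-1], converged, path


def fit_two_component_mixture(
    changes: Sequence[float],
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> MixtureFit:
    """Fit a two-component Gaussian mixture to log2 changes by EM.

    The first initialization splits the sorted data at the empirical 40th
    percentile (lower block seeds the responder component); the remaining
    ``n_restarts - 1`` starts draw random means/weights from ``seed``.  The
    restart with the best final log-likelihood wins.

    Parameters
    ----------
    changes : sequence of float
        Per-patient on-treatment log2 changes; at least 10 finite values.
    seed : int
        Seeds the random restarts; the fit is reproducible for a fixed seed.
    n_restarts : int
        Number of EM starts (>= 1).

    Raises
    ------
    InsufficientDataError
        If fewer than 10 finite observations are supplied.
    """
    x = np.asarray(list(changes), dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise InsufficientDataError(
            f"mixture deconvolution needs >= 10 finite changes, got {x.size}"
        )
    rng = np.random.default_rng(seed)
    sd_all = float(max(x.std(), _SD_FLOOR))

    starts = []
    xs = np.sort(x)
    k = max(1, int(round(0.4 * x.size)))
    lo, hi = xs[:k], xs[k:]
    if hi.size == 0:
        lo, hi = xs[:-1], xs[-1:]
    starts.append((
        lo.size / x.size,
        np.array([lo.mean(), hi.mean()]),
        np.maximum(np.array([lo.std(), hi.std()]), 0.25 * sd_all),
    ))
    for _ in range(max(0, n_restarts - 1)):
        mu0 = rng.choice(x, size=2, replace=False).astype(float)
        mu0.sort()
        starts.append((
            float(rng.uniform(0.2, 0.8)),
            mu0,
            np.full(2, sd_all) * rng.uniform(0.5, 1.5),
        ))

    best = None
    for w0, mu0, sd0 in starts:
        w, mu, sd, ll, conv, path = _em(x, w0, mu0, np.maximum(sd0, _SD_FLOOR), max_iter, tol)
        if best is None or ll > best[3]:
            best = (w, mu, sd, ll, conv, path)

    w, mu, sd, ll, conv, path = best
    weights = np.array([w, 1.0 - w])
    # larger-mean component is the placebo-like one
    i_resp, i_plac = (0, 1) if mu[0] <= mu[1] else (1, 0)
    degenerate = bool(weights.min() < 0.05 or sd.min() < 1e-3)
    return MixtureFit(
        weight_responder=float(weights[i_resp]),
        weight_placebo_like=float(weights[i_plac]),
        mean_responder=float(mu[i_resp]),
        mean_placebo_like=float(mu[i_plac]),
        sd_responder=float(sd[i_resp]),
        sd_placebo_like=float(sd[i_plac]),
        loglik=float(ll),
        converged=bool(conv),
        degenerate=degenerate,
        n_iter=len(path),
        loglik_path=tuple(path),
    )
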