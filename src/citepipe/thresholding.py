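"""Per-antibody expression thresholds from 1-D Gaussian mixture deconvolution.

Each marker's CLR distribution is modelled as background + signal with a
two-component univariate Gaussian mixture fitted by EM; the intersection of
the two weighted component densities between the component means is the
minimum expression threshold, and values below it are zeroed. A
negative-population quantile route is provided as a fallback for markers
where the mixture is degenerate or a negative cell population is declared.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureFit",
    "MarkerThreshold",
    "fit_mixture_1d",
    "gaussian_intersection",
    "threshold_from_negative_population",
    "fit_thresholds",
    "apply_thresholds",
    "exclude_marker",
]

_MIN_SIGMA = 1e-6
_MIN_PI = 1e-12


@dataclass
class MixtureFit:
    """Two-component univariate Gaussian mixture, components ordered mu1 <= mu2."""

    pi: np.ndarray  # weights, sum 1
    mu: np.ndarray
    sigma: np.ndarray  # > 0
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int


@dataclass
class MarkerThreshold:
    marker: str
    method: str  # mixture | negative_population | manual
    threshold: float
    pi1: float = np.nan
    mu1: float = np.nan
    sigma1: float = np.nan
    pi2: float = np.nan
    mu2: float = np.nan
    sigma2: float = np.nan
    converged: bool = False
    n_cells: int = 0


def _log_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return -0.5 * ((x - mu) / sigma) ** 2 - math.log(sigma) - 0.5 * math.log(2 * math.pi)


def mixture_loglik(x: np.ndarray, pi: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    comp = np.stack([np.log(pi[j]) + _log_pdf(x, mu[j], sigma[j]) for j in range(len(pi))])
    m = comp.max(axis=0)
    return float((m + np.log(np.exp(comp - m).sum(axis=0))).sum())


def _em(
    x: np.ndarray,
    pi: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, int]:
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: responsibilities in log space
        logr = np.stack(
            [np.log(pi[j]) + _log_pdf(x, mu[j], sigma[j]) for j in range(2)]
        )
        m = logr.max(axis=0)
        logz = m + np.log(np.exp(logr - m).sum(axis=0))
        r = np.exp(logr - logz)
        ll = float(logz.sum())
        # EM guarantees monotone log-likelihood; tolerate only rounding noise
        assert ll >= prev_ll - 1e-9 * max(1.0, abs(prev_ll)), (
            f"EM log-likelihood decreased: {prev_ll} -> {ll}"
        )
        if ll - prev_ll < tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
        # M-step
        nk = r.sum(axis=1)
        if (nk < 1e-10).any():
            return pi, mu, sigma, prev_ll, False, it
        pi = np.maximum(nk / len(x), _MIN_PI)
        pi = pi / pi.sum()
        mu = (r * x).sum(axis=1) / nk
        var = (r * (x - mu[:, None]) ** 2).sum(axis=1) / nk
        if (var < _MIN_SIGMA**2).any():
            return pi, mu, sigma, prev_ll, False, it
        sigma = np.sqrt(var)
    return pi, mu, sigma, prev_ll, converged, it


def fit_mixture_1d(
    values: np.ndarray,
    k: int = 2,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 5,
    seed: int = 0,
) -> MixtureFit:
    """Fit a 2-component Gaussian mixture by EM.

    Initialization splits the data at the median (component means = means of
    the two halves), plus seeded random restarts; the best-likelihood fit is
    kept. Components are reported with mu1 <= mu2. Degenerate data (zero
    variance) yields ``converged=False``.
    """
    if k != 2:
        raise NotImplementedError("only k=2 mixtures are supported")
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 50:
        raise ValueError(f"need >= 50 finite values, got {len(x)}")
    if np.ptp(x) < _MIN_SIGMA or np.std(x) < _MIN_SIGMA:
        return MixtureFit(
            pi=np.array([0.5, 0.5]),
            mu=np.array([x.mean(), x.mean()]),
            sigma=np.array([_MIN_SIGMA, _MIN_SIGMA]),
            loglik=np.nan,
            converged=False,
            n_iter=0,
            n_obs=len(x),
        )

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if len(hi) == 0:  # heavy ties at the median
        lo, hi = x[x < med], x[x >= med]
    sd0 = max(x.std(), _MIN_SIGMA)
    inits = [
        (
            np.array([0.5, 0.5]),
            np.array([lo.mean(), hi.mean()]),
            np.array([max(lo.std(), 0.1 * sd0), max(hi.std(), 0.1 * sd0)]),
        )
    ]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_restarts - 1)):
        mu0 = np.sort(rng.choice(x, size=2, replace=False))
        inits.append((np.array([0.5, 0.5]), mu0.astype(float), np.array([sd0, sd0])))

    best: tuple | None = None
    for pi0, mu0, sigma0 in inits:
        if abs(mu0[1] - mu0[0]) < _MIN_SIGMA:
            continue
        pi, mu, sigma, ll, conv, it = _em(x, pi0, mu0, sigma0, tol, max_iter)
        if conv and (best is None or ll > best[3]):
            best = (pi, mu, sigma, ll, conv, it)
    if best is None:
        return MixtureFit(
            pi=np.array([0.5, 0.5]),
            mu=np.array([x.mean(), x.mean()]),
            sigma=np.array([sd0, sd0]),
            loglik=np.nan,
            converged=False,
            n_iter=0,
            n_obs=len(x),
        )
    pi, mu, sigma, ll, conv, it = best
    order = np.argsort(mu)
    return MixtureFit(pi[order], mu[order], sigma[order], ll, True, it, len(x))


def gaussian_intersection(fit: MixtureFit) -> float:
    """Threshold where the weighted component densities intersect.

    Solves pi1*phi(x; mu1, s1) = pi2*phi(x; mu2, s2). With equal variances the
    closed-form root is used; otherwise the quadratic's root inside
    [mu1, mu2] is returned, falling back to the midpoint (with a warning)
    when neither root lies in the interval. Invariant to component-label
    order.
    """
    if not fit.converged:
        raise ValueError(
            "mixture did not converge; use threshold_from_negative_population "
            "or a manual threshold instead"
        )
    order = np.argsort(fit.mu)
    (pi1, pi2), (mu1, mu2), (s1, s2) = fit.pi[order], fit.mu[order], fit.sigma[order]
    if math.isclose(s1, s2, rel_tol=1e-9, abs_tol=1e-12):
        return float(0.5 * (mu1 + mu2) + s1**2 * math.log(pi1 / pi2) / (mu2 - mu1))
    a = 1.0 / s1**2 - 1.0 / s2**2
    b = -2.0 * (mu1 / s1**2 - mu2 / s2**2)
    c = mu1**2 / s1**2 - mu2**2 / s2**2 - 2.0 * math.log((pi1 * s2) / (pi2 * s1))
    disc = b * b - 4 * a * c
    if disc >= 0:
        roots = [(-b + s * math.sqrt(disc)) / (2 * a) for s in (+1, -1)]
        inside = [r for r in roots if mu1 <= r <= mu2]
        if inside:
            return float(min(inside, key=lambda r: abs(r - 0.5 * (mu1 + mu2))))
    logger.warning(
        "no density intersection in [%.3f, %.3f]; using midpoint", mu1, mu2
    )
    return float(0.5 * (mu1 + mu2))


def threshold_from_negative_population(
    values_neg: np.ndarray, quantile: float = 0.99
) -> float:
    """Threshold = upper quantile of a declared negative population's CLR values."""
    x = np.asarray(values_neg, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 50:
        raise ValueError(f"need >= 50 negative-population cells, got {len(x)}")
    if not (0 < quantile <= 1):
        raise ValueError(f"quantile must be in (0, 1], got {quantile}")
    return float(np.quantile(x, quantile))


def fit_thresholds(
    clr: pd.DataFrame,
    negative_populations: dict[str, np.ndarray] | None = None,
    manual: dict[str, float] | None = None,
    quantile: float = 0.99,
    min_separation: float = 2.0,
    seed: int = 0,
) -> list[MarkerThreshold]:
    """Fit one threshold per marker: mixture route by default, negative-
    population quantile when declared or when EM fails, manual override last.

    A marker whose fitted component means are closer than ``min_separation``
    (log2-CLR units) is treated as having no signal population; all its cells
    are then the negative population and the threshold is their upper
    ``quantile``. Set ``min_separation=0`` to disable.
    """
    negative_populations = negative_populations or {}
    manual = manual or {}
    out = []
    for m in clr.columns:
        vals = clr[m].to_numpy()
        if m in manual:
            out.append(MarkerThreshold(m, "manual", float(manual[m]), n_cells=len(vals)))
            continue
        if m in negative_populations:
            thr = threshold_from_negative_population(negative_populations[m], quantile)
            out.append(
                MarkerThreshold(m, "negative_population", thr, n_cells=len(vals))
            )
            continue
        fit = fit_mixture_1d(vals, seed=seed)
        unimodal = fit.converged and fit.mu[1] - fit.mu[0] < min_separation
        if (unimodal or not fit.converged) and min_separation > 0:
            logger.info(
                "marker %s: %s; treated as signal-free, negative-population "
                "quantile over all cells used",
                m,
                f"component means {fit.mu[1] - fit.mu[0]:.2f} apart (< {min_separation:.2f})"
                if unimodal else "mixture fit degenerate",
            )
            thr = threshold_from_negative_population(vals, quantile)
            out.append(
                MarkerThreshold(m, "negative_population", thr, n_cells=len(vals))
            )
            continue
        if fit.converged:
            thr = gaussian_intersection(fit)
            out.append(
                MarkerThreshold(
                    m, "mixture", thr,
                    pi1=fit.pi[0], mu1=fit.mu[0], sigma1=fit.sigma[0],
                    pi2=fit.pi[1], mu2=fit.mu[1], sigma2=fit.sigma[1],
                    converged=True, n_cells=fit.n_obs,
                )
            )
        else:
            raise ValueError(
                f"mixture fit failed for marker {m!r}; declare a negative "
                "population or a manual threshold for it"
            )
    return out


def thresholds_to_frame(thresholds: list[MarkerThreshold]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in thresholds]).set_index("marker")


def apply_thresholds(
    clr: pd.DataFrame, thresholds: list[MarkerThreshold] | dict[str, float]
) -> pd.DataFrame:
    """Zero out values strictly below each marker's threshold (>= kept as-is)."""
    if not isinstance(thresholds, dict):
        thresholds = {t.marker: t.threshold for t in thresholds}
    for m in clr.columns:
        if m not in thresholds:
            raise KeyError(f"no threshold for marker {m!r}")
    thr = np.array([thresholds[m] for m in clr.columns])
    vals = clr.to_numpy()
    below = vals < thr
    for j, m in enumerate(clr.columns):
        logger.info("marker %s: zeroed %d/%d cells", m, int(below[:, j].sum()), len(clr))
    return pd.DataFrame(
        np.where(below, 0.0, vals), index=clr.index, columns=clr.columns
    )


def exclude_marker(markers: list[str], exclude: str | list[str]) -> list[str]:
    """Remove marker(s) from the analysis set; unknown names warn and no-op."""
    if isinstance(exclude, str):
        exclude = [exclude]
    out = list(markers)
    for m in exclude:
        if m in out:
            out.remove(m)
            logger.info("marker %s excluded from analysis", m)
        else:
            logger.warning("exclude_marker: unknown marker %s ignored", m)
    return out
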