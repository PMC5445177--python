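"""Gamma and two-component gamma-mixture models for myelin water fraction values.

Whole-brain white-matter MWF histograms are right-skewed with one or two
prominent peaks: a low-MWF peak associated with lesional and "dirty" white
matter, and a high-MWF peak associated with normal-appearing white matter
(NAWM).  The statistical reduction implemented here fits, per subject,

* a single gamma distribution by maximum likelihood, and
* a two-component gamma mixture
  ``p(x) = lam * Gamma(x; a1, b1) + (1 - lam) * Gamma(x; a2, b2)``
  by expectation maximization,

chooses between the two with a penalized, parametric-bootstrap-calibrated
likelihood ratio test, and summarizes the mixture by three numbers: the
component modes ``m1 = (a1 - 1) * b1`` and ``m2 = (a2 - 1) * b2`` (positions
of the low- and high-MWF peaks) and the mixing ratio ``lam`` (weight of the
low-mode component, i.e. the proportion of abnormal-looking white matter).

Fitting consumes raw voxel values; no histogram binning is involved, so the
result is independent of any bin-width choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats
from sklearn.base import BaseEstimator

__all__ = [
    "GammaComponent",
    "GammaMixtureModel",
    "GammaMLE",
    "GammaMixtureEM",
    "ModelSelection",
    "DomainError",
    "DegenerateDataError",
    "ComponentCollapseError",
    "fit_single_gamma",
    "fit_gamma_mixture_em",
    "mixture_mode",
    "penalized_lrt",
    "penalized_statistic",
    "summarize_fit",
]


class DomainError(ValueError):
    """Values outside the gamma support (negative MWF) were supplied."""


class DegenerateDataError(ValueError):
    """The data carry no usable variation (e.g. all values identical)."""


class ComponentCollapseError(RuntimeError):
    """A mixture component lost (almost) all responsibility mass during EM.

    When fewer than ``min_component_obs`` effective observations support a
    component the weighted gamma MLE is meaningless; the data are better
    described by the single-gamma model.
    """


# --------------------------------------------------------------------------
# model containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GammaComponent:
    """One gamma distribution parameterized by shape ``a`` and scale ``b``.

    The density peaks at ``mode = (a - 1) * b`` when ``a > 1``; for
    ``a <= 1`` the density is monotone decreasing and the mode is 0.
    """

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shape) and self.shape > 0):
            raise ValueError(f"shape must be a positive finite number, got {self.shape}")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError(f"scale must be a positive finite number, got {self.scale}")

    @property
    def mode(self) -> float:
        return max(0.0, (self.shape - 1.0) * self.scale)

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def dist(self):
        return stats.gamma(a=self.shape, scale=self.scale)

    def pdf(self, x):
        return stats.gamma.pdf(x, a=self.shape, scale=self.scale)

    def logpdf(self, x):
        return stats.gamma.logpdf(x, a=self.shape, scale=self.scale)

    def cdf(self, x):
        return stats.gamma.cdf(x, a=self.shape, scale=self.scale)

    def ppf(self, q):
        return stats.gamma.ppf(q, a=self.shape, scale=self.scale)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.gamma(self.shape, self.scale, size=int(n))


@dataclass(frozen=True)
class GammaMixtureModel:
    """Two-component gamma mixture; ``lam`` weights the first component.

    By convention the first component is the low-mode ("abnormal WM")
    component; :meth:`ordered` returns a canonically ordered copy with
    ``comp1.mode <= comp2.mode`` and ``lam`` re-attached accordingly.
    """

    lam: float
    comp1: GammaComponent
    comp2: GammaComponent

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lam) and 0.0 <= self.lam <= 1.0):
            raise ValueError(f"mixing ratio lam must lie in [0, 1], got {self.lam}")

    @property
    def modes(self) -> tuple[float, float]:
        return (self.comp1.mode, self.comp2.mode)

    def ordered(self) -> "GammaMixtureModel":
        if self.comp1.mode <= self.comp2.mode:
            return self
        return GammaMixtureModel(1.0 - self.lam, self.comp2, self.comp1)

    def pdf(self, x):
        return self.lam * self.comp1.pdf(x) + (1.0 - self.lam) * self.comp2.pdf(x)

    def logpdf(self, x):
        return _mixture_logpdf(np.asarray(x, dtype=float), self.lam, self.comp1, self.comp2)

    def cdf(self, x):
        return self.lam * self.comp1.cdf(x) + (1.0 - self.lam) * self.comp2.cdf(x)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        n = int(n)
        low = rng.random(n) < self.lam
        out = np.empty(n, dtype=float)
        n_low = int(low.sum())
        out[low] = rng.gamma(self.comp1.shape, self.comp1.scale, size=n_low)
        out[~low] = rng.gamma(self.comp2.shape, self.comp2.scale, size=n - n_low)
        return out


def mixture_mode(comp: GammaComponent) -> float:
    """Mode of a gamma component: ``max(0, (shape - 1) * scale)``."""
    return comp.mode


# --------------------------------------------------------------------------
# numerical core
# --------------------------------------------------------------------------


def _gamma_logpdf(x, logx, shape, scale):
    # inline gamma log-density with precomputed log(x); much faster than the
    # frozen scipy call inside the EM loop
    return ((shape - 1.0) * logx - x / scale
            - shape * np.log(scale) - special.gammaln(shape))


def _mixture_logpdf(x, lam, comp1, comp2):
    with np.errstate(divide="ignore"):
        a = np.log(lam) + comp1.logpdf(x)
        b = np.log1p(-lam) + comp2.logpdf(x)
    return np.logaddexp(a, b)


def _weighted_gamma_mle(x: np.ndarray, logx: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted gamma maximum likelihood via safeguarded Newton iterations.

    Solves ``log(k) - digamma(k) = log(wmean(x)) - wmean(log x)`` for the
    shape ``k`` starting from the standard moment-style closed-form
    approximation, then sets ``scale = wmean(x) / k``.  The left-hand side is
    strictly decreasing in ``k`` so Newton steps converge quadratically; a
    halving safeguard keeps the iterate positive.
    """
    wsum = float(w.sum())
    mean = float(w @ x) / wsum
    meanlog = float(w @ logx) / wsum
    s = np.log(mean) - meanlog  # >= 0 by Jensen; == 0 iff all (weighted) values equal
    if not np.isfinite(s) or s <= 0.0:
        raise DegenerateDataError("weighted sample has no variation; gamma MLE undefined")
    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(100):
        f = np.log(k) - special.digamma(k) - s
        fprime = 1.0 / k - special.polygamma(1, k)
        k_new = k - f / fprime
        if k_new <= 0.0:
            k_new = 0.5 * k
        if abs(k_new - k) <= 1e-12 * max(1.0, abs(k)):
            k = k_new
            break
        k = k_new
    return float(k), float(mean / k)


def _as_positive_values(X, *, min_n: int) -> tuple[np.ndarray, int]:
    """Flatten, validate and return strictly positive values plus drop count.

    Negative values violate the gamma support and raise :class:`DomainError`;
    exact zeros (mask artifacts at the WM boundary) are excluded and counted.
    """
    x = np.asarray(X, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("no values supplied")
    if np.isnan(x).any():
        raise ValueError("values contain NaN")
    if (x < 0).any():
        raise DomainError("negative values are outside the gamma support")
    n_dropped = int((x == 0).sum())
    if n_dropped:
        x = x[x > 0]
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} strictly positive values, got {x.size}")
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("all values identical; gamma fit undefined")
    return x, n_dropped


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------


class GammaMLE(BaseEstimator):
    """Single-gamma maximum-likelihood fit to strictly positive values.

    Fitted attributes
    -----------------
    shape_, scale_ : float
        ML parameter estimates.
    component_ : GammaComponent
        The fitted distribution.
    log_likelihood_ : float
        Maximized log-likelihood (nats) over the retained values.
    n_obs_ : int
        Number of values used; ``n_dropped_`` zeros were excluded.
    """

    def __init__(self, min_obs: int = 10):
        self.min_obs = min_obs

    def fit(self, X, y=None):
        x, n_dropped = _as_positive_values(X, min_n=self.min_obs)
        k, theta = _weighted_gamma_mle(x, np.log(x), np.ones_like(x))
        self.component_ = GammaComponent(k, theta)
        self.shape_ = k
        self.scale_ = theta
        self.log_likelihood_ = float(self.component_.logpdf(x).sum())
        self.n_obs_ = int(x.size)
        self.n_dropped_ = n_dropped
        self.converged_ = True
        self.n_iter_ = 1
        return self

    def score_samples(self, X):
        return self.component_.logpdf(np.asarray(X, dtype=float).ravel())

    def score(self, X, y=None):
        """Total log-likelihood of ``X`` under the fitted gamma."""
        return float(self.score_samples(X).sum())


class GammaMixtureEM(BaseEstimator):
    """Two-component gamma mixture fitted by expectation maximization.

    The E-step computes per-value responsibilities of the first component;
    the M-step sets the mixing ratio to the mean responsibility and solves
    each component's weighted gamma maximum likelihood (safeguarded Newton
    on the shape).  The observed-data log-likelihood is non-decreasing
    across iterations.  After convergence the components are reordered so
    that ``mode(comp1) <= mode(comp2)``, with ``lam_`` re-attached to the
    low-mode component.

    Parameters
    ----------
    tol : float
        Relative log-likelihood change below which iteration stops.
    max_iter : int
        Iteration cap; exceeding it sets ``converged_ = False`` (no error).
    init : GammaMixtureModel, optional
        Starting point.  Default: split the values at their median,
        moment-match a gamma to each half, start with ``lam = 0.5``; if a
        half is degenerate, split at the 20th percentile instead.  This
        initialization is deterministic and scale-free.
    min_component_obs : float
        Minimum effective observations per component; below it the fit
        raises :class:`ComponentCollapseError`.
    polish : bool
        When the components overlap strongly the likelihood has a very flat
        ridge along which EM creeps; after the EM loop stops, a direct
        Nelder-Mead refinement of the same log-likelihood (in unconstrained
        coordinates) is run from the EM solution and accepted only if it
        improves the log-likelihood, so the EM path stays monotone.

    Fitted attributes
    -----------------
    model_ : GammaMixtureModel
        Canonically ordered fitted mixture.
    lam_ : float
        Weight of the low-mode component.
    m1_, m2_ : float
        Component modes, ``m1_ <= m2_``.
    log_likelihood_, ll_path_, n_iter_, converged_, n_obs_, n_dropped_
    boundary_mode_ : bool
        True when a fitted shape is <= 1, so the corresponding mode was
        truncated at zero.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 2000,
                 init: GammaMixtureModel | None = None,
                 min_component_obs: float = 10.0, min_obs: int = 50,
                 polish: bool = True):
        self.tol = tol
        self.max_iter = max_iter
        self.init = init
        self.min_component_obs = min_component_obs
        self.min_obs = min_obs
        self.polish = polish

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _moment_component(x: np.ndarray) -> GammaComponent:
        m = float(x.mean())
        v = float(x.var())
        if not (m > 0 and v > 0):
            raise DegenerateDataError("degenerate split in EM initialization")
        k = np.clip(m * m / v, 1e-3, 1e7)
        return GammaComponent(float(k), float(m / k))

    def _initial_model(self, x: np.ndarray) -> GammaMixtureModel:
        if self.init is not None:
            return self.init
        for q in (0.5, 0.2):
            cut = float(np.quantile(x, q))
            lo, hi = x[x <= cut], x[x > cut]
            if lo.size < 2 or hi.size < 2:
                continue
            try:
                return GammaMixtureModel(0.5, self._moment_component(lo),
                                         self._moment_component(hi))
            except DegenerateDataError:
                continue
        raise DegenerateDataError("could not initialize EM: values nearly constant")

    def _polish(self, x, logx, lam, c1, c2, ll):
        """Direct simplex refinement of the mixture log-likelihood.

        Works in unconstrained coordinates (logit mixing ratio, log shapes
        and scales) so every candidate is a valid mixture; the result is
        kept only when it improves on the EM log-likelihood.
        """
        from scipy import optimize

        def negll(p):
            lam_p = 1.0 / (1.0 + np.exp(-p[0]))
            a1, b1, a2, b2 = np.exp(p[1:])
            with np.errstate(divide="ignore", over="ignore"):
                la = np.log(lam_p) + _gamma_logpdf(x, logx, a1, b1)
                lb = np.log1p(-lam_p) + _gamma_logpdf(x, logx, a2, b2)
                out = -float(np.logaddexp(la, lb).sum())
            return out if np.isfinite(out) else 1e300

        lam0 = float(np.clip(lam, 1e-9, 1.0 - 1e-9))
        p0 = np.array([np.log(lam0 / (1.0 - lam0)),
                       np.log(c1.shape), np.log(c1.scale),
                       np.log(c2.shape), np.log(c2.scale)])
        # fatol scales with |ll|: the simplex f-range criterion is absolute,
        # and log-likelihood magnitudes here span 1e2..1e5
        res = optimize.minimize(negll, p0, method="Nelder-Mead",
                                options=dict(maxiter=6000, maxfev=8000,
                                             xatol=1e-6,
                                             fatol=1e-9 * (1.0 + abs(ll))))
        if -res.fun <= ll:
            return lam, c1, c2, ll, False
        lam_p = float(1.0 / (1.0 + np.exp(-res.x[0])))
        a1, b1, a2, b2 = np.exp(res.x[1:])
        return (lam_p, GammaComponent(float(a1), float(b1)),
                GammaComponent(float(a2), float(b2)), float(-res.fun), True)

    # -- API ---------------------------------------------------------------

    def fit(self, X, y=None):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        x, n_dropped = _as_positive_values(X, min_n=self.min_obs)
        logx = np.log(x)
        model = self._initial_model(x)
        lam = float(np.clip(model.lam, 1e-12, 1.0 - 1e-12))
        c1, c2 = model.comp1, model.comp2

        ll_path = []
        ll_prev = -np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            # E-step
            a = np.log(lam) + _gamma_logpdf(x, logx, c1.shape, c1.scale)
            b = np.log1p(-lam) + _gamma_logpdf(x, logx, c2.shape, c2.scale)
            denom = np.logaddexp(a, b)
            ll = float(denom.sum())
            ll_path.append(ll)
            r1 = np.exp(a - denom)
            if np.isfinite(ll_prev) and abs(ll - ll_prev) <= self.tol * (abs(ll_prev) + 1e-300):
                converged = True
                break
            ll_prev = ll
            # M-step
            w1 = r1
            w2 = 1.0 - r1
            s1, s2 = float(w1.sum()), float(w2.sum())
            if min(s1, s2) < self.min_component_obs:
                raise ComponentCollapseError(
                    f"component responsibility mass collapsed "
                    f"({min(s1, s2):.2f} < {self.min_component_obs} effective observations); "
                    "the data are likely better described by the single-gamma model")
            lam = s1 / x.size
            try:
                c1 = GammaComponent(*_weighted_gamma_mle(x, logx, w1))
                c2 = GammaComponent(*_weighted_gamma_mle(x, logx, w2))
            except DegenerateDataError as err:
                raise ComponentCollapseError(
                    f"a component degenerated during EM ({err}); "
                    "consider the single-gamma model") from err

        ll_final = float(ll_path[-1])
        polished = False
        if self.polish:
            lam, c1, c2, ll_final, polished = self._polish(x, logx, lam, c1, c2, ll_final)

        fitted = GammaMixtureModel(lam, c1, c2).ordered()
        self.model_ = fitted
        self.lam_ = float(fitted.lam)
        self.components_ = (fitted.comp1, fitted.comp2)
        self.m1_ = fitted.comp1.mode
        self.m2_ = fitted.comp2.mode
        self.modes_ = (self.m1_, self.m2_)
        self.log_likelihood_ = ll_final
        self.ll_path_ = np.asarray(ll_path)
        self.n_iter_ = n_iter
        self.converged_ = converged or polished
        self.polished_ = polished
        self.n_obs_ = int(x.size)
        self.n_dropped_ = n_dropped
        self.boundary_mode_ = bool(fitted.comp1.shape <= 1.0 or fitted.comp2.shape <= 1.0)
        return self

    def score_samples(self, X):
        return self.model_.logpdf(np.asarray(X, dtype=float).ravel())

    def score(self, X, y=None):
        """Total log-likelihood of ``X`` under the fitted mixture."""
        return float(self.score_samples(X).sum())

    def predict_proba(self, X):
        """Responsibilities of (low-mode, high-mode) components, shape (n, 2)."""
        x = np.asarray(X, dtype=float).ravel()
        m = self.model_
        a = np.log(m.lam) + m.comp1.logpdf(x)
        b = np.log1p(-m.lam) + m.comp2.logpdf(x)
        denom = np.logaddexp(a, b)
        p1 = np.exp(a - denom)
        return np.column_stack([p1, 1.0 - p1])

    def predict(self, X):
        """Hard component labels: 0 = low-mode, 1 = high-mode."""
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def summary(self) -> tuple[float, float, float]:
        return summarize_fit(self)


# --------------------------------------------------------------------------
# model selection
# --------------------------------------------------------------------------


@dataclass
class ModelSelection:
    """Outcome of the penalized likelihood ratio test (mixture vs single)."""

    statistic: float
    p_value: float
    chosen: str  # "single" | "mixture"
    n_bootstrap: int
    alpha: float
    boot_statistics: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def penalized_statistic(single: GammaMLE, mixture: GammaMixtureEM) -> float:
    """Penalized LRT statistic ``2 * (pen. mixture loglik - single loglik)``.

    The penalty ``log(4 * lam * (1 - lam))`` is zero at ``lam = 0.5`` and
    tends to minus infinity at the boundary ``lam in {0, 1}``, where the
    classical likelihood ratio test is irregular; it can only ever diminish
    the evidence for the mixture.
    """
    lam = mixture.lam_
    with np.errstate(divide="ignore"):
        penalty = float(np.log(4.0 * lam * (1.0 - lam))) if 0.0 < lam < 1.0 else -np.inf
    return 2.0 * ((mixture.log_likelihood_ + penalty) - single.log_likelihood_)


def penalized_lrt(single: GammaMLE, mixture: GammaMixtureEM, values,
                  n_bootstrap: int = 199, alpha: float = 0.05,
                  seed=None, refit_tol: float = 1e-6,
                  refit_max_iter: int = 500) -> ModelSelection:
    """Choose between single-gamma and gamma-mixture fits of the same values.

    The null distribution of the penalized statistic is approximated by a
    parametric bootstrap: ``n_bootstrap`` samples of the observed size are
    drawn from the fitted single gamma and both models are refitted on each.
    The p-value is the add-one exceedance proportion
    ``(1 + #{T_b >= T}) / (n_bootstrap + 1)`` (finite resolution: its floor
    is ``1 / (n_bootstrap + 1)``); the mixture is chosen iff ``p < alpha``.

    Bootstrap refits where the mixture collapses contribute ``-inf``
    statistics (no evidence for a mixture under the null).
    """
    if n_bootstrap < 19:
        raise ValueError("n_bootstrap must be at least 19 for usable p-value resolution")
    x, _ = _as_positive_values(values, min_n=mixture.min_obs)
    if x.size != single.n_obs_ or x.size != mixture.n_obs_:
        raise ValueError("single and mixture fits must come from the supplied values")
    t_obs = penalized_statistic(single, mixture)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        xb = rng.gamma(single.shape_, single.scale_, size=x.size)
        single_b = GammaMLE(min_obs=2).fit(xb)
        try:
            mixture_b = GammaMixtureEM(tol=refit_tol, max_iter=refit_max_iter,
                                       min_obs=2).fit(xb)
        except ComponentCollapseError:
            boot[b] = -np.inf
        else:
            boot[b] = penalized_statistic(single_b, mixture_b)
    p = (1.0 + float(np.sum(boot >= t_obs))) / (n_bootstrap + 1.0)
    chosen = "mixture" if p < alpha else "single"
    return ModelSelection(statistic=float(t_obs), p_value=float(p), chosen=chosen,
                          n_bootstrap=n_bootstrap, alpha=alpha, boot_statistics=boot)


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------


def fit_single_gamma(values) -> GammaMLE:
    """ML single-gamma fit; see :class:`GammaMLE`."""
    return GammaMLE().fit(values)


def fit_gamma_mixture_em(values, init: GammaMixtureModel | None = None,
                         tol: float = 1e-8, max_iter: int = 2000) -> GammaMixtureEM:
    """EM gamma-mixture fit; see :class:`GammaMixtureEM`."""
    return GammaMixtureEM(tol=tol, max_iter=max_iter, init=init).fit(values)


def summarize_fit(fit) -> tuple[float, float, float]:
    """Reduce a converged mixture fit to ``(m1, m2, lam)``.

    ``m1 <= m2`` by canonical ordering; ``lam`` is the weight of the
    low-mode component.  Passing a single-gamma fit is an error: consult the
    model-selection outcome before summarizing.
    """
    if isinstance(fit, GammaMLE) or not hasattr(fit, "lam_"):
        raise TypeError("summarize_fit expects a mixture fit; the model selection "
                        "outcome chose (or you supplied) a single-gamma model")
    if not fit.converged_:
        warnings.warn("summarizing a mixture fit that did not converge", RuntimeWarning,
                      stacklevel=2)
    if fit.boundary_mode_:
        warnings.warn("a fitted shape is <= 1: the corresponding mode was truncated at 0",
                      RuntimeWarning, stacklevel=2)
    return (fit.m1_, fit.m2_, fit.lam_)
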