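"""Count-likelihood loss models and their convex piecewise-quadratic proxies.

Read counts on exonic segments are modelled as negative-binomial (NB)
distributed around the expected coverage implied by the transcript
abundances, with variance growing with the mean,

    Var(V) = mu + alpha * mu^2  (+ optional additive offset beta),

so that deviations on highly covered segments are penalized less per unit
than the same absolute deviation at low coverage.  Background noise (false
alignments, incomplete RNA processing) is modelled as a Poisson with a
fixed, small mean ``lambda_bg``; a segment's count can always be "explained
as noise" at the bounded cost of the background likelihood.  The combined
likelihood of an observed count ``v`` given an expected count ``mu`` is

    L(v | mu) = max{ P_Poisson(v; lambda_bg), P_NB(v; mu, alpha) }

(the default ``combine='max'``; a mixture with weight ``pi_bg`` is also
supported).  The negative log of this likelihood, extended to non-integer
counts through log-gamma functions, is the loss minimized by the solver.

Because the NB negative log-likelihood is not convex in ``mu`` (its tail is
logarithmic), the optimizer works with a convex piecewise-quadratic proxy
per observed count: a function with a continuous, piecewise-linear,
non-decreasing gradient anchored at zero at ``mu = v``, fitted to the true
NLL by non-negative least squares on the gradient's slope increments.  The
proxy is convex by construction, attains its global minimum exactly at the
observation, and equals the true NLL there.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.special import gammaln

DEFAULT_ALPHA = 0.1
DEFAULT_LAMBDA_BG = 0.1

_LOSS_KINDS = ("nb", "poisson", "l2")


@dataclass
class LossModel:
    """Parameters of the count loss.

    Parameters
    ----------
    kind : {'nb', 'poisson', 'l2'}
        'nb' is the NB signal likelihood floored by the Poisson background;
        'poisson' drops the overdispersion term; 'l2' is the squared
        deviation (Gaussian, constant variance).
    lambda_bg : float
        Mean of the background Poisson (reads/base attributable to noise).
    dispersion : float
        NB dispersion alpha in Var = mu + alpha*mu^2.  alpha -> 0 recovers
        the Poisson.
    dispersion_offset : float
        Optional additive variance offset beta (Var = mu + alpha*mu^2 + beta).
    combine : {'max', 'mixture'}
        How background and signal likelihoods are combined.
    pi_bg : float
        Background weight when ``combine == 'mixture'``.
    """

    kind: str = "nb"
    lambda_bg: float = DEFAULT_LAMBDA_BG
    dispersion: float = DEFAULT_ALPHA
    dispersion_offset: float = 0.0
    combine: str = "max"
    pi_bg: float = 0.01

    def __post_init__(self) -> None:
        if self.kind not in _LOSS_KINDS:
            raise ValueError(f"unknown loss kind {self.kind!r}; expected one of {_LOSS_KINDS}")
        if self.lambda_bg < 0:
            raise ValueError("lambda_bg must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    # -- persistence (small key=value text file) ---------------------------
    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# splicefit loss model v1\n")
            for key in ("kind", "lambda_bg", "dispersion", "dispersion_offset", "combine", "pi_bg"):
                fh.write(f"{key}={getattr(self, key)}\n")

    @classmethod
    def from_file(cls, path) -> "LossModel":
        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                kv[key] = val
        return cls(
            kind=kv.get("kind", "nb"),
            lambda_bg=float(kv.get("lambda_bg", DEFAULT_LAMBDA_BG)),
            dispersion=float(kv.get("dispersion", DEFAULT_ALPHA)),
            dispersion_offset=float(kv.get("dispersion_offset", 0.0)),
            combine=kv.get("combine", "max"),
            pi_bg=float(kv.get("pi_bg", 0.01)),
        )


# ---------------------------------------------------------------------------
# negative log-likelihoods (continuous extension via log-gamma)
# ---------------------------------------------------------------------------

_MU_FLOOR = 1e-10


def _poisson_nll(v: np.ndarray, mu: np.ndarray) -> np.ndarray:
    mu = np.maximum(mu, _MU_FLOOR)
    return mu - v * np.log(mu) + gammaln(v + 1.0)


def _nb_nll(v: np.ndarray, mu: np.ndarray, alpha: float, beta: float = 0.0) -> np.ndarray:
    """NB NLL with mean mu, variance mu + alpha*mu^2 + beta, continuous in v.

    Parameterized through r (number of failures) and p: r = mu^2 / (Var - mu).
    For alpha, beta -> 0 this degenerates to the Poisson, handled explicitly.
    """
    mu = np.maximum(np.asarray(mu, dtype=float), _MU_FLOOR)
    v = np.asarray(v, dtype=float)
    # below alpha ~ 1e-9 the NB is numerically indistinguishable from the
    # Poisson but the log-gamma difference terms lose precision; short-circuit
    if alpha < 1e-9 and beta < 1e-12:
        return _poisson_nll(v, mu)
    extra = alpha * mu * mu + beta
    if np.all(extra < 1e-12):
        return _poisson_nll(v, mu)
    r = np.where(extra > 0, mu * mu / np.maximum(extra, 1e-300), np.inf)
    # log pmf = lgamma(v+r) - lgamma(r) - lgamma(v+1) + r*log(r/(r+mu)) + v*log(mu/(r+mu))
    with np.errstate(over="ignore", invalid="ignore"):
        ll = (
            gammaln(v + r)
            - gammaln(r)
            - gammaln(v + 1.0)
            - r * np.log1p(mu / r)
            + v * (np.log(mu) - np.log(r + mu))
        )
    ll = np.where(np.isfinite(ll), ll, -_poisson_nll(v, mu))
    return -ll


def nll_count(v, mu, model: LossModel):
    """Negative log-likelihood of observing count ``v`` at expected count ``mu``.

    For the 'nb' kind this is ``min(NLL_background, NLL_NB)`` under the
    default max-combination, i.e. every observation is explained by
    whichever of background noise or transcript signal makes it more
    likely.  Vectorized over numpy arrays; raises on negative inputs.
    """
    v_arr = np.asarray(v, dtype=float)
    mu_arr = np.asarray(mu, dtype=float)
    if np.any(v_arr < 0) or np.any(mu_arr < 0):
        raise ValueError("counts and expected counts must be non-negative")
    if model.kind == "l2":
        out = (v_arr - mu_arr) ** 2
    elif model.kind == "poisson":
        out = _poisson_nll(v_arr, mu_arr)
    else:  # nb with background floor
        sig = _nb_nll(v_arr, mu_arr, model.dispersion, model.dispersion_offset)
        bg = _poisson_nll(v_arr, np.full_like(v_arr, max(model.lambda_bg, _MU_FLOOR)))
        if model.combine == "mixture":
            pi = model.pi_bg
            out = -np.logaddexp(np.log(pi) - bg, np.log1p(-pi) - sig)
        else:
            out = np.minimum(bg, sig)
    if np.isscalar(v) and np.isscalar(mu):
        return float(out)
    return out


def nll_grad_mu(v, mu, model: LossModel):
    """d nll_count / d mu (subgradient where the background floor is active)."""
    v_arr = np.asarray(v, dtype=float)
    mu_arr = np.maximum(np.asarray(mu, dtype=float), _MU_FLOOR)
    if model.kind == "l2":
        return 2.0 * (mu_arr - v_arr)
    if model.kind == "poisson":
        return 1.0 - v_arr / mu_arr
    alpha, beta = model.dispersion, model.dispersion_offset
    if alpha < 1e-9 and beta < 1e-12:
        sig_grad = 1.0 - v_arr / mu_arr
        sig = _poisson_nll(v_arr, mu_arr)
        bg = _poisson_nll(v_arr, np.full_like(v_arr, max(model.lambda_bg, _MU_FLOOR)))
        return np.where(bg < sig, 0.0, sig_grad)
    extra = alpha * mu_arr * mu_arr + beta
    r = np.where(extra > 0, mu_arr * mu_arr / np.maximum(extra, 1e-300), np.inf)
    # d/dmu of NB NLL at fixed r would be (v+r)/(r+mu) - v/mu, but r depends on
    # mu through the variance function; for the pure alpha model
    # (beta == 0) r = 1/alpha is constant and the simple form is exact.
    grad_sig = np.where(
        np.isfinite(r), (v_arr + r) / (r + mu_arr) - v_arr / mu_arr, 1.0 - v_arr / mu_arr
    )
    sig = _nb_nll(v_arr, mu_arr, alpha, beta)
    bg = _poisson_nll(v_arr, np.full_like(v_arr, max(model.lambda_bg, _MU_FLOOR)))
    return np.where(bg < sig, 0.0, grad_sig)


# ---------------------------------------------------------------------------
# convex piecewise-quadratic proxy
# ---------------------------------------------------------------------------


@dataclass
class ProxyCurve:
    """Convex piecewise-quadratic surrogate of the NLL for one observed count.

    The curve is represented by its gradient: piecewise linear over
    ``knots``, with values ``grad_at_knots`` (non-decreasing, zero at the
    anchor ``v``), extended linearly beyond the last knot with the final
    piece's slope.  Function values follow by exact integration from the
    anchor, where the curve equals the true NLL.
    """

    v: float
    knots: np.ndarray
    grad_at_knots: np.ndarray
    f_at_anchor: float
    max_abs_deviation: float = 0.0
    _f_at_knots: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self._f_at_knots is None:
            self._f_at_knots = self._integrate_to_knots()

    def _integrate_to_knots(self) -> np.ndarray:
        t, g = self.knots, self.grad_at_knots
        # exact integral of a piecewise-linear gradient: trapezoid per piece
        seg = 0.5 * (g[1:] + g[:-1]) * np.diff(t)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        iv = int(np.argmin(np.abs(t - self.v)))
        return self.f_at_anchor + (cum - cum[iv])

    def _locate(self, mu: np.ndarray) -> np.ndarray:
        return np.clip(np.searchsorted(self.knots, mu, side="right") - 1, 0, len(self.knots) - 2)

    def grad(self, mu):
        mu_arr = np.asarray(mu, dtype=float)
        t, g = self.knots, self.grad_at_knots
        i = self._locate(mu_arr)
        slope = (g[i + 1] - g[i]) / (t[i + 1] - t[i])
        out = g[i] + slope * (mu_arr - t[i])
        return float(out) if np.isscalar(mu) else out

    def __call__(self, mu):
        mu_arr = np.asarray(mu, dtype=float)
        t, g, f = self.knots, self.grad_at_knots, self._f_at_knots
        i = self._locate(mu_arr)
        slope = (g[i + 1] - g[i]) / (t[i + 1] - t[i])
        d = mu_arr - t[i]
        out = f[i] + g[i] * d + 0.5 * slope * d * d
        return float(out) if np.isscalar(mu) else out

    def piece_coefficients(self) -> np.ndarray:
        """Per-piece quadratics: rows (t_lo, t_hi, c0, c1, c2) with
        proxy(mu) = c0 + c1*(mu - t_lo) + c2*(mu - t_lo)^2 on [t_lo, t_hi)."""
        t, g, f = self.knots, self.grad_at_knots, self._f_at_knots
        slope = np.diff(g) / np.diff(t)
        return np.column_stack([t[:-1], t[1:], f[:-1], g[:-1], 0.5 * slope])


def _proxy_knots(v: float, t_max: float, n_pieces: int) -> np.ndarray:
    """Geometric breakpoints around the anchor v.

    Left of v the NLL diverges like -v*log(mu), so knots crowd toward 0
    (interior knots at v * q^j); right of v the gaps double away from the
    anchor, where the NLL flattens.
    """
    n_left = max(1, n_pieces // 2) if v > 1e-9 * t_max else 0
    if n_left:
        v = max(v, 1e-9 * t_max)  # keep knots strictly increasing
    n_right = max(1, n_pieces - n_left)

    w = (2.0 ** np.arange(1, n_right + 1) - 1.0) / (2.0**n_right - 1.0)
    right = v + (t_max - v) * np.concatenate([[0.0], w])
    if n_left == 0:
        return right
    q = 0.3
    left = v * np.concatenate([[0.0], q ** np.arange(n_left - 1, 0, -1)])
    return np.concatenate([left, right])


def fit_proxy(
    v: float,
    model: LossModel,
    n_pieces: int = 6,
    n_grid: int = 200,
    min_slope: float = 1e-8,
    cap_frac: float = 0.05,
) -> ProxyCurve:
    """Fit the convex piecewise-quadratic proxy of ``nll_count(v, .)``.

    The mu-grid spans [0, max(4v, 20)].  The fit minimizes the squared
    deviation from the true NLL over the grid, subject to convexity
    (non-decreasing gradient) and the anchored minimum at mu = v, by
    non-negative least squares on the gradient's slope increments.

    The NLL diverges like -v*log(mu) as mu -> 0; chasing that singularity
    would distort the fit everywhere else (and make the curve sag below
    the truth just right of zero), so the fit target is capped at its
    value at ``mu = cap_frac * v``.  ``max_abs_deviation`` is reported
    over the uncapped region.  ``min_slope`` enforces a strictly positive
    gradient step on the pieces flanking the anchor so the minimizer is
    unique.
    """
    if n_pieces < 2:
        raise ValueError("n_pieces must be >= 2")
    if v < 0:
        raise ValueError("observed count must be >= 0")
    v = float(v)
    t_max = max(4.0 * v, 20.0)
    knots = _proxy_knots(v, t_max, n_pieces)
    iv = int(np.argmin(np.abs(knots - v)))
    grid = np.unique(
        np.concatenate(
            [
                np.linspace(0.0, t_max, n_grid),
                # extra resolution where the NLL is steep (small mu)
                np.geomspace(1e-3 * t_max, max(v, 0.02 * t_max), 40),
                knots,
            ]
        )
    )
    y = np.asarray(nll_count(np.full_like(grid, v), grid, model), dtype=float)
    cap_mu = 0.0
    if v > 0 and model.kind != "l2":  # the L2 loss has no singularity at 0
        cap_mu = max(cap_frac * v, 1e-3 * t_max)
        y = np.minimum(y, float(nll_count(v, cap_mu, model)))
    f0 = float(nll_count(v, max(v, 0.0), model))

    m = len(knots)
    n_right = m - 1 - iv
    n_left = iv
    n_par = n_left + n_right

    # design matrix: column k = integral from v to mu of the gradient profile
    # produced by a unit increment of slope-step k (right steps raise g on
    # knots > v, left steps lower g on knots < v)
    design = np.empty((len(grid), n_par))
    col = 0
    for j in range(n_right):  # unit step between right knots iv+j and iv+j+1
        g = np.zeros(m)
        g[iv + 1 + j :] = 1.0
        design[:, col] = _integral_from_anchor(knots, g, iv, grid)
        col += 1
    for j in range(n_left):  # unit (negative) step between left knots
        g = np.zeros(m)
        g[: iv - j] = -1.0
        design[:, col] = _integral_from_anchor(knots, g, iv, grid)
        col += 1

    target = y - f0
    deltas, _ = nnls(design, target)
    deltas = np.maximum(deltas, 0.0)
    if n_right:
        deltas[0] = max(deltas[0], min_slope)
    if n_left:
        deltas[n_right] = max(deltas[n_right], min_slope)

    g = np.zeros(m)
    for j in range(n_right):
        g[iv + 1 + j :] += deltas[j]
    for j in range(n_left):
        g[: iv - j] -= deltas[n_right + j]

    curve = ProxyCurve(v=v, knots=knots, grad_at_knots=g, f_at_anchor=f0)
    report = grid >= cap_mu
    curve.max_abs_deviation = float(np.max(np.abs(curve(grid[report]) - y[report])))
    return curve


def _integral_from_anchor(knots: np.ndarray, g: np.ndarray, iv: int, mu: np.ndarray) -> np.ndarray:
    """Exact integral of the piecewise-linear gradient ``g`` from knots[iv] to mu."""
    seg = 0.5 * (g[1:] + g[:-1]) * np.diff(knots)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    cum -= cum[iv]
    i = np.clip(np.searchsorted(knots, mu, side="right") - 1, 0, len(knots) - 2)
    slope = (g[i + 1] - g[i]) / (knots[i + 1] - knots[i])
    d = mu - knots[i]
    return cum[i] + g[i] * d + 0.5 * slope * d * d


# ---------------------------------------------------------------------------
# noise parameter estimation from single-transcript loci
# ---------------------------------------------------------------------------


def estimate_noise_params(
    single_isoform_loci,
    background=None,
    min_loci: int = 10,
    default_alpha: float = DEFAULT_ALPHA,
    default_lambda: float = DEFAULT_LAMBDA_BG,
    kind: str = "nb",
) -> LossModel:
    """Method-of-moments fit of the NB dispersion from single-transcript loci.

    Each locus contributes the vector of its per-segment coverages (all
    segments of a single-isoform gene share one expected coverage, so the
    spread across segments estimates the noise variance at that mean).
    ``single_isoform_loci`` is a list of 1-D coverage arrays, or of
    ``(ObservationSet, segment_indicator)`` pairs from which one coverage
    vector per sample is extracted.  The dispersion alpha solves the
    weighted least-squares fit of (sample variance - mean) against mean^2.
    ``background`` is an optional array of intronic/intergenic coverages
    whose mean estimates lambda_bg.
    """
    vectors = []
    for locus in single_isoform_loci:
        if isinstance(locus, tuple) and hasattr(locus[0], "seg_counts"):
            obs, indicator = locus
            idx = np.flatnonzero(np.asarray(indicator))
            for row in np.asarray(obs.seg_counts):
                vec = row[idx]
                if vec.size >= 2 and vec.sum() > 0:
                    vectors.append(vec.astype(float))
        else:
            vec = np.asarray(locus, dtype=float)
            if vec.size >= 2 and vec.sum() > 0:
                vectors.append(vec)

    lam = float(np.mean(background)) if background is not None and len(background) else default_lambda

    if len(vectors) < min_loci:
        warnings.warn(
            f"only {len(vectors)} usable single-isoform loci (< {min_loci}); "
            "falling back to shipped default dispersion",
            stacklevel=2,
        )
        return LossModel(kind=kind, lambda_bg=lam, dispersion=default_alpha)

    means = np.array([vec.mean() for vec in vectors])
    variances = np.array([vec.var(ddof=1) for vec in vectors])
    keep = means > 0
    means, variances = means[keep], variances[keep]
    # Var - mean = alpha * mean^2  ->  LS through the origin
    num = float(np.sum((variances - means) * means**2))
    den = float(np.sum(means**4))
    alpha = max(0.0, num / den) if den > 0 else default_alpha
    return LossModel(kind=kind, lambda_bg=lam, dispersion=alpha)
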