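"""Maximum-likelihood estimation of the milking-session model.

The standardized residuals (Y_O(k) - E(Y_M(k))) / sqrt(Var(Y_M(k))) are
standard normal under a correct model, so the Gaussian log-likelihood

    sum_k [ -0.5 log(2 pi Var(Y_M(k))) - 0.5 (Y_O(k) - E(Y_M(k)))^2 / Var(Y_M(k)) ]

is maximized jointly over the mean parameters (delta, lambda_A, lambda_R,
pi, PL per segment) and the variance parameter phi.  Positive parameters
are optimized as theta = exp(alpha) and unit-interval parameters as
theta = exp(-exp(alpha)), both over unconstrained alpha.  Estimator
variances come from the inverse Hessian of the negative log-likelihood at
the optimum; 95% confidence intervals are formed on the transformed scale
(normality of ML estimators) and back-transformed.

The two-stage workflow first fits a constant-PL, constant-pi model, then
feeds its standardized residuals to the conditional-element detectors
(extreme-retention sessions, secretion-rate changepoints), and finally
refits with segment-wise PL(k) and session-specific pi(k).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from . import conditional
from .data import LactationSeries
from .params import MeanParams, VarParams
from .variance import propagate_moment_arrays

__all__ = [
    "FitConfig",
    "FitResult",
    "transform_to_natural",
    "transform_to_working",
    "log_likelihood",
    "fit",
    "two_stage_fit",
]

log = logging.getLogger(__name__)

_Z95 = 1.959963984540054

# transform tags
POSITIVE = "positive"
UNIT = "unit_interval"


def transform_to_natural(alpha: float, kind: str) -> float:
    """Working-scale alpha -> natural-scale theta."""
    a = np.clip(alpha, -700.0, 700.0)
    if kind == POSITIVE:
        return float(np.exp(np.clip(a, -700.0, 50.0)))
    if kind == UNIT:
        return float(np.exp(-np.exp(np.clip(a, -30.0, 6.0))))
    raise ValueError(f"unknown transform {kind!r}")


def transform_to_working(theta: float, kind: str) -> float:
    """Natural-scale theta -> working-scale alpha (inverse transform)."""
    if kind == POSITIVE:
        if theta <= 0:
            raise ValueError("positive-transform parameter must be > 0")
        return float(np.log(theta))
    if kind == UNIT:
        if not 0.0 < theta < 1.0:
            raise ValueError("unit-transform parameter must be in (0, 1)")
        return float(np.log(-np.log(theta)))
    raise ValueError(f"unknown transform {kind!r}")


@dataclass
class FitConfig:
    """Model structure and optimizer settings for one fit."""

    segment_starts: tuple = (1,)
    extreme_sessions: tuple = ()
    interval_uncertainty: bool = False
    cv_measurement: float = 0.025
    var_t: float = 0.25
    nominal_deltas: tuple = (14.0, 10.0)
    init: dict = field(default_factory=dict)
    maxiter: int = 500
    gtol: float = 1e-6
    # detector settings (two-stage workflow)
    alpha_extreme: float = 0.001
    alpha_changepoint: float = 0.05
    # screening level for candidate boundaries inside the iterative
    # workflow; candidates are confirmed on the refitted model afterwards
    alpha_candidates: float = 0.5
    min_segment_length: int = 30

    def parameter_spec(self):
        """Ordered (name, transform) pairs of the free parameters."""
        spec = [
            ("delta", POSITIVE),
            ("lambda_a", POSITIVE),
            ("lambda_r", POSITIVE),
            ("pi", UNIT),
        ]
        if self.extreme_sessions:
            spec.append(("pi_extreme", UNIT))
        spec += [(f"pl_{i + 1}", POSITIVE) for i in range(len(self.segment_starts))]
        spec.append(("phi", UNIT))
        return spec


@dataclass
class FitResult:
    """Estimates, uncertainty and diagnostics of one ML fit."""

    estimates: dict
    ci: dict
    log_likelihood: float
    std_residuals: np.ndarray
    vcov_working: Optional[np.ndarray]
    converged: bool
    n_iter: int
    message: str
    variance_explained_ratio: float
    mean_params: MeanParams
    var_params: VarParams
    config: FitConfig
    fitted_mean: np.ndarray
    fitted_var: np.ndarray

    @property
    def pl_max(self) -> float:
        return self.mean_params.pl_max

    @property
    def beta_segments(self) -> np.ndarray:
        return self.mean_params.beta_segments

    def summary_dict(self) -> dict:
        return {
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "ci95": {
                k: (None if v is None else [float(v[0]), float(v[1])])
                for k, v in self.ci.items()
            },
            "log_likelihood": float(self.log_likelihood),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "variance_explained_ratio": float(self.variance_explained_ratio),
            "pl_max": float(self.pl_max),
            "beta_segments": [float(b) for b in self.beta_segments],
            "segment_starts": [int(s) for s in self.config.segment_starts],
            "extreme_sessions": [int(s) for s in self.config.extreme_sessions],
        }


def _build_params(theta: dict, config: FitConfig):
    n_seg = len(config.segment_starts)
    pls = tuple(theta[f"pl_{i + 1}"] for i in range(n_seg))
    overrides = {}
    if config.extreme_sessions:
        overrides = {int(k): theta["pi_extreme"] for k in config.extreme_sessions}
    mp = MeanParams(
        delta=theta["delta"],
        lambda_a=theta["lambda_a"],
        lambda_r=theta["lambda_r"],
        pi=theta["pi"],
        pl_segments=pls,
        segment_starts=config.segment_starts,
        pi_overrides=overrides,
    )
    vp = VarParams(
        phi=theta["phi"],
        cv_measurement=config.cv_measurement,
        var_t=config.var_t,
        nominal_deltas=config.nominal_deltas,
    )
    return mp, vp


def _moments(series: LactationSeries, mp: MeanParams, vp: VarParams, interval_uncertainty: bool):
    if interval_uncertainty:
        sched = series.nominal_schedule(mp.delta, vp.nominal_deltas)
    else:
        sched = series.schedule(mp.delta)
    return propagate_moment_arrays(sched, mp, vp, interval_uncertainty)


def log_likelihood(
    series: LactationSeries,
    mean_params: MeanParams,
    var_params: VarParams,
    interval_uncertainty: bool = False,
) -> float:
    """Gaussian log-likelihood of the observed yields under the model."""
    a = _moments(series, mean_params, var_params, interval_uncertainty)
    v = a["var_total"]
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("non-positive model variance")
    r = series.yields_kg - a["mean_measured"]
    return float(-0.5 * np.sum(np.log(2.0 * np.pi * v) + r * r / v))


def _initial_theta(series: LactationSeries, config: FitConfig) -> dict:
    pl0 = float(np.max(series.yields_kg)) / 10.0
    theta = {
        "delta": 72.0,
        "lambda_a": 5e-3,
        "lambda_r": 5e-5,
        "pi": 0.05,
        "phi": 0.5,
    }
    if config.extreme_sessions:
        theta["pi_extreme"] = 0.2
    for i in range(len(config.segment_starts)):
        theta[f"pl_{i + 1}"] = pl0
    theta.update(config.init)
    return theta


def _numeric_hessian(f, x, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar f at x."""
    n = len(x)
    h = step * (1.0 + np.abs(x))
    hess = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                val = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (h[i] ** 2)
            else:
                val = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    return hess


def fit(series: LactationSeries, config: Optional[FitConfig] = None) -> FitResult:
    """Maximum-likelihood fit of the milking-session model.

    Raises
    ------
    ValueError
        If the series has fewer than 20 sessions.
    """
    if len(series) < 20:
        raise ValueError("at least 20 sessions are required for a fit")
    config = config or FitConfig()
    spec = config.parameter_spec()
    names = [n for n, _ in spec]
    kinds = dict(spec)
    theta0 = _initial_theta(series, config)
    x0 = np.array([transform_to_working(theta0[n], kinds[n]) for n in names])

    bad = 1e10

    def nll(x):
        theta = {n: transform_to_natural(a, kinds[n]) for n, a in zip(names, x)}
        # identifiability: swapping (lambda_a, lambda_r) and rescaling PL
        # leaves the mean trajectory invariant; activation is the fast
        # process, so the lambda_a > lambda_r branch is the physical one.
        # A smooth penalty (not a cliff) keeps line searches stable.
        ratio = theta["lambda_r"] / theta["lambda_a"]
        penalty = 0.0 if ratio < 0.8 else 1e4 * (ratio - 0.8) ** 2
        if ratio >= 1.0:
            return bad
        try:
            mp, vp = _build_params(theta, config)
            ll = log_likelihood(series, mp, vp, config.interval_uncertainty)
        except (ValueError, FloatingPointError, OverflowError):
            return bad
        if not np.isfinite(ll):
            return bad
        return -ll + penalty + _range_penalty(x)

    # Physical working-scale ranges, enforced as smooth quadratic
    # penalties so the quasi-Newton search cannot drift onto the flat
    # saturated plateaus of the transforms: activation happens within the
    # first weeks (lambda_a >= ~1e-4 /h), inactivation over the whole
    # ~305-day lactation (lambda_r <= ~1e-3 /h).
    _ranges = {
        "delta": (np.log(1.0), np.log(1000.0)),
        "lambda_a": (np.log(1e-4), np.log(0.1)),
        "lambda_r": (np.log(1e-9), np.log(1e-3)),
    }
    unit_b = (np.log(-np.log(0.999)), np.log(-np.log(1e-6)))
    pos_b = (np.log(1e-3), np.log(1e3))
    lo = np.array([_ranges.get(n, unit_b if kinds[n] == UNIT else pos_b)[0] for n in names])
    hi = np.array([_ranges.get(n, unit_b if kinds[n] == UNIT else pos_b)[1] for n in names])

    def _range_penalty(x):
        over = np.maximum(x - hi, 0.0)
        under = np.maximum(lo - x, 0.0)
        return 1e3 * float(np.sum(over**2 + under**2))

    def _minimize(start):
        return optimize.minimize(
            nll,
            start,
            method="BFGS",
            options={"maxiter": config.maxiter, "gtol": config.gtol},
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _minimize(x0)
        if res.fun >= bad:
            res = _minimize(x0 + 0.1)
        elif not res.success:
            # restart resets the Hessian approximation; recovers from
            # stalled line searches near the optimum
            res2 = _minimize(res.x)
            if res2.fun <= res.fun:
                res = res2
        if res.fun > nll(x0) - 1e-6:
            # no progress at all (the first quasi-Newton step can
            # overshoot badly from a cold start): derivative-free warm-up,
            # then polish
            nm = optimize.minimize(
                nll, x0, method="Nelder-Mead",
                options={"maxfev": 4000, "xatol": 1e-4, "fatol": 1e-6},
            )
            res3 = _minimize(nm.x)
            if res3.fun <= res.fun:
                res = res3

        def _saturated(x):
            th = {n: transform_to_natural(a, kinds[n]) for n, a in zip(names, x)}
            unit_hi = any(th[n] > 0.995 for n, k in kinds.items() if k == UNIT)
            return th["lambda_r"] <= 2e-9 or unit_hi

        if _saturated(res.x):
            # a saturated transform marks a degenerate ridge (e.g. the
            # secretion staircase absorbing the whole decline with
            # lambda_r -> 0); retry from the default start and keep the
            # better optimum
            from dataclasses import replace as _replace

            clean = _initial_theta(series, _replace(config, init={}))
            x0_default = np.array(
                [transform_to_working(clean[n], kinds[n]) for n in names]
            )
            res4 = _minimize(x0_default)
            if res4.fun <= res.fun or (
                res4.fun <= res.fun + 2.0 and not _saturated(res4.x)
            ):
                res = res4

    xhat = res.x
    theta_hat = {n: transform_to_natural(a, kinds[n]) for n, a in zip(names, xhat)}
    mp, vp = _build_params(theta_hat, config)
    a = _moments(series, mp, vp, config.interval_uncertainty)
    resid = (series.yields_kg - a["mean_measured"]) / np.sqrt(a["var_total"])
    ver = float(np.sum(a["var_total"]) / np.sum((series.yields_kg - a["mean_measured"]) ** 2))

    # Hessian-based confidence intervals on the working scale
    vcov = None
    ci = {n: None for n in names}
    try:
        hess = _numeric_hessian(nll, xhat)
        try:
            vcov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(hess)
        if not np.all(np.isfinite(vcov)):
            vcov = None
            raise np.linalg.LinAlgError("non-finite covariance")
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(vcov))
        for n, ahat, s in zip(names, xhat, se):
            if not np.isfinite(s):
                continue
            lo_a, hi_a = ahat - _Z95 * s, ahat + _Z95 * s
            lo = transform_to_natural(lo_a, kinds[n])
            hi = transform_to_natural(hi_a, kinds[n])
            ci[n] = (min(lo, hi), max(lo, hi))
    except np.linalg.LinAlgError:
        log.warning("singular Hessian: confidence intervals unavailable")

    # BFGS with finite-difference gradients routinely stops with
    # "precision loss" once gradient noise dominates; accept the optimum
    # when the gradient is small on the scale of the log-likelihood.
    grad_ok = res.jac is not None and np.max(np.abs(res.jac)) < 0.1
    converged = (bool(res.success) or grad_ok) and res.fun < bad
    if not converged:
        log.warning("fit did not converge: %s", res.message)
    return FitResult(
        estimates=theta_hat,
        ci=ci,
        log_likelihood=float(-res.fun),
        std_residuals=resid,
        vcov_working=vcov,
        converged=converged,
        n_iter=int(res.nit),
        message=str(res.message),
        variance_explained_ratio=ver,
        mean_params=mp,
        var_params=vp,
        config=config,
        fitted_mean=a["mean_measured"],
        fitted_var=a["var_total"],
    )


def _structured_config(config: FitConfig, starts, flags, warm) -> FitConfig:
    return FitConfig(
        segment_starts=tuple(starts),
        extreme_sessions=tuple(sorted(flags)),
        interval_uncertainty=config.interval_uncertainty,
        cv_measurement=config.cv_measurement,
        var_t=config.var_t,
        nominal_deltas=config.nominal_deltas,
        init=warm,
        maxiter=config.maxiter,
        gtol=config.gtol,
        alpha_extreme=config.alpha_extreme,
        alpha_changepoint=config.alpha_changepoint,
        min_segment_length=config.min_segment_length,
    )


def _warm_start(result: FitResult, new_starts, n_sessions: int, has_extreme: bool) -> dict:
    warm = {
        "delta": result.estimates["delta"],
        "lambda_a": result.estimates["lambda_a"],
        "lambda_r": result.estimates["lambda_r"],
        "pi": result.estimates["pi"],
        "phi": result.estimates["phi"],
    }
    if has_extreme:
        warm["pi_extreme"] = result.estimates.get("pi_extreme", 0.2)
    # carry the previous fit's PL(k) profile onto the new segmentation
    pl_prev = result.mean_params.pl_for_sessions(n_sessions)
    for i, s in enumerate(new_starts):
        warm[f"pl_{i + 1}"] = float(pl_prev[min(s, n_sessions) - 1])
    return warm


def _merge_starts(existing, new, min_spacing: int, n_sessions: int):
    """Union of boundary sets, dropping new boundaries that crowd an
    existing one or the series ends closer than ``min_spacing``."""
    starts = sorted(set(existing))
    for s in sorted(set(new)):
        if s <= 1 or s > n_sessions - min_spacing + 1:
            continue
        if all(abs(s - t) >= min_spacing for t in starts):
            starts.append(s)
            starts.sort()
    return tuple(starts)


def _polish_boundaries(
    series: LactationSeries,
    result: FitResult,
    config: FitConfig,
    radius: int = 30,
    step: int = 5,
):
    """Greedy profile-likelihood adjustment of boundary positions.

    Detection grids and screening can place a boundary a few tens of
    sessions off the true step; with the continuous parameters held at
    their current estimates, sliding each boundary within ``radius``
    sessions and keeping the likelihood-maximizing position corrects the
    offset at negligible cost.  Candidate positions lie on a coarse
    ``step``-session lattice: a finer search would mostly chase noise
    (post-selection bias in the variance parameters).  Returns the
    polished fit (a single refit at the adjusted segmentation), or the
    input fit if nothing moved.
    """
    starts = list(result.config.segment_starts)
    if len(starts) < 2:
        return result
    mp0, vp0 = result.mean_params, result.var_params
    n = len(series)
    moved = False
    for j in range(1, len(starts)):
        lo = (starts[j - 1] if j >= 1 else 1) + config.min_segment_length
        hi = (starts[j + 1] if j + 1 < len(starts) else n + 1) - config.min_segment_length
        cand = list(range(max(lo, starts[j] - radius), min(hi, starts[j] + radius) + 1, step))
        if starts[j] not in cand:
            cand.append(starts[j])
        if len(cand) <= 1:
            continue
        best_p, best_ll = starts[j], -np.inf
        for p in cand:
            trial = tuple(starts[:j] + [p] + starts[j + 1 :])
            mp = mp0.with_(segment_starts=trial)
            try:
                ll = log_likelihood(series, mp, vp0, config.interval_uncertainty)
            except ValueError:
                continue
            if ll > best_ll:
                best_p, best_ll = p, ll
        if best_p != starts[j]:
            starts[j] = best_p
            mp0 = mp0.with_(segment_starts=tuple(starts))
            moved = True
    if not moved:
        return result
    cfg = _structured_config(
        config, tuple(starts), result.config.extreme_sessions,
        _warm_start(result, tuple(starts), n, bool(result.config.extreme_sessions)),
    )
    try:
        refit = fit(series, cfg)
    except ValueError:
        return result
    return refit if refit.log_likelihood >= result.log_likelihood else result


def _confirm_boundaries(result: FitResult):
    """Boundaries whose adjacent log-PL difference is Wald-significant
    at 5% in the given fit.

    The working scale of PL is log PL, so the fitted covariance applies
    directly.  The weakest non-significant boundary is removed first and
    the test repeated on the merged neighbours (approximated from the
    same covariance: the merged segment's log PL is the precision-weighted
    mean of its parts).
    """
    starts = list(result.config.segment_starts)
    z_thr = _Z95
    if (
        len(starts) < 2
        or result.vcov_working is None
        or not np.all(np.isfinite(result.vcov_working))
    ):
        return tuple(starts)
    names = [n for n, _ in result.config.parameter_spec()]
    idx = {n: i for i, n in enumerate(names)}
    # groups of original segment indices (0-based), merged progressively
    groups = [[j] for j in range(len(starts))]
    v = result.vcov_working
    logpl = np.array([np.log(result.estimates[f"pl_{j + 1}"]) for j in range(len(starts))])
    pl_idx = [idx[f"pl_{j + 1}"] for j in range(len(starts))]

    def group_stats(g):
        ii = [pl_idx[j] for j in g]
        w = np.array([1.0 / max(v[i, i], 1e-12) for i in ii])
        mean = float(np.sum(w * logpl[g]) / np.sum(w))
        var = 1.0 / float(np.sum(w))
        return mean, var, ii

    while len(groups) > 1:
        stats = [group_stats(g) for g in groups]
        zs = []
        for a, b in zip(stats, stats[1:]):
            cross = np.mean([[v[i, j] for j in b[2]] for i in a[2]])
            se2 = max(a[1] + b[1] - 2.0 * cross, 1e-12)
            zs.append(abs(a[0] - b[0]) / np.sqrt(se2))
        weakest = int(np.argmin(zs))
        if zs[weakest] >= z_thr:
            break
        groups[weakest] = groups[weakest] + groups.pop(weakest + 1)
    return tuple(starts[g[0]] for g in groups)


def two_stage_fit(
    series: LactationSeries,
    config: Optional[FitConfig] = None,
    max_refinements: int = 3,
):
    """Full workflow: constant-parameter fit, conditional-element
    discovery on its residuals, refit with the discovered structure.

    A constant-parameter fit partially absorbs the secretion-rate
    staircase into the smooth inactivation decline, which mutes the
    residual steps; single boundaries added one at a time barely improve
    the likelihood because the inactivation rate only relaxes once
    several boundaries enter jointly.  The workflow therefore (1) screens
    liberally — changepoint candidates at ``alpha_candidates`` on the
    current residuals, unioned over up to ``max_refinements`` detect/refit
    rounds — so the jointly refitted rich model identifies the smooth
    parameters well, then (2) confirms each boundary with a Wald test on
    the adjacent log-PL difference in that rich model and refits on the
    confirmed segmentation.

    Returns ``(final_fit, elements)``.  If the detectors find nothing the
    stage-1 fit is returned unchanged; any failed refit degrades
    gracefully to the last good fit.
    """
    config = config or FitConfig()
    stage1_cfg = FitConfig(
        segment_starts=(1,),
        extreme_sessions=(),
        interval_uncertainty=config.interval_uncertainty,
        cv_measurement=config.cv_measurement,
        var_t=config.var_t,
        nominal_deltas=config.nominal_deltas,
        init=config.init,
        maxiter=config.maxiter,
        gtol=config.gtol,
    )
    current = fit(series, stage1_cfg)
    starts = (1,)
    flags: set = set()
    n = len(series)

    for round_i in range(max_refinements):
        try:
            found_flags = conditional.detect_extreme_retention(
                current.std_residuals, config.alpha_extreme
            )
            exclude = flags | found_flags
            exclude |= {k + 1 for k in exclude}
            # re-detect within each currently fitted segment: boundaries
            # already in the model are zero-gain for a whole-sequence scan
            # but still cost penalty there, hiding interior steps
            cands = []
            seg_edges = list(starts) + [n + 1]
            for lo_s, hi_s in zip(seg_edges, seg_edges[1:]):
                z_seg = current.std_residuals[lo_s - 1 : hi_s - 1]
                excl_seg = {k - lo_s + 1 for k in exclude if lo_s <= k < hi_s}
                local = conditional.detect_beta_segments(
                    z_seg,
                    alpha=config.alpha_candidates,
                    min_segment_length=config.min_segment_length,
                    exclude_sessions=excl_seg,
                )
                cands.extend(lo_s + b - 1 for b in local if b > 1)
            if round_i == 0:
                # sieve grid: a constant-parameter fit absorbs much of a
                # secretion-rate staircase into the inactivation decline,
                # muting the residual steps the detector relies on; a
                # provisional over-segmentation frees the smooth
                # parameters regardless of detection luck, and redundant
                # boundaries are merged again at confirmation
                cands.extend(range(1 + 2 * config.min_segment_length, n - config.min_segment_length, 2 * config.min_segment_length))
        except ValueError as err:
            log.warning("conditional-element detection failed (%s)", err)
            break
        new_starts = _merge_starts(starts, cands, config.min_segment_length, n)
        new_flags = flags | found_flags
        if new_starts == starts and new_flags == flags:
            break
        cfg = _structured_config(
            config, new_starts, new_flags,
            _warm_start(current, new_starts, n, bool(new_flags)),
        )
        try:
            refit = fit(series, cfg)
        except ValueError as err:
            log.warning("refit failed (%s); keeping previous stage", err)
            break
        # the previous model is nested in the refit, so a correct refit
        # optimum cannot be worse
        if refit.log_likelihood < current.log_likelihood:
            log.warning("refit did not improve the likelihood; keeping previous stage")
            break
        current, starts, flags = refit, new_starts, new_flags

    current = _polish_boundaries(series, current, config)
    flags = set(current.config.extreme_sessions)
    confirmed = _confirm_boundaries(current)
    n_removed = len(current.config.segment_starts) - len(confirmed)
    if n_removed > 0:
        cfg = _structured_config(
            config, confirmed, tuple(sorted(flags)),
            _warm_start(current, confirmed, n, bool(flags)),
        )
        try:
            refit = fit(series, cfg)
            # the merge must be statistically acceptable: each removed
            # boundary may cost at most its chi2(1) 5% critical value,
            # otherwise the refit left the rich model's optimum basin
            if 2.0 * (current.log_likelihood - refit.log_likelihood) <= 3.84 * n_removed:
                current = refit
            else:
                log.warning(
                    "confirmation refit lost too much likelihood; keeping rich model"
                )
        except ValueError as err:
            log.warning("confirmation refit failed (%s); keeping rich model", err)

    elements = conditional.ConditionalElements(
        extreme_sessions=set(current.config.extreme_sessions),
        segment_starts=tuple(current.config.segment_starts),
    )
    return current, elements
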