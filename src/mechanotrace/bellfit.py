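"""Arrhenius-Bell unbinding kinetics.

Constant-force dynamic force spectroscopy in the single-barrier Bell picture:
a pulling force f lowers the dissociation barrier by f * x_beta, so the rate
is k(f) = (1/tau0) exp(f x_beta / kT). The pipeline is

1. empirical unbound-fraction curve P_u(t) per force,
2. least-squares fit of P_u(t) = 1 - exp(-k t) for the per-force rate,
3. weighted linear regression of ln k on f: slope = x_beta/kT,
   intercept = -ln tau0,
4. barrier estimate dG = ln(tau0 / tauD) in kT over an attempt-time range.

Fitting in log-rate space is a deliberate choice over nonlinear fitting of
the rate law directly: the problem is then convex and deterministic, and the
two parameters map one-to-one onto slope and intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import InvalidParameterError
from .units import thermal_energy


@dataclass
class UnbindingDataset:
    """Event record at one pulling force: times in ns, censored flags, number at risk."""

    force: float  # pN
    times: np.ndarray  # ns
    censored: np.ndarray | None = None
    n_at_risk: int | None = None
    replicate: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(self.times <= 0):
            raise InvalidParameterError("event times must be > 0")
        if self.censored is None:
            self.censored = np.zeros(len(self.times), dtype=bool)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.n_at_risk is None:
            self.n_at_risk = len(self.times)
        if int(np.sum(~self.censored)) > self.n_at_risk:
            raise InvalidParameterError("events exceed the number at risk")

    @property
    def event_times(self) -> np.ndarray:
        return self.times[~self.censored]


@dataclass
class UnboundFractionCurve:
    """Right-continuous empirical fraction of unbound lipids versus time.

    Censored observations contribute to the at-risk denominator only.
    P_u(0) = 0 always; if every observation is an event, P_u(inf) = 1.
    """

    event_times: np.ndarray  # sorted, ns
    n_at_risk: int

    def __post_init__(self):
        self.event_times = np.sort(np.asarray(self.event_times, dtype=float))
        if self.n_at_risk <= 0:
            raise InvalidParameterError("number at risk must be > 0")
        if len(self.event_times) == 0:
            raise InvalidParameterError("need at least one unbinding event")

    @property
    def fractions(self) -> np.ndarray:
        """P_u evaluated just after each event time (right-continuous value)."""
        return np.arange(1, len(self.event_times) + 1) / self.n_at_risk

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.searchsorted(self.event_times, t, side="right") / self.n_at_risk


def unbound_fraction_curve(dataset: UnbindingDataset) -> UnboundFractionCurve:
    """Empirical unbound-fraction step curve for one force."""
    return UnboundFractionCurve(dataset.event_times, dataset.n_at_risk)


@dataclass
class ExpFit:
    """Exponential fit P_u(t) = 1 - exp(-k t)."""

    k: float  # 1/ns
    ci: tuple[float, float] | None  # bootstrap percentile CI on k
    residual_norm: float
    n_events: int

    @property
    def tau(self) -> float:
        return 1.0 / self.k

    @property
    def log_k_se(self) -> float:
        """Standard error of ln k from the CI width (normal approximation)."""
        if self.ci is None or self.ci[0] <= 0:
            return np.nan
        return (np.log(self.ci[1]) - np.log(self.ci[0])) / (2 * 1.959964)


def _fit_exponential_cdf(t: np.ndarray, y: np.ndarray) -> float:
    k0 = 1.0 / max(np.mean(t), 1e-12)
    popt, _ = optimize.curve_fit(
        lambda tt, k: 1.0 - np.exp(-k * tt), t, y, p0=[k0], bounds=(1e-12, np.inf), maxfev=2000
    )
    return float(popt[0])


def fit_unbinding_rate(
    curve: UnboundFractionCurve | tuple[np.ndarray, np.ndarray],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> ExpFit:
    """Least-squares exponential fit of the unbound-fraction curve.

    For a step curve the fit runs on the event times with midpoint plotting
    positions (i - 1/2)/n, a standard low-bias convention for empirical CDFs.
    A dense (t, y) sample pair may be passed instead and is fitted as-is.
    Confidence intervals come from a seeded bootstrap over events.
    """
    if isinstance(curve, UnboundFractionCurve):
        t = curve.event_times
        if len(t) < 5:
            raise InvalidParameterError("need at least 5 events for a rate fit")
        y = (np.arange(1, len(t) + 1) - 0.5) / curve.n_at_risk
        n_at_risk = curve.n_at_risk
        step = True
    else:
        t, y = (np.asarray(a, dtype=float) for a in curve)
        if np.any(np.diff(y) < -1e-12):
            raise InvalidParameterError("unbound-fraction curve must be non-decreasing")
        n_at_risk = None
        step = False
    if np.any(np.diff(t) < 0):
        raise InvalidParameterError("times must be sorted")
    k = _fit_exponential_cdf(t, y)
    resid = float(np.linalg.norm(1.0 - np.exp(-k * t) - y))
    ci = None
    if step and n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        ks = []
        for _ in range(n_bootstrap):
            sample = np.sort(rng.choice(t, size=len(t), replace=True))
            ys = (np.arange(1, len(sample) + 1) - 0.5) / n_at_risk
            try:
                ks.append(_fit_exponential_cdf(sample, ys))
            except RuntimeError:  # pragma: no cover - pathological resample
                continue
        ci = tuple(np.percentile(ks, [2.5, 97.5]))
    return ExpFit(k=k, ci=ci, residual_norm=resid, n_events=len(t))


@dataclass
class BellFit:
    """Fitted Bell parameters: spontaneous dissociation time and dissociation distance."""

    tau0: float  # ns
    xbeta: float  # pm
    covariance: np.ndarray  # 2x2 on (intercept, slope) of ln k vs f
    temperature: float  # K
    forces: np.ndarray  # pN
    rates: np.ndarray  # measured k, 1/ns
    fitted_rates: np.ndarray  # k from the fitted law

    def rate_at(self, force: float) -> float:
        kT = thermal_energy(self.temperature)
        return np.exp(force * self.xbeta * 1e-3 / kT) / self.tau0


def fit_bell_model(
    rates: list[tuple[float, float]] | list[tuple[float, float, float]],
    temperature: float = 310.15,
) -> BellFit:
    """Weighted linear regression of ln k on force.

    ``rates`` is a list of (force pN, k 1/ns) or (force, k, se_ln_k) tuples;
    when standard errors of ln k are given, weights are 1/se^2. Returns
    tau0 = exp(-intercept) in ns and x_beta = slope * kT in pm.
    """
    arr = np.asarray([list(r) for r in rates], dtype=float)
    f = arr[:, 0]
    k = arr[:, 1]
    if len(np.unique(f)) < 3:
        raise InvalidParameterError("need at least 3 distinct forces")
    if np.any(k <= 0):
        raise InvalidParameterError("rates must be > 0")
    if arr.shape[1] > 2 and np.all(np.isfinite(arr[:, 2])) and np.all(arr[:, 2] > 0):
        w = 1.0 / arr[:, 2] ** 2
    else:
        w = np.ones_like(f)
    y = np.log(k)
    X = np.column_stack([np.ones_like(f), f])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    intercept, slope = coef
    resid = y - X @ coef
    dof = max(len(f) - 2, 1)
    s2 = float(np.sum(w * resid**2) / dof)
    cov = s2 * np.linalg.inv((X * w[:, None]).T @ X)
    kT = thermal_energy(temperature)  # pN nm
    tau0 = float(np.exp(-intercept))
    xbeta_pm = float(slope * kT * 1e3)  # slope 1/pN * pN*nm = nm -> pm
    fitted = np.exp(X @ coef)
    return BellFit(
        tau0=tau0, xbeta=xbeta_pm, covariance=cov, temperature=temperature,
        forces=f, rates=k, fitted_rates=fitted,
    )


@dataclass
class BarrierEstimate:
    """Barrier height range dG = ln(tau0/tauD) in kT over an attempt-time interval."""

    dg_low: float  # kT, at the largest attempt time
    dg_high: float  # kT, at the smallest attempt time
    tauD_range: tuple[float, float]  # ps


def barrier_estimate(tau0: float, tauD_range: tuple[float, float] = (1.0, 20.0), temperature: float = 310.15) -> BarrierEstimate:
    """Barrier height from the spontaneous dissociation time and attempt-time range.

    tau0 in ns, tauD in ps. The spread dg_high - dg_low equals
    ln(tauD_max / tauD_min) exactly, independent of tau0.
    """
    tmin, tmax = sorted(float(x) for x in tauD_range)
    if tmin <= 0:
        raise InvalidParameterError("attempt times must be > 0")
    tau0_ps = tau0 * 1e3
    if tau0_ps < tmax:
        raise InvalidParameterError("tau0 below the attempt time: the barrier would be negative")
    return BarrierEstimate(
        dg_low=float(np.log(tau0_ps / tmax)),
        dg_high=float(np.log(tau0_ps / tmin)),
        tauD_range=(tmin, tmax),
    )


def fit_kinetics_pipeline(
    datasets: list[UnbindingDataset],
    temperature: float = 310.15,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> tuple[BellFit, list[ExpFit]]:
    """Full per-force exponential fits followed by the Bell regression."""
    exp_fits = []
    rates = []
    for i, ds in enumerate(datasets):
        fit = fit_unbinding_rate(unbound_fraction_curve(ds), n_bootstrap=n_bootstrap, seed=seed + i)
        exp_fits.append(fit)
        se = fit.log_k_se
        rates.append((ds.force, fit.k, se if np.isfinite(se) else np.nan))
    bell = fit_bell_model(rates, temperature=temperature)
    return bell, exp_fits
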