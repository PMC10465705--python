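"""Scenario-level kinetics: Arrhenius and linear-energy laws vs b_d.

Per-replica rupture events are aggregated into per-scenario means, then
two laws are fitted against the DSB distance b_d:

* the exponential (Arrhenius) law  ln tau_bd = A + k1 * b_d, read as
  ln tau_bd = ln tau0 + (beta ddG) * b_d — tau0 is the blunt-break mean
  rupture time and beta ddG the additive activation increment per intact
  base pair, in units of kB T;
* its base-10 reparameterisation  tau_bd = 10^(w1 + w2 b_d), the form
  used for thermal off-rates in force-spectroscopy work (w2 = k1/ln 10);
* the linear internal-energy law  deltaU(b_d)/kBT = alpha b_d + sigma_c.

Regression is unweighted OLS on the scenario means (a handful of b_d
points per force).  Waiting times of a thermally activated rare event
are exponential, so the per-scenario s.d. is expected on the order of
the mean (CV ~ 1); a one-sample Kolmogorov-Smirnov test against the
exponential law with the estimated mean is provided as a check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .detection import RuptureEvent
from .mechanics import ScenarioConfig


@dataclass
class ScenarioKinetics:
    """Mean rupture kinetics of one (b_d, F_z) scenario."""

    b_d: int
    F_z: float
    n_total: int
    n_censored: int
    tau_mean: Optional[float]      # ns, over uncensored replicas
    tau_sd: Optional[float]        # ns, sample s.d. (n-1)
    delta_U_mean: Optional[float]  # kT
    delta_U_sd: Optional[float]    # kT

    @property
    def has_estimate(self) -> bool:
        return self.tau_mean is not None


def aggregate_scenario(events: Sequence[RuptureEvent],
                       scenario: ScenarioConfig) -> ScenarioKinetics:
    """Mean and sample s.d. of tau and deltaU over uncensored replicas.

    An all-censored scenario yields an explicit no-estimate record
    (means None), never an exception.
    """
    taus = np.array([e.tau for e in events
                     if not e.censored and e.tau is not None])
    dUs = np.array([e.delta_U for e in events
                    if not e.censored and e.delta_U is not None])
    n_cens = sum(e.censored for e in events)

    def _ms(x):
        if x.size == 0:
            return None, None
        sd = float(np.std(x, ddof=1)) if x.size > 1 else None
        return float(np.mean(x)), sd

    tau_mean, tau_sd = _ms(taus)
    dU_mean, dU_sd = _ms(dUs)
    return ScenarioKinetics(b_d=scenario.b_d, F_z=scenario.F_z,
                            n_total=len(events), n_censored=n_cens,
                            tau_mean=tau_mean, tau_sd=tau_sd,
                            delta_U_mean=dU_mean, delta_U_sd=dU_sd)


class ArrheniusRegression(BaseEstimator):
    """OLS of ln(mean rupture time) on the DSB distance.

    ``fit(b_d, tau_mean)`` estimates ln tau = A + k1 * b_d.  Fitted
    attributes: ``A_``, ``k1_`` with standard errors ``se_A_``,
    ``se_k1_``; ``tau0_`` = exp(A); ``beta_ddG_`` (= k1, the activation
    increment in kB T at ``temperature``); base-10 coefficients ``w1_``,
    ``w2_`` with w2 = k1 / ln 10.
    """

    def __init__(self, temperature: float = 310.0):
        self.temperature = temperature

    def fit(self, b_d, tau_mean) -> "ArrheniusRegression":
        x = np.asarray(b_d, dtype=float).ravel()
        y = np.asarray(tau_mean, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("b_d and tau_mean must have equal length")
        if np.unique(x).size < 2:
            raise ValueError("need at least 2 distinct b_d values")
        if np.any(y <= 0):
            raise ValueError("mean rupture times must be positive")
        res = sm.OLS(np.log(y), sm.add_constant(x)).fit()
        self.A_, self.k1_ = map(float, res.params)
        self.se_A_, self.se_k1_ = map(float, res.bse)
        self.tau0_ = math.exp(self.A_)
        self.beta_ddG_ = self.k1_
        self.w1_ = self.A_ / math.log(10.0)
        self.w2_ = self.k1_ / math.log(10.0)
        self.result_ = res
        return self

    def predict(self, b_d) -> np.ndarray:
        """Mean rupture time tau0 * exp(k1 * b_d)."""
        if not hasattr(self, "A_"):
            raise RuntimeError("call fit first")
        return np.exp(self.A_ + self.k1_ * np.asarray(b_d, dtype=float))


class EnergyLinearRegression(BaseEstimator):
    """OLS of the mean rupture energy (kT) on the DSB distance.

    ``fit(b_d, delta_U)`` estimates deltaU/kBT = alpha * b_d + sigma_c;
    fitted attributes ``alpha_``, ``sigma_c_`` and their standard errors.
    """

    def fit(self, b_d, delta_U) -> "EnergyLinearRegression":
        x = np.asarray(b_d, dtype=float).ravel()
        y = np.asarray(delta_U, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("b_d and delta_U must have equal length")
        if np.unique(x).size < 2:
            raise ValueError("need at least 2 distinct b_d values")
        res = sm.OLS(y, sm.add_constant(x)).fit()
        self.sigma_c_, self.alpha_ = map(float, res.params)
        self.se_sigma_c_, self.se_alpha_ = map(float, res.bse)
        self.result_ = res
        return self

    def predict(self, b_d) -> np.ndarray:
        if not hasattr(self, "alpha_"):
            raise RuntimeError("call fit first")
        return self.sigma_c_ + self.alpha_ * np.asarray(b_d, dtype=float)


@dataclass
class ArrheniusFit:
    """Record of the exponential-law fit (natural and base-10 forms)."""

    A: float
    k1: float
    se_A: float
    se_k1: float
    tau0: float
    beta_ddG: float
    w1: float
    w2: float
    temperature: float = 310.0

    def predict(self, b_d) -> np.ndarray:
        return np.exp(self.A + self.k1 * np.asarray(b_d, dtype=float))


@dataclass
class EnergyLinearFit:
    alpha: float
    sigma_c: float
    se_alpha: float
    se_sigma_c: float


def _usable(kinetics: Sequence[ScenarioKinetics]):
    ks = [k for k in kinetics if k.has_estimate]
    if len({k.b_d for k in ks}) < 2:
        raise ValueError("need estimates at >= 2 distinct b_d")
    return ks


def fit_log_linear(kinetics: Sequence[ScenarioKinetics],
                   temperature: float = 310.0) -> ArrheniusFit:
    """Arrhenius fit of per-scenario mean rupture times."""
    ks = _usable(kinetics)
    est = ArrheniusRegression(temperature=temperature)
    est.fit([k.b_d for k in ks], [k.tau_mean for k in ks])
    return ArrheniusFit(A=est.A_, k1=est.k1_, se_A=est.se_A_,
                        se_k1=est.se_k1_, tau0=est.tau0_,
                        beta_ddG=est.beta_ddG_, w1=est.w1_, w2=est.w2_,
                        temperature=temperature)


def fit_power10(kinetics: Sequence[ScenarioKinetics]) -> tuple:
    """(w1, w2) of tau = 10^(w1 + w2 b_d); exact base change of the fit."""
    f = fit_log_linear(kinetics)
    return f.w1, f.w2


def fit_energy_linear(kinetics: Sequence[ScenarioKinetics]
                      ) -> EnergyLinearFit:
    """Linear fit of the mean internal-energy contribution vs b_d."""
    ks = [k for k in kinetics if k.delta_U_mean is not None]
    if len({k.b_d for k in ks}) < 2:
        raise ValueError("need estimates at >= 2 distinct b_d")
    est = EnergyLinearRegression()
    est.fit([k.b_d for k in ks], [k.delta_U_mean for k in ks])
    return EnergyLinearFit(alpha=est.alpha_, sigma_c=est.sigma_c_,
                           se_alpha=est.se_alpha_,
                           se_sigma_c=est.se_sigma_c_)


@dataclass
class ExponentialityTest:
    """One-sample KS test of rupture times against the exponential law.

    The rate is 1/mean with the mean estimated from the same data, so the
    p-value is approximate (conservative under estimation).
    """

    statistic: float
    p_value: float
    n: int
    note: str = field(default="rate estimated from data; "
                              "p-value approximate (conservative)")


def test_exponentiality(taus: Sequence[float]) -> ExponentialityTest:
    x = np.asarray(taus, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 rupture times")
    if np.any(x <= 0):
        raise ValueError("rupture times must be positive")
    res = stats.kstest(x, "expon", args=(0.0, float(np.mean(x))))
    return ExponentialityTest(statistic=float(res.statistic),
                              p_value=float(res.pvalue), n=int(x.size))


def censored_exponential_mean(uncensored: Sequence[float],
                              censored: Sequence[float]) -> float:
    """Exponential MLE of the mean with right-censored observations.

    mean = (sum of all observed times, censored included) / (number of
    uncensored events).  Optional extension; the default aggregation
    excludes censored replicas from the mean.
    """
    u = np.asarray(uncensored, dtype=float)
    c = np.asarray(censored, dtype=float)
    if u.size == 0:
        raise ValueError("need at least one uncensored event")
    return float((u.sum() + c.sum()) / u.size)
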