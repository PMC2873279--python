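"""Rate calibration and conversion of scaled parameters to years and sizes.

The nuclear substitution rate mu is calibrated from a between-species
divergence d and a known split time T as mu = d/(2T); the mtDNA D-loop rate
is a fixed multiple of mu.  Scaled parameters then convert as t = tau/mu (or
t = d/(2 mu)) and Ne = theta/(4 mu g) with generation time g in years.
Uncertainty on d propagates linearly.

The identity-by-descent probability for two haplotypes of length L sampled
from species that split tau ago, with ancestral scaled diversity theta_anc,
is P_C = exp(-2 tau L)/(1 + theta_anc L): no mutation on either branch since
the split, averaged over the exponential ancestral coalescent contribution.
"""
from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class RateCalibration:
    mu: float  # nuclear substitutions/site/year
    mu_err: float
    calibration_d: float
    calibration_T: float  # years
    mt_ratio: float = 1.7

    @property
    def mu_mt(self) -> float:
        return self.mt_ratio * self.mu

    @property
    def mu_mt_err(self) -> float:
        return self.mt_ratio * self.mu_err


@dataclass(frozen=True)
class TimeEstimate:
    years: float
    years_err: float
    mode: str  # "tau" (t = tau/mu) or "d" (t = d/(2 mu))


@dataclass(frozen=True)
class EffectiveSize:
    ne: float
    ne_err: float
    generation_time: float


@dataclass(frozen=True)
class IdentityProbability:
    p_c: float
    length: int
    tau: float
    theta_anc: float


def calibrate_rate(
    d: float, T: float, d_err: float = 0.0, mt_ratio: float = 1.7
) -> RateCalibration:
    """mu = d/(2T) with linear error propagation from +/- d_err."""
    if not 0 < d < 1:
        raise ValueError("calibration divergence d must be in (0, 1)")
    if T <= 0:
        raise ValueError("calibration time T must be positive")
    if d_err < 0:
        raise ValueError("d_err must be >= 0")
    return RateCalibration(d / (2 * T), d_err / (2 * T), d, T, mt_ratio)


def divergence_time(
    value: float,
    calibration: RateCalibration,
    mode: str = "tau",
    value_err: float = 0.0,
) -> TimeEstimate:
    """t = tau/mu (mode "tau") or t = d/(2 mu) (mode "d")."""
    if value < 0 or value_err < 0:
        raise ValueError("divergence and its error must be >= 0")
    if mode == "tau":
        return TimeEstimate(value / calibration.mu, value_err / calibration.mu, mode)
    if mode == "d":
        return TimeEstimate(
            value / (2 * calibration.mu), value_err / (2 * calibration.mu), mode
        )
    raise ValueError("mode must be 'tau' or 'd'")


def effective_size(
    theta: float,
    calibration: RateCalibration,
    g: float = 1.0,
    theta_err: float = 0.0,
) -> EffectiveSize:
    """Ne = theta/(4 mu g); the default generation time is one year."""
    if theta < 0 or theta_err < 0:
        raise ValueError("theta and its error must be >= 0")
    if g <= 0:
        raise ValueError("generation time must be positive")
    denom = 4 * calibration.mu * g
    return EffectiveSize(theta / denom, theta_err / denom, g)


def prob_identical_haplotypes(
    L: int, tau: float, theta_anc: float
) -> IdentityProbability:
    """P_C = exp(-2 tau L) / (1 + theta_anc * L).

    Zero mutations on both branches of combined expected length 2*tau*L plus
    an Exp(theta_anc) ancestral coalescent contribution whose moment
    generating function gives the 1/(1 + theta_anc*L) factor.
    """
    if L < 1 or int(L) != L:
        raise ValueError("L must be a positive integer")
    if tau < 0 or theta_anc < 0:
        raise ValueError("tau and theta_anc must be >= 0")
    return IdentityProbability(
        math.exp(-2 * tau * L) / (1 + theta_anc * L), int(L), tau, theta_anc
    )


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (report-formatting helper)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
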