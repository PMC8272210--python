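"""Dipolar relaxation rates for isotropic rotational diffusion (BPP model).

The model relates the longitudinal (R1 = 1/T1) and transverse
(R2 = 1/T2) relaxation rates of a like-spin proton pair to a single
mean rotational correlation time tau_c at a given Larmor frequency:

    R1 = (6/20) K [ tau_c/(1 + (w tau_c)^2) + 4 tau_c/(1 + (2 w tau_c)^2) ]
    R2 = (3/20) K [ 3 tau_c + 5 tau_c/(1 + (w tau_c)^2)
                    + 2 tau_c/(1 + (2 w tau_c)^2) ]

with w = 2 pi f the angular Larmor frequency and K the lumped dipolar
prefactor (mu0/4pi)^2 gamma^4 hbar^2 / r0^6.

Forward evaluation (`r1_bpp`, `r2_bpp`, `ratio_r2_r1`) and inversion
(`tau_c_from_ratio`, `tau_c_from_r1`) are provided.  The ratio R2/R1 is
independent of K, so correlation times can be extracted without knowing
the internuclear distance; this is the default route used by the
pipeline.  Inverting R1 alone needs K and, because R1 is non-monotonic
in tau_c (maximum near w tau_c ~ 0.62), an explicit branch choice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from scipy.optimize import bisect, brentq

from . import constants

__all__ = [
    "BPPContext",
    "CorrelationTime",
    "MissingPrefactorError",
    "InfeasibleRateError",
    "BracketingError",
    "NoiseInconsistentRatioWarning",
    "r1_bpp",
    "r2_bpp",
    "ratio_r2_r1",
    "tau_c_from_ratio",
    "tau_c_from_r1",
    "r1_argmax_omega_tau",
]


class MissingPrefactorError(ValueError):
    """The dipolar prefactor K is required but not configured."""


class InfeasibleRateError(ValueError):
    """A requested R1 exceeds the maximum the model can produce."""


class BracketingError(ValueError):
    """A root-finding bracket does not contain a sign change."""


class NoiseInconsistentRatioWarning(UserWarning):
    """A measured R2/R1 ratio fell marginally below the physical floor of 1."""


@dataclass(frozen=True)
class BPPContext:
    """Spectrometer frequency and dipolar-coupling bookkeeping.

    Parameters
    ----------
    larmor_frequency_hz : float
        Spectrometer (Larmor) frequency f in Hz.  Defaults to 15 MHz,
        the low-field regime this package targets.
    dipolar_prefactor_K : float, optional
        Lumped dipolar constant K in s^-2.  Needed only for absolute
        rate evaluation and for inverting R1 alone; the R2/R1 ratio
        route works without it.
    r0 : float, optional
        Internuclear proton-proton distance in metres.  If given and
        ``dipolar_prefactor_K`` is not, K is computed from it; if both
        are given they must agree to relative 1e-9.
    """

    larmor_frequency_hz: float = 15e6
    dipolar_prefactor_K: float | None = None
    r0: float | None = None

    def __post_init__(self) -> None:
        if self.larmor_frequency_hz <= 0:
            raise ValueError(
                f"larmor_frequency_hz must be positive, got {self.larmor_frequency_hz}"
            )
        if self.r0 is not None:
            k_from_r0 = constants.dipolar_prefactor(self.r0)
            if self.dipolar_prefactor_K is None:
                object.__setattr__(self, "dipolar_prefactor_K", k_from_r0)
            elif not math.isclose(
                self.dipolar_prefactor_K, k_from_r0, rel_tol=1e-9
            ):
                raise ValueError(
                    "dipolar_prefactor_K inconsistent with r0: "
                    f"stored {self.dipolar_prefactor_K:.6e}, recomputed {k_from_r0:.6e}"
                )
        if self.dipolar_prefactor_K is not None and self.dipolar_prefactor_K <= 0:
            raise ValueError("dipolar_prefactor_K must be positive")

    @property
    def angular_frequency(self) -> float:
        """Angular Larmor frequency w = 2 pi f (rad/s)."""
        return 2.0 * math.pi * self.larmor_frequency_hz

    @classmethod
    def from_r0(
        cls, r0: float = constants.DEFAULT_PROTON_DISTANCE, larmor_frequency_hz: float = 15e6
    ) -> "BPPContext":
        """Build a context with K computed from an internuclear distance."""
        return cls(larmor_frequency_hz=larmor_frequency_hz, r0=r0)

    def _require_prefactor(self) -> float:
        if self.dipolar_prefactor_K is None:
            raise MissingPrefactorError(
                "dipolar_prefactor_K is not set; either construct the context "
                "with r0 (BPPContext.from_r0) or use the K-free R2/R1 ratio "
                "route (ratio_r2_r1 / tau_c_from_ratio)."
            )
        return self.dipolar_prefactor_K


@dataclass(frozen=True)
class CorrelationTime:
    """A mean rotational correlation time, optionally tagged with its temperature."""

    tau_c: float
    temperature_k: float | None = None
    clamped: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.tau_c > 0:
            raise ValueError(f"tau_c must be positive, got {self.tau_c}")
        if self.temperature_k is not None and not self.temperature_k > 0:
            raise ValueError(
                f"temperature_k must be positive, got {self.temperature_k}"
            )


def _check_tau(tau_c: float) -> None:
    if not tau_c > 0:
        raise ValueError(f"tau_c must be positive, got {tau_c}")


def r1_bpp(tau_c: float, ctx: BPPContext) -> float:
    """Longitudinal relaxation rate R1 (s^-1) at correlation time ``tau_c``."""
    _check_tau(tau_c)
    k = ctx._require_prefactor()
    x = ctx.angular_frequency * tau_c
    return (6.0 / 20.0) * k * (tau_c / (1.0 + x * x) + 4.0 * tau_c / (1.0 + 4.0 * x * x))


def r2_bpp(tau_c: float, ctx: BPPContext) -> float:
    """Transverse relaxation rate R2 (s^-1) at correlation time ``tau_c``.

    Monotonically increasing in tau_c (the secular 3*tau_c term never
    disperses), hence R2 always >= R1.
    """
    _check_tau(tau_c)
    k = ctx._require_prefactor()
    x = ctx.angular_frequency * tau_c
    return (3.0 / 20.0) * k * (
        3.0 * tau_c + 5.0 * tau_c / (1.0 + x * x) + 2.0 * tau_c / (1.0 + 4.0 * x * x)
    )


def ratio_r2_r1(tau_c: float, ctx: BPPContext) -> float:
    """The K-free ratio R2/R1 at correlation time ``tau_c``.

    The dipolar prefactor cancels, so only the angular frequency enters.
    The ratio is >= 1, equals 1 in the extreme-narrowing limit
    (w tau_c << 1) and increases strictly with tau_c.
    """
    _check_tau(tau_c)
    x = ctx.angular_frequency * tau_c
    j1 = 1.0 / (1.0 + x * x)
    j2 = 1.0 / (1.0 + 4.0 * x * x)
    return 0.5 * (3.0 + 5.0 * j1 + 2.0 * j2) / (j1 + 4.0 * j2)


#: Floor below which a measured R2/R1 ratio is considered pathological
#: rather than mere noise; see `tau_c_from_ratio`.
RATIO_ABORT_FLOOR = 0.9

#: Value marginally-sub-unity ratios are clamped to.
RATIO_CLAMP_VALUE = 1.0 + 1e-9

_DEFAULT_RATIO_BRACKET = (1e-14, 1e-4)


def clamp_ratio(ratio: float) -> tuple[float, bool]:
    """Apply the sub-unity ratio policy.

    Physically R2/R1 >= 1; measurement noise at high temperature can push
    an observed ratio marginally below 1.  Ratios in [0.9, 1) are clamped
    to 1 + 1e-9 and flagged; ratios below 0.9 indicate something worse
    than noise and raise.

    Returns
    -------
    (ratio, clamped) : tuple of float and bool
    """
    if ratio < RATIO_ABORT_FLOOR:
        raise ValueError(
            f"R2/R1 ratio {ratio:.4f} is below {RATIO_ABORT_FLOOR}; this is "
            "inconsistent with dipolar relaxation and is not treated as noise."
        )
    if ratio < 1.0:
        return RATIO_CLAMP_VALUE, True
    return ratio, False


def tau_c_from_ratio(
    ratio: float,
    ctx: BPPContext,
    bracket: tuple[float, float] = _DEFAULT_RATIO_BRACKET,
) -> CorrelationTime:
    """Invert the R2/R1 ratio to a correlation time.

    The ratio is strictly increasing in tau_c, so the root is unique; it
    is located by bisection on ln(tau_c) to a relative tolerance well
    below 1e-10.  Ratios marginally below 1 are clamped (see
    `clamp_ratio`) and the returned `CorrelationTime` carries
    ``clamped=True``.

    Parameters
    ----------
    ratio : float
        Observed R2/R1 (equivalently T1/T2) value.
    ctx : BPPContext
        Supplies the angular frequency; the dipolar prefactor is not used.
    bracket : (float, float)
        tau_c interval (s) that must bracket the root.
    """
    ratio, clamped = clamp_ratio(ratio)
    if clamped:
        warnings.warn(
            "R2/R1 ratio marginally below 1 clamped to the extreme-narrowing "
            "floor; the correlation time is an upper-limit estimate.",
            NoiseInconsistentRatioWarning,
            stacklevel=2,
        )
    lo, hi = bracket
    if not (0 < lo < hi):
        raise ValueError(f"invalid bracket {bracket}")

    def objective(log_tau: float) -> float:
        return ratio_r2_r1(math.exp(log_tau), ctx) - ratio

    f_lo, f_hi = objective(math.log(lo)), objective(math.log(hi))
    if f_lo * f_hi > 0:
        raise BracketingError(
            f"bracket {bracket} does not enclose ratio {ratio:.6g}: "
            f"ratio range is [{ratio_r2_r1(lo, ctx):.6g}, {ratio_r2_r1(hi, ctx):.6g}]"
        )
    log_tau = bisect(objective, math.log(lo), math.log(hi), xtol=1e-12)
    return CorrelationTime(tau_c=math.exp(log_tau), clamped=clamped)


def r1_argmax_omega_tau() -> float:
    """The value of w*tau_c at which R1 attains its maximum (~0.616).

    Found as the root of d/dx [x/(1+x^2) + 4x/(1+4x^2)], which depends
    on neither K nor the frequency.
    """

    def slope(x: float) -> float:
        return (1.0 - x * x) / (1.0 + x * x) ** 2 + 4.0 * (1.0 - 4.0 * x * x) / (
            1.0 + 4.0 * x * x
        ) ** 2

    return brentq(slope, 0.1, 1.0, xtol=1e-15)


_X_R1_MAX = r1_argmax_omega_tau()


def tau_c_from_r1(r1: float, ctx: BPPContext, branch: str) -> CorrelationTime:
    """Invert R1 to a correlation time on an explicitly chosen branch.

    R1(tau_c) rises to a maximum at w tau_c ~ 0.62 and falls again, so a
    feasible rate corresponds to two correlation times.  ``branch``
    selects which: ``"fast"`` for the motional-narrowing side
    (w tau_c < 0.62), ``"slow"`` for the slow-motion side.

    Raises
    ------
    InfeasibleRateError
        If ``r1`` exceeds the attainable maximum at this frequency and K.
    MissingPrefactorError
        If the context carries no dipolar prefactor.
    """
    if branch not in ("fast", "slow"):
        raise ValueError(
            f"branch must be 'fast' or 'slow', got {branch!r}; there is no "
            "default because R1 is double-valued in tau_c."
        )
    if not r1 > 0:
        raise ValueError(f"r1 must be positive, got {r1}")
    ctx._require_prefactor()
    omega = ctx.angular_frequency
    tau_max = _X_R1_MAX / omega
    r1_max = r1_bpp(tau_max, ctx)
    if r1 > r1_max * (1.0 + 1e-12):
        raise InfeasibleRateError(
            f"r1 = {r1:.6g} s^-1 exceeds the BPP maximum {r1_max:.6g} s^-1 "
            f"at f = {ctx.larmor_frequency_hz:.6g} Hz with the configured K."
        )
    r1 = min(r1, r1_max)
    if branch == "fast":
        lo, hi = 1e-16, tau_max
    else:
        lo, hi = tau_max, 1e-2
    # At the bracket edges R1 can still be above the target on the
    # chosen side; widen checks with explicit errors.
    f_lo = r1_bpp(lo, ctx) - r1
    f_hi = r1_bpp(hi, ctx) - r1
    if f_lo * f_hi > 0:
        raise BracketingError(
            f"r1 = {r1:.6g} s^-1 has no root on the {branch} branch within "
            f"tau_c in [{lo:.1e}, {hi:.1e}] s"
        )
    # solve on ln(tau) so the tolerance is relative across 14 decades
    log_tau = brentq(
        lambda u: r1_bpp(math.exp(u), ctx) - r1,
        math.log(lo), math.log(hi), xtol=1e-13,
    )
    return CorrelationTime(tau_c=math.exp(log_tau))
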