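"""Mono/multiexponential fitting of inversion-recovery and CPMG traces.

Two model classes follow the Model/Results pattern: construct a model
from a `SignalTrace`, call `.fit()`, get a `RelaxationFitResults`
carrying the extracted components, their uncertainties and diagnostics.

Inversion recovery (180-tau-90) samples longitudinal recovery,

    M(tau) = M0 [ 1 - 2 alpha sum_i p_i exp(-tau / T1_i) ],

with inversion efficiency alpha = 1 for an ideal 180 pulse (an opt-in
fit of alpha in [0.8, 1] is available).  A CPMG echo train samples
transverse decay,

    A(t) = A0 sum_i p_i exp(-t / T2_i).

Both are fitted by variable projection: a deterministic log-spaced grid
search over time-constant combinations with a non-negative linear solve
for the amplitudes, followed by full nonlinear refinement
(`scipy.optimize.least_squares`).  Multiexponential fitting is
ill-conditioned; the deterministic initialisation makes results
reproducible.  Fractions p_i are amplitude shares and always sum to 1.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls

__all__ = [
    "SignalTrace",
    "RelaxationComponent",
    "RelaxationFitResults",
    "InversionRecoveryModel",
    "CPMGModel",
    "fit_inversion_recovery",
    "fit_cpmg",
    "select_n_components",
    "score_components",
    "observed_rate",
    "assign_phases",
    "NonDecayingTraceError",
    "PhaseAssignmentError",
    "ComponentCollapseWarning",
]

#: Adjacent time constants closer than this ratio are considered
#: unresolved: the fit has effectively collapsed to fewer components.
COLLAPSE_RATIO = 1.2


class NonDecayingTraceError(ValueError):
    """A CPMG trace shows no overall decay."""


class PhaseAssignmentError(ValueError):
    """Oil/water assignment is only defined for two-component fits."""


class ComponentCollapseWarning(UserWarning):
    """Two fitted time constants are too close to be distinct."""


@dataclass(frozen=True)
class SignalTrace:
    """One recorded relaxation trace.

    Parameters
    ----------
    times : array
        Inversion-recovery delays or CPMG echo times (s), strictly
        increasing, at least 8 points.
    amplitudes : array
        Signal amplitude at each time (arbitrary units).
    kind : {"inversion_recovery", "cpmg"}
    n_accumulations : int
        Number of averaged acquisitions (>= 1).
    noise_sigma : float, optional
        Known amplitude noise s.d.; when present, fits use
        inverse-variance weighting.
    """

    times: np.ndarray
    amplitudes: np.ndarray
    kind: str
    n_accumulations: int = 1
    noise_sigma: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        amplitudes = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "amplitudes", amplitudes)
        if self.kind not in ("inversion_recovery", "cpmg"):
            raise ValueError(f"unknown trace kind {self.kind!r}")
        if times.ndim != 1 or times.shape != amplitudes.shape:
            raise ValueError("times and amplitudes must be 1-D arrays of equal length")
        if len(times) < 8:
            raise ValueError(
                f"a trace needs at least 8 points, got {len(times)}"
            )
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.n_accumulations < 1:
            raise ValueError("n_accumulations must be >= 1")
        if self.noise_sigma is not None and self.noise_sigma <= 0:
            raise ValueError("noise_sigma, when given, must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "amplitude": self.amplitudes})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: str, **kwargs) -> "SignalTrace":
        df = pd.read_csv(path)
        missing = {"time_s", "amplitude"} - set(df.columns)
        if missing:
            raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
        return cls(
            times=df["time_s"].to_numpy(),
            amplitudes=df["amplitude"].to_numpy(),
            kind=kind,
            **kwargs,
        )


@dataclass(frozen=True)
class RelaxationComponent:
    """One exponential pool: a time constant, its proton fraction and labels."""

    time_constant: float
    fraction: float
    which: str  # "T1" or "T2"
    phase: str = "unassigned"  # "oil", "water" or "unassigned"

    def __post_init__(self) -> None:
        if not self.time_constant > 0:
            raise ValueError(f"time_constant must be positive, got {self.time_constant}")
        if not 0.0 <= self.fraction <= 1.0 + 1e-12:
            raise ValueError(f"fraction must lie in [0, 1], got {self.fraction}")
        if self.which not in ("T1", "T2"):
            raise ValueError(f"which must be 'T1' or 'T2', got {self.which!r}")
        if self.phase not in ("oil", "water", "unassigned"):
            raise ValueError(f"unknown phase label {self.phase!r}")


@dataclass
class RelaxationFitResults:
    """Results of a mono/multiexponential relaxation fit.

    Attributes
    ----------
    components : list of RelaxationComponent
        Sorted ascending by time constant; fractions sum to 1.
    m0 : float
        Equilibrium amplitude (sum of component amplitudes).
    alpha : float
        Inversion efficiency (1.0 for CPMG fits).
    residual_rms : float
        Root-mean-square of unweighted residuals, amplitude units.
    converged : bool
        Whether the nonlinear refinement reported success.
    bse : dict
        Approximate standard errors (from the Jacobian at the optimum)
        keyed like ``T_1``, ``p_1``, ...; empty if not computable.
    model_scores : dict or None
        Per-candidate information-criterion values when the fit came
        out of automatic model selection.
    """

    components: list[RelaxationComponent]
    m0: float
    alpha: float
    residual_rms: float
    converged: bool
    kind: str
    n_obs: int
    rss: float
    bse: dict = field(default_factory=dict)
    model_scores: dict | None = None

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def time_constants(self) -> np.ndarray:
        return np.array([c.time_constant for c in self.components])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([c.fraction for c in self.components])

    @property
    def aicc(self) -> float:
        """Small-sample corrected Akaike criterion of this fit."""
        k = 2 * self.n_components + (1 if self.alpha not in (1.0,) else 0)
        return _aicc(self.rss, self.n_obs, k, scale=abs(self.m0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, self.n_components + 1),
                "which": [c.which for c in self.components],
                "time_constant_s": self.time_constants,
                "fraction": self.fractions,
                "phase": [c.phase for c in self.components],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def predict(self, times: np.ndarray) -> np.ndarray:
        """Model curve at the given times."""
        times = np.asarray(times, dtype=float)
        decays = np.array(
            [f * np.exp(-times / t) for f, t in zip(self.fractions, self.time_constants)]
        ).sum(axis=0)
        if self.kind == "inversion_recovery":
            return self.m0 * (1.0 - 2.0 * self.alpha * decays)
        return self.m0 * decays

    def summary(self) -> str:
        which = self.components[0].which if self.components else "?"
        lines = [
            f"{'Inversion recovery' if self.kind == 'inversion_recovery' else 'CPMG'} "
            f"fit: {self.n_components} component(s), n = {self.n_obs}",
            f"  M0 = {self.m0:.6g}   alpha = {self.alpha:.4g}   "
            f"residual rms = {self.residual_rms:.3g}   converged = {self.converged}",
            f"  {'comp':>4} {which + ' (s)':>12} {'fraction':>10} {'phase':>11}",
        ]
        for i, c in enumerate(self.components, 1):
            se = self.bse.get(f"T_{i}")
            se_txt = f" +/- {se:.2g}" if se is not None else ""
            lines.append(
                f"  {i:>4} {c.time_constant:>12.5g}{se_txt} {c.fraction:>10.4f} {c.phase:>11}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data (from the fitted trace times) vs fitted curve; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.set_xlabel("time (s)")
        ax.set_ylabel("amplitude")
        return ax


def _aicc(rss: float, n: int, k: int, scale: float = 1.0) -> float:
    """Small-sample corrected AIC from a residual sum of squares.

    The RSS is floored near machine precision of the signal scale so
    that nested exact fits score as ties (broken toward fewer
    parameters by the caller) instead of comparing rounding noise.
    """
    floor = n * (1e-12 * max(scale, 1e-300)) ** 2
    rss = max(rss, floor)
    if n - k - 1 <= 0:
        return math.inf
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


class _MultiExponentialModel:
    """Shared variable-projection machinery; subclasses fix the basis."""

    kind = ""

    def __init__(self, trace: SignalTrace, n_components: int = 2):
        if trace.kind != self.kind:
            raise ValueError(
                f"{type(self).__name__} expects a {self.kind!r} trace, got {trace.kind!r}"
            )
        if not 1 <= n_components <= 3:
            raise ValueError(f"n_components must be in 1..3, got {n_components}")
        if len(trace.times) < 4 * n_components:
            raise ValueError(
                f"need at least {4 * n_components} points for {n_components} "
                f"component(s), got {len(trace.times)}"
            )
        self.trace = trace
        self.n_components = n_components
        self._which = "T1" if self.kind == "inversion_recovery" else "T2"

    # -- basis ---------------------------------------------------------
    def _design(self, taus: np.ndarray, alpha: float) -> np.ndarray:
        raise NotImplementedError

    # -- fitting -------------------------------------------------------
    def _weights(self) -> np.ndarray:
        t = self.trace
        if t.noise_sigma is not None:
            return np.full_like(t.amplitudes, 1.0 / t.noise_sigma)
        return np.ones_like(t.amplitudes)

    def _tau_bounds(self) -> tuple[float, float]:
        times = self.trace.times
        lo = times[1] / 10.0 if times[1] > 0 else times[-1] * 1e-4
        return lo, 10.0 * times[-1]

    def _grid_init(self, alpha: float) -> tuple[np.ndarray, np.ndarray]:
        """Best time-constant combination on a log grid, amplitudes by NNLS."""
        m = self.n_components
        lo, hi = self._tau_bounds()
        n_grid = 25 if m <= 2 else 14
        grid = np.geomspace(lo, hi, n_grid)
        w = self._weights()
        y = self.trace.amplitudes * w
        best_rss, best = np.inf, None
        for combo in itertools.combinations(range(n_grid), m):
            taus = grid[list(combo)]
            phi = self._design(taus, alpha) * w[:, None]
            amps, rnorm = nnls(phi, y)
            if rnorm**2 < best_rss:
                best_rss, best = rnorm**2, (taus, amps)
        taus, amps = best
        amps = np.maximum(amps, 1e-12 * max(np.abs(amps).max(), 1.0))
        return taus, amps

    def fit(self, fit_alpha: bool = False) -> RelaxationFitResults:
        """Fit the model and return a results object."""
        m = self.n_components
        alpha0 = 1.0
        taus0, amps0 = self._grid_init(alpha0)
        lo, hi = self._tau_bounds()
        w = self._weights()
        y = self.trace.amplitudes

        def unpack(theta):
            taus = np.exp(theta[:m])
            amps = theta[m : 2 * m]
            alpha = theta[2 * m] if fit_alpha else 1.0
            return taus, amps, alpha

        def residuals(theta):
            taus, amps, alpha = unpack(theta)
            model = self._design(taus, alpha) @ amps
            return (model - y) * w

        theta0 = np.concatenate([np.log(taus0), amps0, [1.0] if fit_alpha else []])
        scale = max(np.abs(y).max(), 1e-300)
        lower = np.concatenate(
            [np.full(m, math.log(lo)), np.zeros(m), [0.8] if fit_alpha else []]
        )
        upper = np.concatenate(
            [np.full(m, math.log(hi)), np.full(m, 10 * scale), [1.0] if fit_alpha else []]
        )
        res = least_squares(
            residuals, theta0, bounds=(lower, upper), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400 * (m + 1),
        )
        taus, amps, alpha = unpack(res.x)
        order = np.argsort(taus)
        taus, amps = taus[order], amps[order]
        total = amps.sum()
        if total <= 0:
            raise RuntimeError("fit collapsed to zero amplitude")
        fractions = amps / total
        # exact renormalisation so fractions sum to 1 to machine precision
        fractions = fractions / fractions.sum()

        model_curve = self._design(taus, alpha) @ amps
        resid = model_curve - y
        rss = float(np.sum((resid * w) ** 2))
        residual_rms = float(np.sqrt(np.mean(resid**2)))

        bse = self._standard_errors(res, m, order, total, fit_alpha)

        components = [
            RelaxationComponent(time_constant=t, fraction=f, which=self._which)
            for t, f in zip(taus, fractions)
        ]
        if m > 1:
            ratios = taus[1:] / taus[:-1]
            if np.any(ratios < COLLAPSE_RATIO):
                warnings.warn(
                    f"adjacent time constants within a factor of {COLLAPSE_RATIO} "
                    "are effectively unresolved; consider fewer components.",
                    ComponentCollapseWarning,
                    stacklevel=2,
                )
        return RelaxationFitResults(
            components=components,
            m0=float(total),
            alpha=float(alpha),
            residual_rms=residual_rms,
            converged=bool(res.success),
            kind=self.kind,
            n_obs=len(y),
            rss=rss,
            bse=bse,
        )

    def _standard_errors(self, res, m, order, total, fit_alpha) -> dict:
        n = len(self.trace.times)
        k = len(res.x)
        dof = n - k
        if dof <= 0 or not np.all(np.isfinite(res.jac)):
            return {}
        try:
            jtj = res.jac.T @ res.jac
            cov = np.linalg.pinv(jtj) * (2.0 * res.cost / dof)
        except np.linalg.LinAlgError:
            return {}
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        taus = np.exp(res.x[:m])[order]
        se_logtau = se[:m][order]
        se_amp = se[m : 2 * m][order]
        out = {}
        for i in range(m):
            out[f"T_{i + 1}"] = taus[i] * se_logtau[i]  # delta method on log scale
            out[f"p_{i + 1}"] = se_amp[i] / total
        if fit_alpha:
            out["alpha"] = se[2 * m]
        return out


class InversionRecoveryModel(_MultiExponentialModel):
    """Multiexponential longitudinal-recovery model for a 180-tau-90 trace."""

    kind = "inversion_recovery"

    def __init__(self, trace: SignalTrace, n_components: int = 2, fit_alpha: bool = False):
        super().__init__(trace, n_components)
        self.fit_alpha = fit_alpha

    def _design(self, taus: np.ndarray, alpha: float) -> np.ndarray:
        t = self.trace.times[:, None]
        return 1.0 - 2.0 * alpha * np.exp(-t / taus[None, :])

    def fit(self, fit_alpha: bool | None = None) -> RelaxationFitResults:
        return super().fit(self.fit_alpha if fit_alpha is None else fit_alpha)


class CPMGModel(_MultiExponentialModel):
    """Multiexponential transverse-decay model for a CPMG echo train."""

    kind = "cpmg"

    def __init__(self, trace: SignalTrace, n_components: int = 2):
        super().__init__(trace, n_components)
        amps = trace.amplitudes
        head = amps[: max(3, len(amps) // 4)].mean()
        tail = amps[-max(3, len(amps) // 4):].mean()
        if not head > 0 or tail >= 0.9 * head:
            raise NonDecayingTraceError(
                "CPMG amplitudes show no overall decay; nothing to fit."
            )

    def _design(self, taus: np.ndarray, alpha: float) -> np.ndarray:
        t = self.trace.times[:, None]
        return np.exp(-t / taus[None, :])


def fit_inversion_recovery(
    trace: SignalTrace, n_components: int = 2, fit_alpha: bool = False
) -> RelaxationFitResults:
    """Fit an inversion-recovery trace with ``n_components`` pools."""
    return InversionRecoveryModel(trace, n_components, fit_alpha=fit_alpha).fit()


def fit_cpmg(trace: SignalTrace, n_components: int = 2) -> RelaxationFitResults:
    """Fit a CPMG echo train with ``n_components`` pools."""
    return CPMGModel(trace, n_components).fit()


def _model_for(trace: SignalTrace, n_components: int) -> _MultiExponentialModel:
    if trace.kind == "inversion_recovery":
        return InversionRecoveryModel(trace, n_components)
    return CPMGModel(trace, n_components)


def _is_degenerate(result: RelaxationFitResults) -> bool:
    taus = result.time_constants
    if len(taus) > 1 and np.any(taus[1:] / taus[:-1] < COLLAPSE_RATIO):
        return True
    if len(taus) > 1 and np.any(result.fractions < 1e-3):
        return True
    return False


def score_components(
    trace: SignalTrace, max_components: int = 2
) -> dict[int, RelaxationFitResults]:
    """Fit 1..max_components models; returns the results keyed by count."""
    if max_components not in (2, 3):
        raise ValueError(f"max_components must be 2 or 3, got {max_components}")
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ComponentCollapseWarning)
        for m in range(1, max_components + 1):
            out[m] = _model_for(trace, m).fit()
    return out


def select_n_components(trace: SignalTrace, max_components: int = 2) -> int:
    """Choose the number of exponential components for a trace.

    Candidate counts 1..max_components are fitted and compared by
    small-sample AICc.  A larger model is accepted only when it both
    improves the criterion and resolves genuinely distinct components
    (adjacent time-constant ratio >= 1.2, no vanishing fraction); ties
    and degenerate improvements break toward fewer components.
    """
    results = score_components(trace, max_components)
    scores = {m: r.aicc for m, r in results.items()}
    best = 1
    for m in range(2, max_components + 1):
        if scores[m] < scores[best] - 1e-9 and not _is_degenerate(results[m]):
            best = m
    return best


def observed_rate(components: list[RelaxationComponent]) -> float:
    """Fraction-weighted mean relaxation rate sum_i p_i / T_i (s^-1).

    This is the fast-exchange observable: when pools exchange quickly the
    measured single rate is the weighted average of pool rates.
    """
    if not components:
        raise ValueError("need at least one component")
    kinds = {c.which for c in components}
    if len(kinds) > 1:
        raise TypeError(
            f"cannot average T1 and T2 components together, got {sorted(kinds)}"
        )
    total = sum(c.fraction for c in components)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {total}")
    return sum(c.fraction / c.time_constant for c in components)


def assign_phases(
    fit_t1: RelaxationFitResults, fit_t2: RelaxationFitResults
) -> tuple[list[RelaxationComponent], list[RelaxationComponent]]:
    """Label two-component T1 and T2 fits as oil (short) and water (long).

    In an oil-in-water emulsion the short components of both relaxation
    times are ascribed to the oil phase and the long components to the
    water phase.  Returns ``(oil, water)``, each a list holding one T1
    and one T2 component with ``phase`` set.
    """
    for name, fit in (("T1", fit_t1), ("T2", fit_t2)):
        if fit.n_components != 2:
            raise PhaseAssignmentError(
                f"{name} fit has {fit.n_components} component(s); oil/water "
                "assignment needs exactly 2 — map components explicitly instead."
            )
        taus = fit.time_constants
        if abs(taus[1] - taus[0]) <= 1e-9 * max(taus):
            raise PhaseAssignmentError(
                f"{name} components are tied ({taus[0]:.6g} s); cannot assign "
                "phases without an arbitrary choice."
            )
    oil = [
        replace(fit_t1.components[0], phase="oil"),
        replace(fit_t2.components[0], phase="oil"),
    ]
    water = [
        replace(fit_t1.components[1], phase="water"),
        replace(fit_t2.components[1], phase="water"),
    ]
    return oil, water
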