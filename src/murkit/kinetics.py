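"""Mur-ligase enzymology: coupled-assay rates, kinetic fits, pH profiles.

The assay is the classic pyruvate-kinase / lactate-dehydrogenase coupled
system: each mol of ADP released by the ligase consumes one mol of NADH,
observed as a fall in A340.  Initial rates are therefore

    v0 = (-dA340/dt) / (eps * l) / [E]      (mol ADP * mol ligase^-1 * s^-1)

with eps the NADH extinction coefficient (default 6220 M^-1 cm^-1) and l the
path length.  Because v0 is already per mol of enzyme, kcat equals the fitted
Vmax and kcat/KM is the apparent catalytic efficiency.

Rate-vs-substrate data are fitted by nonlinear least squares to

    Michaelis-Menten       v = Vmax * S / (KM + S)
    substrate inhibition   v = Vmax * S / (KM + S * (1 + S / Ki))

and pH profiles to the diprotic bell

    v(pH) = vopt / (1 + 10**(pKa1 - pH) + 10**(pH - pKa2))

whose optimum is the midpoint (pKa1 + pKa2) / 2.  The fitters are
scikit-learn style estimators (``fit``/``predict``/``score``, fitted
attributes with trailing underscores) so they compose with sklearn tooling;
module-level ``fit_*`` functions wrap them and return a :class:`KineticFit`
summary.  All fitted constants are "apparent": the co-substrates are held at
fixed concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "AssayConfig",
    "AssayTrace",
    "RateSeries",
    "KineticFit",
    "PHProfile",
    "PHBellFit",
    "ModelComparison",
    "SpecificityPanel",
    "FitError",
    "UnidentifiableProfileError",
    "MichaelisMentenRegressor",
    "SubstrateInhibitionRegressor",
    "PHBellRegressor",
    "initial_rate",
    "fit_michaelis_menten",
    "fit_substrate_inhibition",
    "fit_ph_bell",
    "compare_models",
    "catalytic_efficiency",
    "coupling_control_check",
    "specificity_test",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries diagnostics, never defaults."""


class UnidentifiableProfileError(FitError):
    """pH data cover only one flank of the bell; both pKa's are not estimable."""


# ---------------------------------------------------------------------------
# trace -> rate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssayConfig:
    """Coupled-assay constants.

    epsilon : NADH extinction coefficient at 340 nm, M^-1 cm^-1.
    path_cm : cuvette path length, cm.
    volume_l : assay volume, L (0.2 mL standard).
    enzyme_m : ligase concentration, M.
    """

    enzyme_m: float
    epsilon: float = 6220.0
    path_cm: float = 1.0
    volume_l: float = 2.0e-4

    def __post_init__(self) -> None:
        for name in ("enzyme_m", "epsilon", "path_cm", "volume_l"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class AssayTrace:
    """A340 time course with its assay configuration."""

    time_s: np.ndarray
    a340: np.ndarray
    config: AssayConfig

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.a340 = np.asarray(self.a340, dtype=float)
        if self.time_s.shape != self.a340.shape:
            raise ValueError("time and A340 arrays must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class InitialRate:
    """v0 in mol ADP / mol ligase / s, with the raw slope it came from."""

    v0: float
    slope_a_per_s: float
    nadh_rate_m_per_s: float
    n_points: int
    negative_flagged: bool


def initial_rate(trace: AssayTrace, window: "tuple[float, float] | None" = None) -> InitialRate:
    """Least-squares slope of A340 vs t over ``window``, converted to v0.

    A computed negative v0 (rising absorbance) is reported as-is and flagged,
    never clamped.
    """
    t, a = trace.time_s, trace.a340
    if window is not None:
        lo, hi = window
        if lo < t[0] - 1e-12 or hi > t[-1] + 1e-12:
            raise ValueError(f"window {window} outside trace span ({t[0]}, {t[-1]})")
        mask = (t >= lo) & (t <= hi)
        t, a = t[mask], a[mask]
    if t.size < 3:
        raise ValueError("window must contain at least 3 points")
    slope = float(np.polyfit(t, a, 1)[0])
    cfg = trace.config
    nadh_m_per_s = -slope / (cfg.epsilon * cfg.path_cm)
    v0 = nadh_m_per_s / cfg.enzyme_m
    return InitialRate(
        v0=v0, slope_a_per_s=slope, nadh_rate_m_per_s=nadh_m_per_s,
        n_points=int(t.size), negative_flagged=v0 < 0,
    )


# ---------------------------------------------------------------------------
# rate models
# ---------------------------------------------------------------------------


@dataclass
class RateSeries:
    """Initial rates v0 (ADP/s) versus substrate concentration S (uM)."""

    s_um: np.ndarray
    v0: np.ndarray
    replicate: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        self.s_um = np.asarray(self.s_um, dtype=float)
        self.v0 = np.asarray(self.v0, dtype=float)
        if self.s_um.shape != self.v0.shape:
            raise ValueError("S and v0 must have equal length")
        if np.any(self.s_um < 0):
            raise ValueError("substrate concentrations must be >= 0")
        if not np.all(np.isfinite(self.v0)):
            raise ValueError("rates must be finite")


def michaelis_menten(s, vmax, km):
    return vmax * s / (km + s)


def substrate_inhibition(s, vmax, km, ki):
    return vmax * s / (km + s * (1.0 + s / ki))


def ph_bell(ph, vopt, pka1, pka2):
    return vopt / (1.0 + 10.0 ** (pka1 - ph) + 10.0 ** (ph - pka2))


def _r_squared(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def _aicc(n: int, n_params: int, ss_res: float) -> float:
    """Small-sample corrected AIC under i.i.d. Gaussian errors (k counts sigma)."""
    k = n_params + 1
    ss = max(ss_res, 1e-300)
    aic = n * math.log(ss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    else:
        aic = math.inf
    return aic


class _NLSRegressor(RegressorMixin, BaseEstimator):
    """Shared curve_fit machinery for the 1-D kinetic models."""

    _param_names: tuple[str, ...] = ()
    _model: Callable = staticmethod(lambda x: x)

    def __init__(self, max_nfev: int = 10000):
        self.max_nfev = max_nfev

    # subclasses provide starting points and bounds
    def _starts(self, x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
        raise NotImplementedError

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def _validate_xy(self, X, y) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("expected a single feature column")
            x = x[:, 0]
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("X and y must have equal length")
        return x, y

    def fit(self, X, y):
        x, y = self._validate_xy(X, y)
        n_distinct = np.unique(x).size
        if n_distinct < len(self._param_names):
            raise ValueError(
                f"need >= {len(self._param_names)} distinct x values, got {n_distinct}"
            )
        best = None
        errors = []
        for p0 in self._starts(x, y):
            try:
                popt, pcov = optimize.curve_fit(
                    type(self)._model,
                    x,
                    y,
                    p0=p0,
                    bounds=self._bounds(),
                    max_nfev=self.max_nfev,
                    method="trf",
                )
            except (RuntimeError, ValueError) as exc:  # non-convergence
                errors.append(f"start {np.round(p0, 6)}: {exc}")
                continue
            ss = float(np.sum((y - type(self)._model(x, *popt)) ** 2))
            if best is None or ss < best[2]:
                best = (popt, pcov, ss)
        if best is None:
            raise FitError(
                f"{type(self).__name__} failed to converge from all starts: {errors}"
            )
        popt, pcov, ss_res = best
        self.params_ = dict(zip(self._param_names, map(float, popt)))
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(pcov))
        self.se_ = dict(zip(self._param_names, map(float, se)))
        self.cov_ = pcov
        self.ss_res_ = ss_res
        self.n_obs_ = int(x.size)
        self.r_squared_ = _r_squared(y, type(self)._model(x, *popt))
        self.aicc_ = _aicc(self.n_obs_, len(self._param_names), ss_res)
        for name, value in self.params_.items():
            setattr(self, f"{name}_", value)
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return type(self)._model(x, *self.params_.values())

    def confidence_intervals(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        """Per-parameter t-based CIs from the linearized covariance."""
        check_is_fitted(self, "params_")
        dof = max(self.n_obs_ - len(self._param_names), 1)
        tq = stats.t.ppf(0.5 + level / 2.0, dof)
        return {
            name: (self.params_[name] - tq * self.se_[name],
                   self.params_[name] + tq * self.se_[name])
            for name in self._param_names
        }


class MichaelisMentenRegressor(_NLSRegressor):
    """v = Vmax * S / (KM + S); fitted attributes ``vmax_``, ``km_``."""

    _param_names = ("vmax", "km")
    _model = staticmethod(michaelis_menten)

    def _starts(self, x, y):
        vmax0 = max(float(np.max(y)), 1e-12)
        half = np.abs(y - vmax0 / 2.0)
        km0 = max(float(x[np.argmin(half)]), 1e-9)
        return [
            np.array([vmax0, km0]),
            np.array([vmax0 * 1.5, max(float(np.median(x[x > 0])) if np.any(x > 0) else 1.0, 1e-9)]),
        ]

    def _bounds(self):
        return (np.array([0.0, 1e-12]), np.array([np.inf, np.inf]))


class SubstrateInhibitionRegressor(_NLSRegressor):
    """v = Vmax * S / (KM + S (1 + S/Ki)); attributes ``vmax_``, ``km_``, ``ki_``.

    The fitted curve peaks at S* = sqrt(KM * Ki).
    """

    _param_names = ("vmax", "km", "ki")
    _model = staticmethod(substrate_inhibition)

    def _starts(self, x, y):
        vmax0 = max(float(np.max(y)), 1e-12)
        half = np.abs(y - vmax0 / 2.0)
        km0 = max(float(x[np.argmin(half)]), 1e-9)
        smax = max(float(np.max(x)), 1.0)
        return [
            np.array([vmax0, km0, smax]),
            np.array([vmax0 * 2.0, km0, smax * 10.0]),
            np.array([vmax0, km0, 1e7]),
        ]

    def _bounds(self):
        return (np.array([0.0, 1e-12, 1e-12]), np.array([np.inf, np.inf, np.inf]))

    @property
    def s_optimum_(self) -> float:
        check_is_fitted(self, "params_")
        return math.sqrt(self.km_ * self.ki_)


class PHBellRegressor(_NLSRegressor):
    """Diprotic bell; fitted attributes ``vopt_``, ``pka1_``, ``pka2_``.

    Raises :class:`UnidentifiableProfileError` when the data are one-sided
    (the empirical maximum sits on a boundary of the pH grid), since a
    single observed flank cannot pin down both ionizations.
    """

    _param_names = ("vopt", "pka1", "pka2")
    _model = staticmethod(ph_bell)

    def fit(self, X, y):
        x, yv = self._validate_xy(X, y)
        if np.unique(x).size < 5:
            raise ValueError("need >= 5 distinct pH values spanning both flanks")
        order = np.argsort(x)
        imax = int(np.argmax(yv[order]))
        if imax == 0 or imax == x.size - 1:
            raise UnidentifiableProfileError(
                "activity maximum lies on the boundary of the pH grid; "
                "both flanks of the bell are required to estimate pKa1 and pKa2"
            )
        fitted = super().fit(x, yv)
        if fitted.pka1_ >= fitted.pka2_:
            raise FitError(
                f"fit collapsed: pKa1 ({fitted.pka1_:.3f}) >= pKa2 ({fitted.pka2_:.3f})"
            )
        return fitted

    def _starts(self, x, y):
        ph_at_max = float(x[np.argmax(y)])
        vopt0 = max(float(np.max(y)), 1e-12)
        return [
            np.array([vopt0, ph_at_max - 1.0, ph_at_max + 1.0]),
            np.array([vopt0 * 1.2, ph_at_max - 2.0, ph_at_max + 2.0]),
        ]

    def _bounds(self):
        return (np.array([0.0, -2.0, -2.0]), np.array([np.inf, 16.0, 16.0]))

    @property
    def optimum_(self) -> float:
        check_is_fitted(self, "params_")
        return 0.5 * (self.pka1_ + self.pka2_)


# ---------------------------------------------------------------------------
# summaries and wrappers
# ---------------------------------------------------------------------------


@dataclass
class KineticFit:
    """Reported constants of one rate-curve fit (all 'apparent')."""

    model: str  # "MM" | "SI"
    vmax: float  # ADP/s
    km: float  # uM
    ki: "float | None"  # uM, SI only
    se: dict[str, float]
    r_squared: float
    n: int
    ss_res: float
    aicc: float
    apparent: bool = True
    estimator: "object | None" = field(default=None, repr=False, compare=False)

    @property
    def kcat(self) -> float:
        """kcat in s^-1; equals Vmax because v0 is already per mol of enzyme."""
        return self.vmax

    @property
    def kcat_over_km(self) -> float:
        """Apparent catalytic efficiency, uM^-1 s^-1."""
        if self.km <= 0:
            raise ValueError("KM must be positive")
        return self.kcat / self.km

    def confidence_intervals(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        return self.estimator.confidence_intervals(level)


def _as_xy(data: "RateSeries") -> tuple[np.ndarray, np.ndarray]:
    return data.s_um, data.v0


def fit_michaelis_menten(data: RateSeries) -> KineticFit:
    est = MichaelisMentenRegressor().fit(*_as_xy(data))
    return KineticFit(
        model="MM", vmax=est.vmax_, km=est.km_, ki=None, se=est.se_,
        r_squared=est.r_squared_, n=est.n_obs_, ss_res=est.ss_res_,
        aicc=est.aicc_, estimator=est,
    )


def fit_substrate_inhibition(data: RateSeries) -> KineticFit:
    est = SubstrateInhibitionRegressor().fit(*_as_xy(data))
    return KineticFit(
        model="SI", vmax=est.vmax_, km=est.km_, ki=est.ki_, se=est.se_,
        r_squared=est.r_squared_, n=est.n_obs_, ss_res=est.ss_res_,
        aicc=est.aicc_, estimator=est,
    )


@dataclass
class ModelComparison:
    """Both fits side by side; headline selection by R², AICc advisory."""

    mm: KineticFit
    si: KineticFit
    selected: str  # "MM" | "SI" | "tie"
    selected_by_aicc: str
    delta_r_squared: float  # R²(SI) - R²(MM)
    delta_aicc: float  # AICc(SI) - AICc(MM)


def compare_models(mm: KineticFit, si: KineticFit, tie_eps: float = 1e-9) -> ModelComparison:
    """Compare an MM and an SI fit of the same data.

    Headline selection follows the larger R²; because SI nests MM it can
    only help R², so the small-sample AICc (which charges for Ki) is
    reported alongside and is the better guide when the models are close.
    """
    if mm.n != si.n:
        raise ValueError("fits must be on the same data (unequal n)")
    d_r2 = si.r_squared - mm.r_squared
    if abs(d_r2) <= tie_eps:
        selected = "tie"
    else:
        selected = "SI" if d_r2 > 0 else "MM"
    d_aicc = si.aicc - mm.aicc
    by_aicc = "MM" if d_aicc >= 0 else "SI"
    return ModelComparison(
        mm=mm, si=si, selected=selected, selected_by_aicc=by_aicc,
        delta_r_squared=d_r2, delta_aicc=d_aicc,
    )


def catalytic_efficiency(fit: KineticFit) -> tuple[float, float]:
    """(kcat [s^-1], kcat/KM [uM^-1 s^-1]) from a converged fit."""
    return fit.kcat, fit.kcat_over_km


# ---------------------------------------------------------------------------
# pH profile
# ---------------------------------------------------------------------------


@dataclass
class PHProfile:
    ph: np.ndarray
    v0: np.ndarray

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.v0 = np.asarray(self.v0, dtype=float)
        if self.ph.shape != self.v0.shape:
            raise ValueError("pH and v0 must have equal length")


@dataclass
class PHBellFit:
    vopt: float
    pka1: float
    pka2: float
    optimum: float
    r_squared: float
    se: dict[str, float]
    n: int
    estimator: "object | None" = field(default=None, repr=False, compare=False)


def fit_ph_bell(profile: PHProfile) -> PHBellFit:
    est = PHBellRegressor().fit(profile.ph, profile.v0)
    return PHBellFit(
        vopt=est.vopt_, pka1=est.pka1_, pka2=est.pka2_, optimum=est.optimum_,
        r_squared=est.r_squared_, se=est.se_, n=est.n_obs_, estimator=est,
    )


# ---------------------------------------------------------------------------
# controls and specificity statistics
# ---------------------------------------------------------------------------


@dataclass
class CouplingReport:
    """Is the measured ligase rate independent of coupling-enzyme amount?"""

    mean_ratio: float
    ci: tuple[float, float]
    t_statistic: float
    p_value: float
    independent: bool


def coupling_control_check(
    rates_1x: Sequence[float], rates_2x: Sequence[float], alpha: float = 0.05
) -> CouplingReport:
    """Paired comparison of rates at 1x vs 2x coupling-enzyme concentration.

    Verdict "independent" when the t-CI for the mean 2x/1x ratio contains 1.
    """
    r1 = np.asarray(rates_1x, dtype=float)
    r2 = np.asarray(rates_2x, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError("paired series must have equal length")
    if np.any(r1 == 0):
        raise ValueError("zero rate in the 1x series; ratio undefined")
    ratio = r2 / r1
    mean = float(np.mean(ratio))
    n = ratio.size
    if n > 1 and float(np.std(ratio, ddof=1)) > 0:
        sem = float(np.std(ratio, ddof=1) / math.sqrt(n))
        tq = stats.t.ppf(1 - alpha / 2, n - 1)
        ci = (mean - tq * sem, mean + tq * sem)
        tstat = (mean - 1.0) / sem
        p = 2 * stats.t.sf(abs(tstat), n - 1)
    else:
        ci = (mean, mean)
        tstat = 0.0 if mean == 1.0 else math.inf * np.sign(mean - 1.0)
        p = 1.0 if mean == 1.0 else 0.0
    return CouplingReport(
        mean_ratio=mean, ci=ci, t_statistic=float(tstat), p_value=float(p),
        independent=ci[0] <= 1.0 <= ci[1],
    )


@dataclass
class SpecificityPanel:
    """Replicate v0 values per amino-acid substrate."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}


@dataclass
class GroupStats:
    substrate: str
    n: int
    mean: float
    ci: tuple[float, float]
    t_vs_reference: "float | None"
    p_vs_reference: "float | None"
    t_vs_zero: "float | None" = None
    p_vs_zero: "float | None" = None
    p_adjusted: "float | None" = None
    excluded: bool = False


def _group_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    mean = float(np.mean(x))
    if x.size < 2 or float(np.std(x, ddof=1)) == 0:
        return (mean, mean)
    sem = float(np.std(x, ddof=1) / math.sqrt(x.size))
    tq = stats.t.ppf(0.5 + level / 2.0, x.size - 1)
    return (mean - tq * sem, mean + tq * sem)


def specificity_test(
    panel: SpecificityPanel,
    reference: str,
    welch: bool = True,
    holm: bool = False,
) -> list[GroupStats]:
    """Specificity panel statistics: per-group mean, 95% CI and t-tests.

    Each substrate is compared to ``reference`` with an unpaired two-tailed
    t-test (Welch by default; classic Student with ``welch=False``).
    P-values are unadjusted unless ``holm=True``.  Groups with fewer than 2
    replicates are excluded with a warning flag in the output.
    """
    if reference not in panel.groups:
        raise KeyError(f"reference substrate {reference!r} not in panel")
    ref = panel.groups[reference]
    if ref.size < 2:
        raise ValueError("reference group needs >= 2 replicates")
    out: list[GroupStats] = []
    tested: list[GroupStats] = []
    for name, x in panel.groups.items():
        if x.size < 2:
            out.append(GroupStats(name, int(x.size), float(np.mean(x)) if x.size else math.nan,
                                  (math.nan, math.nan), None, None, excluded=True))
            continue
        mean = float(np.mean(x))
        ci = _group_ci(x)
        if np.std(x, ddof=1) == 0:
            t0, p0 = (0.0, 1.0) if mean == 0 else (math.inf, 0.0)
        else:
            t0, p0 = stats.ttest_1samp(x, 0.0)
        if name == reference:
            gs = GroupStats(name, int(x.size), mean, ci, None, None,
                            t_vs_zero=float(t0), p_vs_zero=float(p0))
        else:
            if np.std(x, ddof=1) == 0 and np.std(ref, ddof=1) == 0 and np.mean(x) == np.mean(ref):
                t, p = 0.0, 1.0  # identical degenerate groups
            else:
                t, p = stats.ttest_ind(x, ref, equal_var=not welch)
            gs = GroupStats(name, int(x.size), mean, ci, float(t), float(p),
                            t_vs_zero=float(t0), p_vs_zero=float(p0))
            tested.append(gs)
        out.append(gs)
    if holm and tested:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests([g.p_vs_reference for g in tested], method="holm")
        for g, pa in zip(tested, p_adj):
            g.p_adjusted = float(pa)
    return out
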