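"""Farquhar–von Caemmerer–Berry (FvCB) model of C3 leaf photosynthesis.

Net assimilation is the minimum of the Rubisco-limited carboxylation rate

    A_c = Vcmax * (Ci - Gamma*) / (Ci + Km),        Km = Kc * (1 + O2 / Ko)

and the RuBP-regeneration (electron-transport) limited rate

    A_j = J * (Ci - Gamma*) / (4 Ci + 8 Gamma*),

minus day respiration Rd.  J is the smaller root of the non-rectangular
hyperbola  theta J^2 - (alpha I + Jmax) J + alpha I Jmax = 0, with I the
incident PPFD, alpha the apparent quantum yield on an electron basis and
theta the curvature.

This module provides the forward model, quality control for measured
CO2-response (A/Ci) curves, and a bounded multi-start nonlinear
least-squares fitter estimating (Vcmax, Jmax, Rd) with standard errors.
All kinetics are for a leaf temperature of 25 C; no temperature response
is applied (measurements are assumed made at 25 C) and triose-phosphate
(TPU) limitation is not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sstats
from sklearn.base import BaseEstimator

__all__ = [
    "KineticConstants",
    "ACiCurve",
    "QCResult",
    "FvCBFit",
    "electron_transport_rate",
    "fvcb_assimilation",
    "limiting_rates",
    "qc_aci",
    "FvCBFitter",
    "fit_aci",
    "CI_PROTOCOL_PPM",
]

#: The 13-step chamber Ci protocol (ppm): start at ambient 400, step down to
#: compensation, return to ambient (twice) and step up to 2000.
CI_PROTOCOL_PPM = (400.0, 300.0, 200.0, 100.0, 50.0, 0.0,
                   400.0, 400.0, 600.0, 800.0, 1200.0, 1600.0, 2000.0)


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetic constants at 25 C (Bernacchi-family values).

    Parameters
    ----------
    gamma_star : float
        CO2 compensation point in the absence of day respiration (ppm).
    kc : float
        Michaelis constant of Rubisco for CO2 (ppm).
    ko : float
        Michaelis constant of Rubisco for O2 (mbar).
    o2 : float
        Chloroplastic O2 partial pressure (mbar).
    """

    gamma_star: float = 42.75
    kc: float = 404.9
    ko: float = 278.4
    o2: float = 210.0

    def __post_init__(self) -> None:
        for name in ("gamma_star", "kc", "ko", "o2"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"KineticConstants.{name} must be positive and finite")

    @property
    def km(self) -> float:
        """Effective Michaelis constant for carboxylation, Kc*(1+O2/Ko) (ppm)."""
        return self.kc * (1.0 + self.o2 / self.ko)


@dataclass
class ACiCurve:
    """An ordered CO2-response curve: (Ci, A) pairs plus chamber metadata."""

    ci: np.ndarray
    a: np.ndarray
    leaf_temp: float = 25.0
    ppfd: float = 1800.0
    ca_ambient: float = 400.0
    label: str = ""

    def __post_init__(self) -> None:
        self.ci = np.asarray(self.ci, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.ci.shape != self.a.shape or self.ci.ndim != 1:
            raise ValueError("ci and a must be 1-d arrays of equal length")
        if self.ci.size == 0:
            raise ValueError("empty A/Ci curve")
        if self.leaf_temp <= 0 or self.ppfd <= 0:
            raise ValueError("leaf_temp and ppfd must be positive")

    def __len__(self) -> int:
        return self.ci.size


def electron_transport_rate(ppfd, jmax, alpha: float = 0.24, theta: float = 0.85):
    """Potential electron transport rate J at irradiance `ppfd`.

    Smaller root of theta*J^2 - (alpha*I + Jmax)*J + alpha*I*Jmax = 0.
    """
    ppfd = np.asarray(ppfd, dtype=float)
    b = alpha * ppfd + jmax
    disc = b * b - 4.0 * theta * alpha * ppfd * jmax
    return (b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * theta)


def limiting_rates(ci, vcmax, jmax, k: KineticConstants | None = None,
                   ppfd: float = 1800.0, alpha: float = 0.24, theta: float = 0.85):
    """Gross Rubisco-limited and RuBP-regeneration-limited rates (A_c, A_j)."""
    k = k or KineticConstants()
    ci = np.asarray(ci, dtype=float)
    if np.any(ci < 0):
        raise ValueError("ci must be >= 0")
    if vcmax <= 0 or jmax <= 0:
        raise ValueError("vcmax and jmax must be positive")
    a_c = vcmax * (ci - k.gamma_star) / (ci + k.km)
    j = electron_transport_rate(ppfd, jmax, alpha=alpha, theta=theta)
    a_j = j * (ci - k.gamma_star) / (4.0 * ci + 8.0 * k.gamma_star)
    return a_c, a_j


def fvcb_assimilation(ci, vcmax, jmax, rd, k: KineticConstants | None = None,
                      ppfd: float = 1800.0, alpha: float = 0.24, theta: float = 0.85):
    """Net assimilation A = min(A_c, A_j) - Rd (umol m-2 s-1).

    Continuous in Ci; below the compensation point both gross rates are
    negative and A falls below -Rd smoothly.
    """
    if rd < 0:
        raise ValueError("rd must be >= 0")
    a_c, a_j = limiting_rates(ci, vcmax, jmax, k=k, ppfd=ppfd,
                              alpha=alpha, theta=theta)
    return np.minimum(a_c, a_j) - rd


@dataclass
class QCResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # allows `if qc_aci(curve): ...`
        return self.passed


def qc_aci(curve: ACiCurve, min_initial_a: float = 10.0, min_points: int = 5,
           spearman_threshold: float = 0.5) -> QCResult:
    """Quality control for a measured A/Ci curve.

    Rules (all violations reported, not just the first):

    1. assimilation at the first (ambient-Ci) point must be at least
       `min_initial_a` — leaves that are not photosynthetically active
       enough cannot constrain capacity;
    2. at least `min_points` usable points;
    3. all values finite;
    4. A must broadly track Ci over the initial descending limb
       (Spearman rho >= `spearman_threshold`), guarding against leaks,
       drift or stomatal closure during the down-ramp.
    """
    if len(curve) == 0:
        raise ValueError("empty A/Ci curve")
    reasons: list[str] = []
    finite = np.isfinite(curve.ci) & np.isfinite(curve.a)
    if not finite.all():
        reasons.append("non-finite values present")
    if finite.sum() < min_points:
        reasons.append(f"too few points ({int(finite.sum())} < {min_points})")
    if finite[0] and curve.a[0] < min_initial_a:
        reasons.append(f"initial A below {min_initial_a:g}")
    # initial descending limb: maximal prefix with non-increasing Ci
    limb_end = 1
    while limb_end < len(curve) and curve.ci[limb_end] <= curve.ci[limb_end - 1]:
        limb_end += 1
    if limb_end >= 3:
        ci_limb = curve.ci[:limb_end]
        a_limb = curve.a[:limb_end]
        ok = np.isfinite(ci_limb) & np.isfinite(a_limb)
        if ok.sum() >= 3:
            rho = sstats.spearmanr(ci_limb[ok], a_limb[ok]).statistic
            if not np.isfinite(rho) or rho < spearman_threshold:
                reasons.append("A not increasing with Ci on descending limb")
    return QCResult(passed=not reasons, reasons=reasons)


@dataclass
class FvCBFit:
    """Result of fitting the FvCB model to one A/Ci curve."""

    vcmax: float
    jmax: float
    rd: float
    se_vcmax: float
    se_jmax: float
    se_rd: float
    rmse: float
    n_points: int
    limitation_labels: list[str]
    success: bool
    flags: list[str] = field(default_factory=list)
    label: str = ""


# multi-start grid: coarse Vcmax ladder with Jmax = 2*Vcmax avoids the
# local minimum where the two limitations swap roles
_DEFAULT_STARTS = ((25.0, 50.0, 1.0), (50.0, 100.0, 1.0),
                   (100.0, 200.0, 1.0), (200.0, 400.0, 1.0))
_DEFAULT_BOUNDS = ((1.0, 1.0, 0.0), (1000.0, 2000.0, 10.0))


class FvCBFitter(BaseEstimator):
    """Bounded multi-start least-squares estimator of (Vcmax, Jmax, Rd).

    scikit-learn-style: ``fit(ci, a)`` populates trailing-underscore
    attributes (``vcmax_``, ``jmax_``, ``rd_``, ``se_*_``, ``rmse_``,
    ``limitation_labels_``); ``predict(ci)`` evaluates the fitted model.

    Parameters
    ----------
    kinetics : KineticConstants
        Rubisco kinetics at 25 C.
    ppfd, alpha, theta : float
        Light environment / light-response parameters. At PPFD 1800 the
        electron transport rate is close to Jmax, so estimates are
        insensitive to alpha and theta.
    starts : sequence of (vcmax, jmax, rd)
        Multi-start initial guesses; the best final SSR wins.
    bounds : ((lo_v, lo_j, lo_rd), (hi_v, hi_j, hi_rd))
        Box constraints; a solution within `bound_rtol` of a bound is
        flagged rather than silently accepted.
    """

    def __init__(self, kinetics: KineticConstants | None = None,
                 ppfd: float = 1800.0, alpha: float = 0.24, theta: float = 0.85,
                 starts=_DEFAULT_STARTS, bounds=_DEFAULT_BOUNDS,
                 bound_rtol: float = 1e-3):
        self.kinetics = kinetics
        self.ppfd = ppfd
        self.alpha = alpha
        self.theta = theta
        self.starts = starts
        self.bounds = bounds
        self.bound_rtol = bound_rtol

    def _model(self, ci, params):
        vcmax, jmax, rd = params
        return fvcb_assimilation(ci, vcmax, jmax, rd,
                                 k=self.kinetics or KineticConstants(),
                                 ppfd=self.ppfd, alpha=self.alpha, theta=self.theta)

    def fit(self, ci, a):
        ci = np.asarray(ci, dtype=float)
        a = np.asarray(a, dtype=float)
        if ci.ndim != 1 or ci.shape != a.shape:
            raise ValueError("ci and a must be 1-d arrays of equal length")
        if ci.size < 5:
            raise ValueError("need at least 5 points to fit the FvCB model")
        if np.any(~np.isfinite(ci)) or np.any(~np.isfinite(a)):
            raise ValueError("non-finite values in input; run QC first")
        if np.any(ci < 0):
            raise ValueError("ci must be >= 0")

        lo, hi = np.asarray(self.bounds[0], float), np.asarray(self.bounds[1], float)

        def resid(p):
            return self._model(ci, p) - a

        best = None
        for x0 in self.starts:
            try:
                # min(A_c, A_j) is only piecewise smooth, so the gradient
                # test can be unattainable at a limitation crossover; step
                # and cost tolerances govern convergence instead
                sol = optimize.least_squares(
                    resid, np.clip(np.asarray(x0, float), lo, hi),
                    bounds=(lo, hi), method="trf", xtol=1e-8, ftol=1e-8,
                    gtol=None)
            except Exception:  # pragma: no cover - defensive
                continue
            if not sol.success:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            self.success_ = False
            self.flags_ = ["optimizer failed to converge from every start"]
            self.vcmax_ = self.jmax_ = self.rd_ = np.nan
            self.se_vcmax_ = self.se_jmax_ = self.se_rd_ = np.nan
            self.rmse_ = np.nan
            self.limitation_labels_ = []
            self.n_points_ = ci.size
            return self

        vcmax, jmax, rd = best.x
        n, p = ci.size, 3
        ssr = 2.0 * best.cost
        sigma2 = ssr / max(n - p, 1)
        jac = best.jac
        try:
            cov = sigma2 * np.linalg.inv(jac.T @ jac)
            ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            cov = sigma2 * np.linalg.pinv(jac.T @ jac)
            ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))

        flags: list[str] = []
        for name, val, l, h in zip(("vcmax", "jmax", "rd"), best.x, lo, hi):
            span = h - l
            if val - l < self.bound_rtol * span or h - val < self.bound_rtol * span:
                if not (name == "rd" and abs(val - l) < self.bound_rtol * span):
                    flags.append(f"{name} at bound")

        a_c, a_j = limiting_rates(ci, vcmax, jmax,
                                  k=self.kinetics or KineticConstants(),
                                  ppfd=self.ppfd, alpha=self.alpha, theta=self.theta)
        labels = ["Rubisco" if c <= j else "RuBP-regeneration"
                  for c, j in zip(a_c, a_j)]
        if "Rubisco" not in labels or "RuBP-regeneration" not in labels:
            flags.append("single limitation state across all points")

        self.vcmax_, self.jmax_, self.rd_ = map(float, best.x)
        self.se_vcmax_, self.se_jmax_, self.se_rd_ = map(float, ses)
        self.rmse_ = float(np.sqrt(ssr / n))
        self.limitation_labels_ = labels
        self.n_points_ = n
        self.success_ = True
        self.flags_ = flags
        return self

    def predict(self, ci):
        if not hasattr(self, "vcmax_"):
            raise RuntimeError("FvCBFitter is not fitted")
        return self._model(np.asarray(ci, dtype=float),
                           (self.vcmax_, self.jmax_, self.rd_))

    def result_(self, label: str = "") -> FvCBFit:
        return FvCBFit(vcmax=self.vcmax_, jmax=self.jmax_, rd=self.rd_,
                       se_vcmax=self.se_vcmax_, se_jmax=self.se_jmax_,
                       se_rd=self.se_rd_, rmse=self.rmse_,
                       n_points=self.n_points_,
                       limitation_labels=list(self.limitation_labels_),
                       success=self.success_, flags=list(self.flags_),
                       label=label)


def fit_aci(curve: ACiCurve, k: KineticConstants | None = None,
            require_qc: bool = True, **fitter_kwargs) -> FvCBFit:
    """Fit the FvCB model to an A/Ci curve; point order does not matter.

    Raises if the curve fails QC (set ``require_qc=False`` to only warn).
    """
    qc = qc_aci(curve)
    if not qc.passed:
        msg = "A/Ci curve failed QC: " + "; ".join(qc.reasons)
        if require_qc:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    fitter = FvCBFitter(kinetics=k, ppfd=curve.ppfd, **fitter_kwargs)
    fitter.fit(curve.ci, curve.a)
    return fitter.result_(label=curve.label)
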