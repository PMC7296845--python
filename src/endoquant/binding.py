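"""One-site binding fits, end-point titres and domain-titre analyses."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import rankdata

from .errors import SpecValidationError, UndefinedCorrelationError
from .synthetic import TitrationCurve, one_site

__all__ = [
    "BindingFit",
    "DilutionSeries",
    "DomainTitres",
    "TitreResult",
    "DomainRatio",
    "fit_one_site",
    "endpoint_titre",
    "domain_ratio",
    "correlate_titres",
]


@dataclass
class BindingFit:
    Kd: float
    Bmax: float
    standard_errors: dict[str, float]
    rss: float
    converged: bool
    n_points: int
    message: str = ""

    def predict(self, x) -> np.ndarray:
        return one_site(np.asarray(x, dtype=float), self.Bmax, self.Kd)


def _initial_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    bmax0 = float(np.max(y))
    half = bmax0 / 2.0
    kd0 = None
    for xi, yi in sorted(zip(x, y)):
        if yi >= half and xi > 0:
            kd0 = float(xi)
            break
    if kd0 is None or kd0 <= 0:
        positive = x[x > 0]
        kd0 = float(np.median(positive)) if positive.size else 1.0
    return bmax0, kd0


def fit_one_site(curve: TitrationCurve, max_nfev: int = 2000) -> BindingFit:
    """Least-squares fit of ``y = Bmax * x / (x + Kd)``.

    Positivity of both parameters is enforced via a log parameterization;
    the optimizer is damped least squares (scipy ``least_squares``).
    Standard errors come from the local curvature (Gauss-Newton
    approximation of the Hessian at the optimum, delta method back from
    log scale).
    """
    x, y = curve.x, curve.y
    if np.all(y == y[0]):
        raise SpecValidationError("y", "all signals equal; nothing to fit")
    if np.all(y == 0):
        raise SpecValidationError("y", "all signals zero; nothing to fit")

    bmax0, kd0 = _initial_guess(x, y)
    theta0 = np.log([max(bmax0, 1e-12), kd0])

    def residuals(theta: np.ndarray) -> np.ndarray:
        bmax, kd = np.exp(theta)
        return one_site(x, bmax, kd) - y

    sol = optimize.least_squares(
        residuals, theta0, method="trf", max_nfev=max_nfev, xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    bmax, kd = np.exp(sol.x)
    rss = float(np.sum(sol.fun**2))

    n, p = x.size, 2
    se = {"Bmax": float("nan"), "Kd": float("nan")}
    if n > p:
        jtj = sol.jac.T @ sol.jac
        try:
            cov_log = np.linalg.inv(jtj) * rss / (n - p)
            se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
            # delta method: se(param) = param * se(log param)
            se = {"Bmax": float(bmax * se_log[0]), "Kd": float(kd * se_log[1])}
        except np.linalg.LinAlgError:
            pass

    return BindingFit(
        Kd=float(kd),
        Bmax=float(bmax),
        standard_errors=se,
        rss=rss,
        converged=bool(sol.success),
        n_points=int(n),
        message=str(sol.message),
    )


# --------------------------------------------------------------------------
# End-point titres


@dataclass
class DilutionSeries:
    """Signals at a strictly increasing ladder of reciprocal dilutions."""

    dilutions: list[int]
    signals: list[float]
    control_signals: list[float]

    def __post_init__(self) -> None:
        if len(self.dilutions) != len(self.signals):
            raise SpecValidationError("signals", "length must match dilutions")
        d = self.dilutions
        if any(b <= a for a, b in zip(d, d[1:])):
            raise SpecValidationError("dilutions", "must be strictly increasing")


@dataclass
class TitreResult:
    titre: int  # reciprocal dilution; 0 = below starting dilution
    threshold: float
    unsaturated: bool  # True when even the largest tested dilution was positive


def default_endpoint_rule(control_signals: Sequence[float], sd_multiplier: float = 3.0) -> float:
    """Positivity threshold: mean(control) + ``sd_multiplier`` * SD(control)."""
    c = np.asarray(control_signals, dtype=float)
    if c.size == 0:
        raise SpecValidationError("control_signals", "empty control set under the default rule")
    sd = float(c.std(ddof=1)) if c.size > 1 else 0.0
    return float(c.mean()) + sd_multiplier * sd


def endpoint_titre(
    series: DilutionSeries,
    rule: Optional[Callable[[Sequence[float]], float]] = None,
) -> TitreResult:
    """Largest reciprocal dilution whose signal exceeds the positivity threshold.

    The default rule is mean(control) + 3 SD — a reproducible surrogate for
    the blinded visual end-point call.  An all-negative series yields titre
    0 (below the starting dilution); an all-positive series is flagged
    ``unsaturated``.
    """
    threshold = (rule or default_endpoint_rule)(series.control_signals)
    positive = [d for d, s in zip(series.dilutions, series.signals) if s > threshold]
    if not positive:
        return TitreResult(titre=0, threshold=threshold, unsaturated=False)
    titre = max(positive)
    return TitreResult(
        titre=int(titre),
        threshold=threshold,
        unsaturated=(titre == series.dilutions[-1]),
    )


# --------------------------------------------------------------------------
# Domain titres


@dataclass
class DomainTitres:
    subject_id: str
    timepoint: float
    full_length_titre: int
    lrr_titre: int
    eptp_titre: int

    def __post_init__(self) -> None:
        for name in ("full_length_titre", "lrr_titre", "eptp_titre"):
            if getattr(self, name) < 0:
                raise SpecValidationError(name, "titres must be >= 0")


@dataclass
class DomainRatio:
    value: Optional[float]  # lrr/eptp by default; None when one-sided
    one_sided: Optional[str] = None  # "EPTP-negative" / "LRR-negative"
    orientation: str = "lrr_over_eptp"


def domain_ratio(t: DomainTitres, orientation: str = "lrr_over_eptp") -> DomainRatio:
    """Ratio of the two domain titres; zero denominators yield one-sided flags."""
    if orientation == "lrr_over_eptp":
        num, den, flag = t.lrr_titre, t.eptp_titre, "EPTP-negative"
    elif orientation == "eptp_over_lrr":
        num, den, flag = t.eptp_titre, t.lrr_titre, "LRR-negative"
    else:
        raise SpecValidationError("orientation", f"unknown orientation {orientation!r}")
    if den == 0:
        return DomainRatio(value=None, one_sided=flag, orientation=orientation)
    return DomainRatio(value=num / den, orientation=orientation)


# --------------------------------------------------------------------------
# Rank correlation


def _spearman_r(a: np.ndarray, b: np.ndarray) -> float:
    ra, rb = rankdata(a), rankdata(b)  # mid-ranks for ties
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = math.sqrt(float(ra @ ra) * float(rb @ rb))
    if denom == 0:
        raise UndefinedCorrelationError("constant input vector")
    return float(ra @ rb) / denom


def correlate_titres(
    pairs: Sequence[tuple[float, float]],
    n_permutations: int = 10_000,
    seed: int = 0,
    exact_limit: int = 7,
) -> tuple[float, float]:
    """Spearman rank correlation with a permutation p-value.

    Ties use mid-ranks.  For n <= ``exact_limit`` the two-sided p-value is
    exact (all n! permutations of one margin enumerated); otherwise a
    seeded Monte-Carlo permutation test with the standard add-one
    correction is used.
    """
    if len(pairs) < 4:
        raise SpecValidationError("pairs", "need at least 4 pairs")
    a = np.array([p[0] for p in pairs], dtype=float)
    b = np.array([p[1] for p in pairs], dtype=float)
    r_obs = _spearman_r(a, b)

    n = len(pairs)
    tol = 1e-12
    if n <= exact_limit:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r_perm = _spearman_r(a, b[list(perm)])
            if abs(r_perm) >= abs(r_obs) - tol:
                count += 1
            total += 1
        p = count / total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            r_perm = _spearman_r(a, rng.permutation(b))
            if abs(r_perm) >= abs(r_obs) - tol:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    return r_obs, float(p)
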