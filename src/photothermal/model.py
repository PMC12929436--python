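"""Bi-linear photoperiod-response model: fitting, selection, classification.

The genotype mean thermal time to heading is the continuous hinge

    mu_g(P) = I_g + S_g * max(0, T_g - P)

with intrinsic earliness I (°Cd, the plateau), photoperiod sensitivity S
(°Cd per hour of daylength, slope magnitude of the declining arm) and
threshold photoperiod T (h, the breakpoint beyond which longer days no
longer accelerate flowering).  Individual plants scatter around the mean
with Gaussian residual SD sigma.

Estimation is deterministic maximum likelihood by profiling: for any fixed
threshold the model is linear in (I, S), so (I, S) are solved in closed
form (non-negative S) and the threshold is optimised by multi-start over a
fine grid followed by bounded local refinement.  Model variants share or
drop parameters across genotypes (e.g. a flat variant with S = 0, or a
single threshold common to all genotypes) and are ranked by an information
criterion (BIC by default; AICc also computed).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear, minimize_scalar

from .types import PlantRecord, ResponseParams, ValidationError

__all__ = [
    "predict_mean",
    "ModelVariant",
    "FitConfig",
    "ParamEstimate",
    "ModelFit",
    "ComparisonResult",
    "IdentifiabilityError",
    "FULL",
    "FLAT",
    "SHARED_T",
    "VARIANTS",
    "fit",
    "compare_variants",
    "select_best_per_genotype",
    "ResponseClass",
    "Classification",
    "classify_response",
    "Recommendation",
    "recommend_photoperiod",
]

Z_95 = 1.959963984540054  # standard-normal 97.5% quantile


class IdentifiabilityError(ValidationError):
    """The requested parameters cannot be identified from the data layout."""


def predict_mean(params: ResponseParams, photoperiod_h: float) -> float:
    """Mean thermal time (°Cd) under the linear-plateau response."""
    if not (0.0 <= photoperiod_h <= 24.0):
        raise ValidationError("photoperiod must lie in [0, 24] h")
    return params.mean(photoperiod_h)


# ---------------------------------------------------------------------------
# model variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelVariant:
    """Parameter-sharing scheme across genotypes.

    ``sensitivity`` may be ``per_genotype``, ``shared`` or ``fixed_zero``
    (the flat variant; the threshold is then dropped from the parameter
    vector).  ``threshold`` may be ``per_genotype`` or ``shared``; a
    per-genotype threshold is only supported together with per-genotype
    intrinsic earliness and sensitivity (the model is then separable by
    genotype).
    """

    name: str
    intrinsic: str = "per_genotype"
    sensitivity: str = "per_genotype"
    threshold: str = "per_genotype"
    sigma: str = "per_genotype"
    t_bounds: Tuple[float, float] = (12.0, 24.0)

    def __post_init__(self) -> None:
        if self.intrinsic not in {"per_genotype", "shared"}:
            raise ValidationError(f"bad intrinsic sharing {self.intrinsic!r}")
        if self.sensitivity not in {"per_genotype", "shared", "fixed_zero"}:
            raise ValidationError(f"bad sensitivity sharing {self.sensitivity!r}")
        if self.threshold not in {"per_genotype", "shared"}:
            raise ValidationError(f"bad threshold sharing {self.threshold!r}")
        if self.sigma not in {"per_genotype", "shared"}:
            raise ValidationError(f"bad sigma sharing {self.sigma!r}")
        if (
            self.sensitivity != "fixed_zero"
            and self.threshold == "per_genotype"
            and (self.intrinsic != "per_genotype" or self.sensitivity != "per_genotype")
        ):
            raise ValidationError(
                "per-genotype threshold requires per-genotype I and S"
            )
        if not (0.0 <= self.t_bounds[0] < self.t_bounds[1] <= 24.0):
            raise ValidationError("threshold bounds must satisfy 0 <= lo < hi <= 24")

    @property
    def is_flat(self) -> bool:
        return self.sensitivity == "fixed_zero"


FULL = ModelVariant("full")
FLAT = ModelVariant("flat", sensitivity="fixed_zero")
SHARED_T = ModelVariant("sharedT", threshold="shared")

VARIANTS: Dict[str, ModelVariant] = {v.name: v for v in (FULL, FLAT, SHARED_T)}


@dataclass(frozen=True)
class FitConfig:
    """Numerical settings of the ML path."""

    t_grid_step: float = 0.05
    criterion: str = "bic"  # "bic" | "aicc"
    ci_level_z: float = Z_95

    def __post_init__(self) -> None:
        if self.criterion not in {"bic", "aicc"}:
            raise ValidationError(f"unknown criterion {self.criterion!r}")
        if self.t_grid_step <= 0:
            raise ValidationError("t_grid_step must be > 0")


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

@dataclass
class ParamEstimate:
    """Point estimates, standard errors and central 95% intervals."""

    params: ResponseParams
    se: Dict[str, float]
    ci: Dict[str, Tuple[float, float]]
    threshold_identifiable: bool = True
    notes: List[str] = field(default_factory=list)


@dataclass
class ModelFit:
    variant: ModelVariant
    estimates: Dict[str, ParamEstimate]
    n_obs: int
    n_params: int
    loglik: float
    rss: float
    aicc: float
    bic: float
    criterion: str
    converged: bool
    notes: List[str] = field(default_factory=list)

    @property
    def information_criterion(self) -> float:
        """The ranking criterion (lower is better)."""
        return self.bic if self.criterion == "bic" else self.aicc

    def predict(self, genotype: str, photoperiod_h: float) -> float:
        return predict_mean(self.estimates[genotype].params, photoperiod_h)

    def curve_frame(self, p_min: float = 0.0, p_max: float = 24.0,
                    step: float = 0.1) -> pd.DataFrame:
        """Fitted curves on a photoperiod grid (long format, for export)."""
        grid = np.round(np.arange(p_min, p_max + step / 2, step), 6)
        rows = [
            {"genotype": g, "photoperiod_h": float(p),
             "predicted_cd": self.predict(g, float(p))}
            for g in sorted(self.estimates)
            for p in grid
        ]
        return pd.DataFrame(rows, columns=["genotype", "photoperiod_h",
                                           "predicted_cd"])

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.name,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "loglik": self.loglik,
            "rss": self.rss,
            "aicc": self.aicc,
            "bic": self.bic,
            "criterion": self.criterion,
            "information_criterion": self.information_criterion,
            "converged": self.converged,
            "notes": list(self.notes),
            "estimates": {
                g: {
                    "intrinsic_earliness": e.params.intrinsic_earliness,
                    "sensitivity": e.params.sensitivity,
                    "threshold": e.params.threshold,
                    "sigma": e.params.sigma,
                    "se": e.se,
                    "ci": {k: list(v) for k, v in e.ci.items()},
                    "threshold_identifiable": e.threshold_identifiable,
                    "notes": list(e.notes),
                }
                for g, e in self.estimates.items()
            },
        }


@dataclass
class ComparisonResult:
    """Variants ranked by information criterion (ties: fewer params, name)."""

    ranked: List[ModelFit]
    errors: Dict[str, str] = field(default_factory=dict)

    @property
    def best(self) -> ModelFit:
        return self.ranked[0]


# ---------------------------------------------------------------------------
# internals: profiled least squares
# ---------------------------------------------------------------------------

def _records_arrays(records: Sequence[PlantRecord]):
    y = np.array([r.thermal_time_cd for r in records], dtype=float)
    p = np.array([r.photoperiod_h for r in records], dtype=float)
    g = np.array([r.genotype for r in records])
    return y, p, g


def _solve_linear(y: np.ndarray, X: np.ndarray, nonneg: np.ndarray):
    """Least squares with non-negativity on selected coefficients.

    Tries the unconstrained solution first; falls back to bounded lsq only
    when a constrained coordinate goes negative.
    """
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    if np.any(beta[nonneg] < 0):
        lb = np.where(nonneg, 0.0, -np.inf)
        ub = np.full(X.shape[1], np.inf)
        res = lsq_linear(X, y, bounds=(lb, ub), method="bvls")
        beta = res.x
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _design(p: np.ndarray, g: np.ndarray, genos: Sequence[str],
            t_of: Mapping[str, float], variant: ModelVariant):
    """Design matrix for fixed thresholds; returns (X, column labels)."""
    cols, labels = [], []
    if variant.intrinsic == "shared":
        cols.append(np.ones_like(p))
        labels.append(("I", None))
    else:
        for geno in genos:
            cols.append((g == geno).astype(float))
            labels.append(("I", geno))
    if variant.sensitivity == "shared":
        h = np.zeros_like(p)
        for geno in genos:
            m = g == geno
            h[m] = np.maximum(0.0, t_of[geno] - p[m])
        cols.append(h)
        labels.append(("S", None))
    elif variant.sensitivity == "per_genotype":
        for geno in genos:
            m = (g == geno).astype(float)
            cols.append(m * np.maximum(0.0, t_of[geno] - p))
            labels.append(("S", geno))
    return np.column_stack(cols), labels


def _profile_rss(t: float, y, p, g, genos, variant) -> float:
    t_of = {geno: t for geno in genos}
    X, labels = _design(p, g, genos, t_of, variant)
    nonneg = np.array([lab[0] == "S" for lab in labels])
    _, rss = _solve_linear(y, X, nonneg)
    return rss


def _optimize_threshold(objective: Callable[[float], float],
                        bounds: Tuple[float, float],
                        step: float) -> float:
    """Multi-start grid scan + bounded Brent refinement around the best node."""
    lo, hi = bounds
    grid = np.arange(lo, hi + step / 2, step)
    vals = np.array([objective(t) for t in grid])
    best = grid[int(np.argmin(vals))]
    a, b = max(lo, best - step), min(hi, best + step)
    res = minimize_scalar(objective, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x) if res.fun <= objective(best) else float(best)


def _single_genotype_fit(y: np.ndarray, p: np.ndarray,
                         bounds: Tuple[float, float], step: float):
    """Profiled ML for one genotype.

    Returns (I, S, T, rss, t_identifiable, ridge).  Two degenerate layouts
    are resolved deterministically: a zero fitted slope leaves T completely
    unconstrained (reported at the lower bound, non-identifiable), and a
    threshold below the second-smallest observed photoperiod puts only one
    photoperiod on the declining arm, so S and T trade off along an
    RSS-equivalent ridge — the fit is canonicalised to T at that second
    photoperiod, where S becomes the identified initial-segment slope.
    """

    def rss_at(t: float) -> float:
        X = np.column_stack([np.ones_like(p), np.maximum(0.0, t - p)])
        _, rss = _solve_linear(y, X, np.array([False, True]))
        return rss

    t_hat = _optimize_threshold(rss_at, bounds, step)
    X = np.column_stack([np.ones_like(p), np.maximum(0.0, t_hat - p)])
    beta, rss = _solve_linear(y, X, np.array([False, True]))
    i_hat, s_hat = float(beta[0]), float(beta[1])
    identifiable = s_hat > 0
    ridge = False
    if not identifiable:
        # with S = 0 the likelihood is flat in T: report the lower bound,
        # flagged non-identifiable
        t_hat = bounds[0]
        i_hat = float(np.mean(y))
        rss = float(np.sum((y - i_hat) ** 2))
    else:
        distinct = np.unique(p)
        p2 = float(distinct[1])
        if t_hat < p2:
            t_hat = min(p2, bounds[1])
            X = np.column_stack([np.ones_like(p),
                                 np.maximum(0.0, t_hat - p)])
            beta, rss = _solve_linear(y, X, np.array([False, True]))
            i_hat, s_hat = float(beta[0]), float(beta[1])
            identifiable = False
            ridge = True
    return i_hat, s_hat, t_hat, rss, identifiable, ridge


def _gauss_newton_cov(p, t, s, rss, n, k_mean):
    """Per-genotype covariance of (I, S, T) from the response Jacobian."""
    h = np.maximum(0.0, t - p)
    J = np.column_stack([np.ones_like(p), h, s * (p < t).astype(float)])
    dof = max(n - k_mean, 1)
    sigma2 = rss / dof
    JtJ = J.T @ J
    cov = sigma2 * np.linalg.pinv(JtJ)
    return cov


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------

def fit(records: Sequence[PlantRecord], variant: ModelVariant,
        config: Optional[FitConfig] = None) -> ModelFit:
    """Maximum-likelihood fit of a model variant to plant records.

    Raises
    ------
    IdentifiabilityError
        If any genotype has all observations at a single photoperiod while
        the variant estimates a per-genotype threshold (or slope).
    """
    config = config or FitConfig()
    if len(records) == 0:
        raise ValidationError("no records to fit")
    y, p, g = _records_arrays(records)
    genos = sorted(set(g))

    if not variant.is_flat:
        if variant.threshold == "per_genotype":
            for geno in genos:
                if len(np.unique(p[g == geno])) < 2:
                    raise IdentifiabilityError(
                        f"genotype {geno!r} observed at a single photoperiod: "
                        "per-genotype threshold/slope not identifiable"
                    )
        elif len(np.unique(p)) < 2:
            raise IdentifiabilityError(
                "all observations share one photoperiod: threshold/slope "
                "not identifiable"
            )

    notes: List[str] = []
    estimates: Dict[str, ParamEstimate] = {}
    per_geno_rss: Dict[str, float] = {}

    if variant.is_flat:
        t_hat_of = {geno: variant.t_bounds[0] for geno in genos}
        i_of, s_of = {}, {}
        if variant.intrinsic == "shared":
            mu = float(np.mean(y))
            for geno in genos:
                i_of[geno] = mu
        else:
            for geno in genos:
                i_of[geno] = float(np.mean(y[g == geno]))
        for geno in genos:
            s_of[geno] = 0.0
            res = y[g == geno] - i_of[geno]
            per_geno_rss[geno] = float(res @ res)
        t_identifiable = {geno: False for geno in genos}
        ridge_of = {geno: False for geno in genos}
    elif variant.threshold == "per_genotype":
        # fully separable: fit each genotype on its own records
        i_of, s_of, t_hat_of, t_identifiable = {}, {}, {}, {}
        ridge_of: Dict[str, bool] = {}
        for geno in genos:
            m = g == geno
            i_hat, s_hat, t_hat, rss_g, ident, ridge = _single_genotype_fit(
                y[m], p[m], variant.t_bounds, config.t_grid_step
            )
            i_of[geno], s_of[geno], t_hat_of[geno] = i_hat, s_hat, t_hat
            per_geno_rss[geno] = rss_g
            t_identifiable[geno] = ident
            ridge_of[geno] = ridge
            if ridge:
                notes.append(
                    f"{geno}: threshold at/below the second tested "
                    f"photoperiod is not separately identifiable from the "
                    f"slope; reported at its upper bound {t_hat:.2f} h"
                )
            elif not ident:
                notes.append(
                    f"{geno}: fitted slope is zero; threshold not identifiable"
                )
    else:  # shared threshold
        obj = lambda t: _profile_rss(t, y, p, g, genos, variant)
        t_hat = _optimize_threshold(obj, variant.t_bounds, config.t_grid_step)
        t_hat_of = {geno: t_hat for geno in genos}
        X, labels = _design(p, g, genos, t_hat_of, variant)
        nonneg = np.array([lab[0] == "S" for lab in labels])
        beta, _ = _solve_linear(y, X, nonneg)
        coef = dict(zip(labels, beta))
        i_of = {
            geno: float(coef.get(("I", geno), coef.get(("I", None), 0.0)))
            for geno in genos
        }
        s_of = {
            geno: float(coef.get(("S", geno), coef.get(("S", None), 0.0)))
            for geno in genos
        }
        t_identifiable = {geno: s_of[geno] > 0 for geno in genos}
        ridge_of = {geno: False for geno in genos}
        for geno in genos:
            m = g == geno
            mu = i_of[geno] + s_of[geno] * np.maximum(0.0, t_hat - p[m])
            res = y[m] - mu
            per_geno_rss[geno] = float(res @ res)

    rss = float(sum(per_geno_rss.values()))
    n = len(y)

    # parameter count: mean parameters + residual SDs
    n_i = 1 if variant.intrinsic == "shared" else len(genos)
    if variant.is_flat:
        n_s = n_t = 0
    else:
        n_s = 1 if variant.sensitivity == "shared" else len(genos)
        n_t = 1 if variant.threshold == "shared" else len(genos)
    n_sigma = 1 if variant.sigma == "shared" else len(genos)
    k_mean = n_i + n_s + n_t
    k = k_mean + n_sigma

    # Gaussian log-likelihood at the sigma MLE
    if variant.sigma == "shared":
        sigma2 = max(rss / n, 1e-300)
        loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
        sigma_of = {geno: math.sqrt(sigma2) for geno in genos}
    else:
        loglik = 0.0
        sigma_of = {}
        for geno in genos:
            n_g = int(np.sum(g == geno))
            sigma2_g = max(per_geno_rss[geno] / n_g, 1e-300)
            loglik += -0.5 * n_g * (math.log(2 * math.pi * sigma2_g) + 1.0)
            sigma_of[geno] = math.sqrt(sigma2_g)

    aic = -2.0 * loglik + 2.0 * k
    aicc = aic + (2.0 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else math.inf)
    bic = -2.0 * loglik + k * math.log(n)

    # per-genotype uncertainty (Gauss-Newton around the optimum)
    z = config.ci_level_z
    k_mean_per_geno = 1 if variant.is_flat else 3
    for geno in genos:
        m = g == geno
        n_g = int(np.sum(m))
        if variant.is_flat:
            dof = max(n_g - 1, 1)
            se_i = math.sqrt(per_geno_rss[geno] / dof / n_g)
            se = {"intrinsic_earliness": se_i, "sensitivity": 0.0,
                  "threshold": math.nan}
        else:
            cov = _gauss_newton_cov(
                p[m], t_hat_of[geno], s_of[geno], per_geno_rss[geno],
                n_g, k_mean_per_geno,
            )
            diag = np.sqrt(np.maximum(np.diag(cov), 0.0))
            se = {"intrinsic_earliness": float(diag[0]),
                  "sensitivity": float(diag[1]),
                  "threshold": float(diag[2]) if t_identifiable[geno]
                  else math.nan}
        params = ResponseParams(
            intrinsic_earliness=max(i_of[geno], 1e-9),
            sensitivity=max(s_of[geno], 0.0),
            threshold=t_hat_of[geno],
            sigma=sigma_of[geno],
        )
        ci = {
            "intrinsic_earliness": (
                params.intrinsic_earliness - z * se["intrinsic_earliness"],
                params.intrinsic_earliness + z * se["intrinsic_earliness"],
            ),
            "sensitivity": (
                max(0.0, params.sensitivity - z * se["sensitivity"]),
                params.sensitivity + z * se["sensitivity"],
            ),
            "threshold": (
                (params.threshold - z * se["threshold"],
                 params.threshold + z * se["threshold"])
                if not math.isnan(se["threshold"])
                else (math.nan, math.nan)
            ),
        }
        est_notes = []
        if ridge_of.get(geno, False):
            est_notes.append(
                "threshold not separately identifiable below the second "
                "tested photoperiod; reported at its upper bound"
            )
        elif not t_identifiable[geno]:
            est_notes.append("threshold not identifiable (zero fitted slope)")
        estimates[geno] = ParamEstimate(
            params=params, se=se, ci=ci,
            threshold_identifiable=t_identifiable[geno], notes=est_notes,
        )

    return ModelFit(
        variant=variant, estimates=estimates, n_obs=n, n_params=k,
        loglik=loglik, rss=rss, aicc=aicc, bic=bic,
        criterion=config.criterion, converged=True, notes=notes,
    )


def compare_variants(records: Sequence[PlantRecord],
                     variants: Sequence[ModelVariant],
                     config: Optional[FitConfig] = None) -> ComparisonResult:
    """Fit each variant on the same records and rank by information criterion.

    Ties are broken by fewer parameters, then lexicographic variant name.
    Per-variant fit errors are collected, not raised, as long as at least
    one variant fits.
    """
    if len(variants) == 0:
        raise ValidationError("at least one variant is required")
    fits: List[ModelFit] = []
    errors: Dict[str, str] = {}
    for v in variants:
        try:
            fits.append(fit(records, v, config))
        except (ValidationError, np.linalg.LinAlgError) as exc:
            errors[v.name] = str(exc)
    if not fits:
        raise ValidationError(f"all variants failed: {errors}")
    fits.sort(key=lambda f: (f.information_criterion, f.n_params,
                             f.variant.name))
    return ComparisonResult(ranked=fits, errors=errors)


def select_best_per_genotype(
    records: Sequence[PlantRecord],
    variants: Sequence[ModelVariant] = (FULL, FLAT),
    config: Optional[FitConfig] = None,
) -> Dict[str, ModelFit]:
    """Per-genotype model selection: fit candidate variants on each
    genotype's own records and keep the criterion winner."""
    by_geno: Dict[str, List[PlantRecord]] = {}
    for r in records:
        by_geno.setdefault(r.genotype, []).append(r)
    return {
        geno: compare_variants(recs, variants, config).best
        for geno, recs in sorted(by_geno.items())
    }


# ---------------------------------------------------------------------------
# classification and recommendation
# ---------------------------------------------------------------------------

class ResponseClass(str, enum.Enum):
    RESPONSIVE = "responsive"
    FLAT_SATURATED = "flat_saturated"
    INDETERMINATE = "indeterminate"


_FLAT_NOTE = (
    "flat over the tested range: cannot distinguish photoperiod "
    "insensitivity from a threshold below the shortest tested photoperiod "
    "without data at shorter daylengths"
)


@dataclass(frozen=True)
class Classification:
    genotype: str
    category: ResponseClass
    note: str = ""


def classify_response(
    fit_result: ModelFit,
    tested_range: Tuple[float, float],
    near_zero_band: float = 2.0,
) -> Dict[str, Classification]:
    """Classify each genotype as responsive / flat_saturated / indeterminate.

    Responsive: the 95% sensitivity interval lies above the near-zero band
    (default 2 °Cd/h) and the threshold estimate exceeds the shortest
    tested photoperiod.  Flat-saturated: the fitted curve is constant over
    the tested range — either the slope is indistinguishable from zero or
    the threshold sits at/below the range start (consistent with a
    response already saturated at the shortest tested daylength).
    Everything else is indeterminate.
    """
    if not fit_result.converged:
        raise ValidationError("cannot classify an unconverged fit")
    p_min, p_max = tested_range
    if not p_min < p_max:
        raise ValidationError("tested_range must satisfy P_min < P_max")
    out: Dict[str, Classification] = {}
    for geno, est in fit_result.estimates.items():
        s = est.params.sensitivity
        t = est.params.threshold
        s_lo, s_hi = est.ci["sensitivity"]
        if fit_result.variant.is_flat or s == 0.0:
            out[geno] = Classification(geno, ResponseClass.FLAT_SATURATED,
                                       _FLAT_NOTE)
        elif s_lo > near_zero_band and t > p_min:
            out[geno] = Classification(
                geno, ResponseClass.RESPONSIVE,
                f"sensitivity 95% CI [{s_lo:.2f}, {s_hi:.2f}] °Cd/h above "
                f"the {near_zero_band} °Cd/h band; threshold {t:.2f} h "
                f"inside the tested range",
            )
        elif t <= p_min or s_hi < near_zero_band:
            out[geno] = Classification(geno, ResponseClass.FLAT_SATURATED,
                                       _FLAT_NOTE)
        else:
            out[geno] = Classification(
                geno, ResponseClass.INDETERMINATE,
                f"sensitivity 95% CI [{s_lo:.2f}, {s_hi:.2f}] °Cd/h "
                f"straddles the {near_zero_band} °Cd/h band",
            )
    return out


@dataclass(frozen=True)
class Recommendation:
    genotype: str
    photoperiod_h: float
    provenance: str
    warning: str = ""


def recommend_photoperiod(
    genotype: str,
    classifications: Mapping[str, Classification],
    fits: Mapping[str, ModelFit],
    tested_photoperiods: Sequence[float] = (16.0, 18.0, 20.0, 22.0, 24.0),
    conservative_default: float = 22.0,
) -> Recommendation:
    """Genotype-tailored speed-breeding photoperiod.

    Responsive genotypes get the tested photoperiod nearest to the
    estimated threshold (ties snap upward): the threshold estimator is
    unbiased around the true breakpoint, so requiring a tested rung
    strictly above the estimate would jump to the next rung in half the
    replicates even when the breakpoint sits exactly on a rung.
    Flat-saturated genotypes get the shortest tested photoperiod (their
    requirement is already met there); indeterminate genotypes fall back
    to a conservative default with a warning.
    """
    cls = classifications[genotype]
    tested = sorted(tested_photoperiods)
    if cls.category == ResponseClass.RESPONSIVE:
        t_hat = fits[genotype].estimates[genotype].params.threshold
        if t_hat > tested[-1]:
            return Recommendation(
                genotype, tested[-1],
                f"estimated threshold {t_hat:.2f} h above the tested ladder",
                warning="threshold exceeds the longest tested photoperiod",
            )
        nearest = min(tested, key=lambda p: (abs(p - t_hat), -p))
        return Recommendation(
            genotype, nearest,
            f"estimated threshold {t_hat:.2f} h snapped to the nearest "
            f"tested photoperiod",
        )
    if cls.category == ResponseClass.FLAT_SATURATED:
        return Recommendation(
            genotype, tested[0],
            "flat over the tested range: shortest tested photoperiod "
            "already saturates the response",
        )
    return Recommendation(
        genotype, conservative_default,
        "indeterminate response class: conservative default",
        warning="classification indeterminate; using the configured default",
    )
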