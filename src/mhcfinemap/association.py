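"""Single-variant additive logistic association, with optional conditioning.

Each variable is tested one at a time in a logistic regression of
case/control status on its dosage (0-2 copies, fractional allowed for
imputed SNPs), optionally adjusting for a set of previously chosen
conditioning variants. Scan p-values are Wald by default; a likelihood-ratio
variant is available via ``ScanSettings.test_kind``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .cohort import AssociationResult, DosageMatrix


class AssociationError(ValueError):
    pass


@dataclass
class ScanSettings:
    alpha_family: float = 0.05
    max_iterations: int = 100
    tolerance: float = 1e-8
    test_kind: str = "wald"  # or "lrt"

    def __post_init__(self) -> None:
        if not 0 < self.alpha_family < 1:
            raise AssociationError("alpha_family must be in (0,1)")
        if self.tolerance <= 0:
            raise AssociationError("tolerance must be positive")
        if self.test_kind not in ("wald", "lrt"):
            raise AssociationError(f"unknown test kind {self.test_kind!r}")


_Z95 = 1.96  # normal 95% multiplier, matching the reporting convention

# a per-copy |log-odds| this large, or a Wald SE this unstable, marks a
# diverging fit (complete or quasi-complete separation), not a usable estimate
_SEPARATION_BETA = 10.0
_SEPARATION_SE = 25.0


def fit_logistic_additive(
    dosage: np.ndarray,
    status: np.ndarray,
    covariates: list[np.ndarray] | None = None,
    settings: ScanSettings | None = None,
    variant_id: str = "",
    conditioning_set: tuple[str, ...] = (),
) -> AssociationResult:
    """Maximum-likelihood additive logistic fit for one variant.

    Subjects missing the dosage or any covariate are dropped (complete-case
    per test); ``n_used`` records the analyzed count. Constant dosage yields
    a non-informative result and detected separation a non-converged one --
    neither reports an OR.
    """
    settings = settings or ScanSettings()
    dosage = np.asarray(dosage, dtype=float)
    status = np.asarray(status, dtype=float)
    covariates = [np.asarray(c, dtype=float) for c in (covariates or [])]
    mask = np.isfinite(dosage) & np.isfinite(status)
    for c in covariates:
        mask &= np.isfinite(c)
    d, y = dosage[mask], status[mask]
    covs = [c[mask] for c in covariates]
    n = int(mask.sum())

    def failed(reason: str) -> AssociationResult:
        return AssociationResult(variant_id, n_used=n, converged=False,
                                 reason=reason, conditioning_set=conditioning_set)

    if n == 0 or y.min() == y.max():
        return failed("needs at least one case and one control")
    if d.min() == d.max():
        return failed("non-informative: constant dosage")

    X = np.column_stack([np.ones(n), d, *covs])
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            fit = model.fit(method="newton", maxiter=settings.max_iterations,
                            tol=settings.tolerance, disp=0)
            if not fit.mle_retvals.get("converged", True):
                fit = None
        except Exception:
            fit = None
        if fit is None:
            # Newton stalls when a covariate quasi-separates; a quasi-Newton
            # refit still pins down the tested variant's coefficient
            try:
                fit = model.fit(method="lbfgs", maxiter=500, disp=0)
            except Exception:
                return failed("separation or singular design")
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if (not np.isfinite(beta) or not np.isfinite(se)
            or abs(beta) > _SEPARATION_BETA or se > _SEPARATION_SE):
        return failed("separation: |beta| diverging")

    if settings.test_kind == "wald":
        p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else float("nan")
    else:
        X0 = np.column_stack([np.ones(n), *covs])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit0 = sm.Logit(y, X0).fit(method="newton",
                                       maxiter=settings.max_iterations,
                                       tol=settings.tolerance, disp=0)
        lr = 2 * (fit.llf - fit0.llf)
        p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return AssociationResult(
        variant_id=variant_id,
        n_used=n,
        beta=beta,
        se=se,
        or_point=float(np.exp(beta)),
        ci95=(float(np.exp(np.clip(beta - _Z95 * se, -700, 700))),
              float(np.exp(np.clip(beta + _Z95 * se, -700, 700)))),
        p_value=p,
        conditioning_set=conditioning_set,
        converged=True,
    )


def _check_conditioning(matrix: DosageMatrix, conditioning: list[str]) -> None:
    for v in conditioning:
        if v not in matrix:
            raise AssociationError(f"conditioning variant {v!r} not in matrix")
    cols = [matrix.column(v) for v in conditioning]
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            mask = np.isfinite(cols[i]) & np.isfinite(cols[j])
            a, b = cols[i][mask], cols[j][mask]
            if a.std() == 0 or b.std() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            if abs(r) >= 1 - 1e-12:
                raise AssociationError(
                    f"conditioning set collinear: {conditioning[i]!r} and "
                    f"{conditioning[j]!r} have |r| = 1"
                )


def scan(
    matrix: DosageMatrix,
    status: np.ndarray,
    conditioning: list[str] | None = None,
    settings: ScanSettings | None = None,
) -> list[AssociationResult]:
    """Test every non-conditioning variable, adjusted for the conditioning set.

    Returns one result per variable, sorted by p-value (non-converged fits
    last); each result records the conditioning set verbatim.
    """
    settings = settings or ScanSettings()
    conditioning = list(conditioning or [])
    _check_conditioning(matrix, conditioning)
    cond_cols = [matrix.column(v) for v in conditioning]
    cond_tuple = tuple(conditioning)
    status = np.asarray(status, dtype=float)
    results = []
    for vid in matrix.variants:
        if vid in conditioning:
            continue
        results.append(fit_logistic_additive(
            matrix.column(vid), status, cond_cols, settings,
            variant_id=vid, conditioning_set=cond_tuple,
        ))
    results.sort(key=lambda r: (not r.converged,
                                r.p_value if np.isfinite(r.p_value) else 2.0,
                                r.variant_id))
    return results


def bonferroni_threshold(n_variables: int, alpha_family: float = 0.05) -> float:
    """Per-test threshold alpha / N for a family of N comparisons."""
    if n_variables < 1:
        raise AssociationError("need at least one variable")
    return alpha_family / n_variables


@dataclass
class OddsRatio2x2:
    or_point: float
    ci95: tuple[float, float]
    p_value: float
    corrected: bool  # Haldane-Anscombe 0.5 applied to a zero cell


def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> OddsRatio2x2:
    """Allelic odds ratio with Woolf (log-scale Wald) confidence interval.

    ``a``/``b`` are exposed/unexposed allele counts in cases, ``c``/``d``
    in controls. Any zero cell triggers the Haldane-Anscombe 0.5
    continuity correction, flagged in the result.
    """
    counts = [a, b, c, d]
    if any(v < 0 for v in counts):
        raise AssociationError("2x2 counts must be non-negative")
    corrected = any(v == 0 for v in counts)
    if corrected:
        counts = [v + 0.5 for v in counts]
    a, b, c, d = counts
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    p = float(2 * stats.norm.sf(abs(log_or / se)))
    return OddsRatio2x2(
        or_point=float(np.exp(log_or)),
        ci95=(float(np.exp(log_or - _Z95 * se)), float(np.exp(log_or + _Z95 * se))),
        p_value=p,
        corrected=corrected,
    )
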