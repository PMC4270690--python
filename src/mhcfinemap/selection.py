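"""Unconditional multivariate modeling of classical HLA variation.

Two complementary analyses:

* single-locus sufficiency: likelihood-ratio tests asking whether any one
  HLA locus, used as baseline, already explains the contribution of each of
  the other loci (if not, multiple independent locus effects exist);
* bidirectional stepwise selection over allele / haplotype-block dosages
  minimizing AIC (= -2 loglik + 2k), followed by likelihood-ratio pruning so
  that every retained covariate contributes at p <= alpha (0.01 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .cohort import DosageMatrix, VariantDescriptor


class SelectionError(ValueError):
    pass


def _fit(y: np.ndarray, columns: list[np.ndarray], allow_divergent: bool = False):
    """Logistic MLE with intercept; returns the statsmodels result or None.

    With ``allow_divergent`` a fit whose coefficients drift under
    quasi-separation is still returned: the log-likelihood plateaus even when
    a rare covariate's coefficient does not, which is all an LRT needs.
    """
    X = np.column_stack([np.ones(len(y)), *columns]) if columns else np.ones((len(y), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        fit = None
        try:
            fit = model.fit(method="newton", maxiter=200, tol=1e-10, disp=0)
            if not fit.mle_retvals.get("converged", True):
                fit = None
        except Exception:
            fit = None
        if fit is None:
            try:
                fit = model.fit(method="lbfgs", maxiter=500, disp=0)
            except Exception:
                return None
    if not np.all(np.isfinite(fit.params)):
        return None
    if not allow_divergent and np.abs(fit.params).max() > 25:
        return None
    return fit


def _rank_independent(
    base: list[np.ndarray], candidates: list[tuple[str, np.ndarray]],
    tol: float = 1e-8,
) -> tuple[list[str], list[str]]:
    """Split candidate columns into rank-increasing and redundant sets.

    Columns are considered in the given order against an implicit intercept
    plus ``base``; a column is redundant when it does not increase the rank
    of the design (collinearity, e.g. the per-locus dosage-sum constraint).
    """
    n = len(candidates[0][1]) if candidates else (len(base[0]) if base else 0)
    design = [np.ones(n)] + [np.asarray(b, dtype=float) for b in base]
    Q: np.ndarray = np.linalg.qr(np.column_stack(design))[0]
    kept, dropped = [], []
    for name, col in candidates:
        col = np.asarray(col, dtype=float)
        resid = col - Q @ (Q.T @ col)
        norm = np.linalg.norm(resid)
        if norm > tol * max(1.0, np.linalg.norm(col)):
            kept.append(name)
            Q = np.column_stack([Q, resid / norm])
        else:
            dropped.append(name)
    return kept, dropped


# ---------------------------------------------------------------------------
# single-locus sufficiency
# ---------------------------------------------------------------------------

@dataclass
class LocusLRT:
    locus: str
    lr_stat: float
    df: int
    p_value: float
    dropped_columns: list[str] = field(default_factory=list)


def _locus_groups(descriptors: list[VariantDescriptor]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for d in descriptors:
        if d.category == "hla_allele":
            groups.setdefault(d.locus_or_region, []).append(d.variant_id)
    return groups


def _reference_order(matrix: DosageMatrix, status: np.ndarray, ids: list[str]) -> list[str]:
    """Allele columns with the most frequent control allele last (reference)."""
    controls = np.asarray(status) == 0
    freqs = {v: matrix.column(v)[controls].sum() for v in ids}
    ref = max(ids, key=lambda v: (freqs[v], v))
    return [v for v in ids if v != ref] + [ref]

def locus_sufficiency_test(
    matrix: DosageMatrix,
    descriptors: list[VariantDescriptor],
    status: np.ndarray,
    baseline_locus: str,
    alpha: float = 0.05,
) -> tuple[dict[str, LocusLRT], bool]:
    """LRT of every other locus's contribution over a baseline-locus model.

    For each non-baseline locus L, compares baseline-allele model vs
    baseline + L's allele columns; the df counts only linearly independent
    added columns (each locus's most frequent control allele acts as the
    implicit reference and per-locus sums are collinear with the
    intercept). Returns per-locus tests and a "sufficient" verdict: True
    iff no locus is significant at *alpha*.
    """
    groups = _locus_groups(descriptors)
    if baseline_locus not in groups:
        raise SelectionError(f"baseline locus {baseline_locus!r} has no allele columns")
    y = np.asarray(status, dtype=float)

    base_ids = _reference_order(matrix, status, groups[baseline_locus])
    base_kept, _ = _rank_independent([], [(v, matrix.column(v)) for v in base_ids])
    base_cols = [matrix.column(v) for v in base_kept]
    fit0 = _fit(y, base_cols, allow_divergent=True)
    if fit0 is None:
        raise SelectionError(f"baseline model for {baseline_locus} did not converge")

    out: dict[str, LocusLRT] = {}
    for locus, ids in groups.items():
        if locus == baseline_locus:
            continue
        ordered = _reference_order(matrix, status, ids)
        kept, dropped = _rank_independent(
            base_cols, [(v, matrix.column(v)) for v in ordered]
        )
        if not kept:
            out[locus] = LocusLRT(locus, 0.0, 0, 1.0, dropped)
            continue
        fit1 = _fit(y, base_cols + [matrix.column(v) for v in kept],
                    allow_divergent=True)
        if fit1 is None:
            out[locus] = LocusLRT(locus, float("nan"), len(kept), float("nan"), dropped)
            continue
        lr = max(0.0, 2 * (fit1.llf - fit0.llf))
        out[locus] = LocusLRT(locus, lr, len(kept),
                              float(stats.chi2.sf(lr, df=len(kept))), dropped)
    sufficient = all(
        np.isnan(t.p_value) or t.p_value > alpha for t in out.values()
    )
    return out, sufficient


# ---------------------------------------------------------------------------
# stepwise AIC
# ---------------------------------------------------------------------------

@dataclass
class SelectionTrace:
    actions: list[tuple[str, str, float, float]] = field(default_factory=list)
    # (action "add"/"drop", variant_id, AIC before, AIC after)
    final_set: list[str] = field(default_factory=list)
    dropped_collinear: dict[str, str] = field(default_factory=dict)
    skipped_moves: list[str] = field(default_factory=list)
    final_aic: float = float("nan")


def stepwise_aic_select(
    candidates: DosageMatrix,
    status: np.ndarray,
    start: str = "empty",
) -> SelectionTrace:
    """Bidirectional stepwise logistic selection minimizing AIC.

    Starts from an intercept-only model (``start='empty'``) or from all
    candidates (``start='full'``); at each step the single add or drop that
    lowers AIC the most is accepted, ties breaking lexicographically on
    variant id; stops when no move improves. Collinear candidates are
    reduced beforehand to a logged representative. Deterministic given the
    input.
    """
    y = np.asarray(status, dtype=float)
    trace = SelectionTrace()
    kept, dropped = _rank_independent(
        [], [(v, candidates.column(v)) for v in candidates.variants]
    )
    for v in dropped:
        trace.dropped_collinear[v] = "collinear with earlier candidates"
    pool = list(kept)
    current: list[str] = list(pool) if start == "full" else []
    if start not in ("empty", "full"):
        raise SelectionError(f"unknown start {start!r}")

    def aic_of(ids: list[str]) -> float | None:
        fit = _fit(y, [candidates.column(v) for v in ids])
        return None if fit is None else float(-2 * fit.llf + 2 * (len(ids) + 1))

    current_aic = aic_of(current)
    if current_aic is None:
        raise SelectionError("start model did not converge")
    while True:
        moves: list[tuple[float, str, str, list[str]]] = []
        for v in pool:
            proposal = (
                [c for c in current if c != v] if v in current else current + [v]
            )
            action = "drop" if v in current else "add"
            a = aic_of(proposal)
            if a is None:
                trace.skipped_moves.append(f"{action} {v}: fit failed")
                continue
            moves.append((a, v, action, proposal))
        if not moves:
            break
        best_aic, best_v, action, proposal = min(moves, key=lambda m: (m[0], m[1]))
        if best_aic >= current_aic - 1e-9:
            break
        trace.actions.append((action, best_v, current_aic, best_aic))
        current, current_aic = proposal, best_aic
    trace.final_set = sorted(current)
    trace.final_aic = current_aic
    return trace


# ---------------------------------------------------------------------------
# LRT pruning of a selected model
# ---------------------------------------------------------------------------

@dataclass
class PrunedCovariate:
    variant_id: str
    or_point: float
    ci95: tuple[float, float]
    lrt_p: float
    stable: bool = True  # False: Wald SE diverged (quasi-separation); the
    #                      LRT p remains valid but the CI is uninformative


def lrt_prune(
    candidates: DosageMatrix,
    selected: list[str],
    status: np.ndarray,
    alpha: float = 0.01,
) -> list[PrunedCovariate]:
    """Keep only covariates with a significant single-covariate LRT.

    Iteratively refits after dropping the covariate with the largest LRT p
    until every remaining one has p <= alpha (boundary inclusive). Returns
    the final model's per-covariate OR with Wald 95% CI and LRT p; an empty
    result (everything pruned) is a warning, not an error.
    """
    if not selected:
        raise SelectionError("selected set is empty")
    y = np.asarray(status, dtype=float)
    current = list(selected)
    while current:
        fit = _fit(y, [candidates.column(v) for v in current])
        if fit is None:
            raise SelectionError("model fit failed during pruning")
        ps = {}
        for v in current:
            sub = _fit(y, [candidates.column(c) for c in current if c != v])
            if sub is None:
                ps[v] = 0.0  # treat an inestimable reduced model as a keep
                continue
            lr = max(0.0, 2 * (fit.llf - sub.llf))
            ps[v] = float(stats.chi2.sf(lr, df=1))
        worst = max(current, key=lambda v: (ps[v], v))
        if ps[worst] <= alpha:
            out = []
            for i, v in enumerate(current, start=1):
                beta, se = float(fit.params[i]), float(fit.bse[i])
                lo = float(np.exp(np.clip(beta - 1.96 * se, -700, 700)))
                hi = float(np.exp(np.clip(beta + 1.96 * se, -700, 700)))
                out.append(PrunedCovariate(
                    v, float(np.exp(np.clip(beta, -700, 700))), (lo, hi), ps[v],
                    stable=se < 10,
                ))
            return sorted(out, key=lambda c: c.variant_id)
        current.remove(worst)
    warnings.warn("all covariates pruned; returning an empty model")
    return []
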