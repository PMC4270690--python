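"""Additive logistic association: fits, scan semantics, thresholds, 2x2 ORs."""

import numpy as np
import pytest

from mhcfinemap.association import (
    AssociationError,
    ScanSettings,
    bonferroni_threshold,
    fit_logistic_additive,
    odds_ratio_2x2,
    scan,
)
from mhcfinemap.cohort import DosageMatrix
from tests.conftest import newton_logistic


def test_symmetric_dosage_gives_null_or():
    """Identical dosage distribution in cases and controls: beta = 0, OR = 1."""
    dosage = np.array([0, 1, 2, 1, 0, 1] * 2, dtype=float)
    status = np.array([1] * 6 + [0] * 6, dtype=float)
    res = fit_logistic_additive(dosage, status)
    assert res.converged
    assert res.beta == pytest.approx(0.0, abs=1e-8)
    assert res.or_point == pytest.approx(1.0, abs=1e-8)


def test_mle_matches_newton_oracle():
    """The worked 12-subject dataset reproduces an independent Newton-Raphson
    oracle's estimate to 1e-8."""
    dosage = np.array([0, 1, 2, 1, 0, 2, 1, 1, 0, 2, 0, 1], dtype=float)
    status = np.array([0, 1, 1, 0, 0, 0, 1, 1, 1, 1, 0, 0], dtype=float)
    res = fit_logistic_additive(dosage, status)
    X = np.column_stack([np.ones(12), dosage])
    oracle = newton_logistic(X, status)
    assert res.beta == pytest.approx(oracle[1], abs=1e-8)


def test_mle_with_covariate_matches_oracle(study_sim):
    dosage = study_sim.true_dosages["B*08"]
    cov = study_sim.true_dosages["cIII_tag"]
    status = study_sim.status.astype(float)
    res = fit_logistic_additive(dosage, status, [cov])
    X = np.column_stack([np.ones(len(status)), dosage, cov])
    oracle = newton_logistic(X, status)
    assert res.beta == pytest.approx(oracle[1], abs=1e-8)


def test_complete_separation_flagged():
    dosage = np.array([2.0] * 8 + [0.0] * 8)
    status = np.array([1] * 8 + [0] * 8)
    res = fit_logistic_additive(dosage, status)
    assert not res.converged and "separation" in res.reason
    assert np.isnan(res.or_point)


def test_constant_dosage_non_informative():
    res = fit_logistic_additive(np.ones(10), np.array([1] * 5 + [0] * 5))
    assert not res.converged and "non-informative" in res.reason


def test_missing_dosage_complete_case():
    dosage = np.array([0, 1, 2, np.nan, 1, 0, 2, 1])
    status = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    res = fit_logistic_additive(dosage, status)
    assert res.n_used == 7


def test_wald_p_invariant_under_dosage_reflection():
    rng = np.random.default_rng(8)
    dosage = rng.integers(0, 3, size=200).astype(float)
    status = (rng.random(200) < 1 / (1 + np.exp(-(dosage - 1)))).astype(float)
    a = fit_logistic_additive(dosage, status)
    b = fit_logistic_additive(2 - dosage, status)
    assert a.beta == pytest.approx(-b.beta, abs=1e-7)
    assert a.p_value == pytest.approx(b.p_value, rel=1e-6)


@pytest.mark.parametrize("n,expected,rel", [
    (18771, 2.66e-6, 5e-3),   # printed to 3 significant figures
    (1, 0.05, 1e-12),
    (10, 0.005, 1e-12),
])
def test_bonferroni_threshold(n, expected, rel):
    assert bonferroni_threshold(n) == pytest.approx(expected, rel=rel)
    with pytest.raises(AssociationError):
        bonferroni_threshold(0)


def test_odds_ratio_2x2_cross_product():
    res = odds_ratio_2x2(20, 10, 10, 20)
    assert res.or_point == pytest.approx(4.0)
    assert not res.corrected


def test_odds_ratio_allelic_replication_scale():
    """Allele counts implied by 81% / 66% A-allele frequencies in 365 cases and
    368 controls give OR ~2.2 with a Woolf CI overlapping 2.28 [1.79-2.91]."""
    res = odds_ratio_2x2(591, 139, 486, 250)
    assert res.or_point == pytest.approx(2.2, abs=0.1)
    assert res.ci95[0] < 2.28 < res.ci95[1]


def test_odds_ratio_zero_cell_correction():
    res = odds_ratio_2x2(0, 10, 10, 10)
    assert res.corrected and res.or_point > 0
    with pytest.raises(AssociationError):
        odds_ratio_2x2(-1, 1, 1, 1)


def _toy_matrix(seed=0, n=300):
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 3, size=n).astype(float)
    copy = base.copy()                      # r^2 = 1 with base
    other = rng.integers(0, 3, size=n).astype(float)
    status = (rng.random(n) < 1 / (1 + np.exp(-(base - 1)))).astype(int)
    return DosageMatrix([f"s{i}" for i in range(n)], ["base", "copy", "other"],
                        np.column_stack([base, copy, other])), status


def test_scan_base_case_and_sorting():
    matrix, status = _toy_matrix()
    res = scan(matrix, status)
    assert {r.variant_id for r in res} == {"base", "copy", "other"}
    ps = [r.p_value for r in res if r.converged]
    assert ps == sorted(ps)
    assert all(r.conditioning_set == () for r in res)


def test_scan_collinear_conditioning_rejected():
    matrix, status = _toy_matrix()
    with pytest.raises(AssociationError, match="collinear"):
        scan(matrix, status, conditioning=["base", "copy"])


def test_perfectly_tagged_variant_dies_under_conditioning():
    matrix, status = _toy_matrix()
    res = {r.variant_id: r for r in scan(matrix, status, conditioning=["base"])}
    r = res["copy"]
    assert (not r.converged) or r.p_value > 0.5


def test_uncorrelated_conditioning_barely_moves_beta():
    """Adding an independent covariate shifts a null variant's beta by < 3 se."""
    rng = np.random.default_rng(5)
    moved = 0
    for rep in range(50):
        n = 400
        v = rng.integers(0, 3, size=n).astype(float)
        cov = rng.integers(0, 3, size=n).astype(float)
        status = rng.integers(0, 2, size=n).astype(float)
        plain = fit_logistic_additive(v, status)
        adj = fit_logistic_additive(v, status, [cov])
        if abs(adj.beta - plain.beta) > 3 * plain.se:
            moved += 1
    assert moved == 0


def test_lrt_test_kind_agrees_with_wald_asymptotically():
    matrix, status = _toy_matrix(seed=2, n=500)
    wald = {r.variant_id: r for r in scan(matrix, status)}
    lrt = {r.variant_id: r for r in
           scan(matrix, status, settings=ScanSettings(test_kind="lrt"))}
    for v in ("base", "other"):
        lw, ll = -np.log10(wald[v].p_value), -np.log10(lrt[v].p_value)
        assert lw == pytest.approx(ll, rel=0.25, abs=0.5)
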