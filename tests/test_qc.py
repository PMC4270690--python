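"""SNP QC: exact HWE test, genotyped-panel filters, MAF-binned r^2 filter."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhcfinemap.cohort import DosageMatrix
from mhcfinemap.qc import (
    MAF_BINS,
    QCError,
    QCRecord,
    apply_imputation_filter,
    genotyped_qc,
    hwe_exact_test,
    maf_bin_thresholds,
)
from mhcfinemap.simulate import imputation_qc_records, qc_fixture


def hwe_enumeration_oracle(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Full enumeration of the conditional genotype distribution."""
    n = n_hom1 + n_het + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het
    common = 2 * n - rare
    if rare == 0:
        return 1.0
    probs = {}
    for het in range(rare % 2, min(rare, common) + 1, 2):
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        # P(het | allele counts) ~ n! / (hom_r! het! hom_c!) * 2^het
        logp = (
            math.lgamma(n + 1)
            - math.lgamma(hom_r + 1) - math.lgamma(het + 1) - math.lgamma(hom_c + 1)
            + het * math.log(2)
        )
        probs[het] = logp
    mx = max(probs.values())
    vals = {h: math.exp(v - mx) for h, v in probs.items()}
    total = sum(vals.values())
    obs = vals[n_het]
    return min(1.0, sum(v for v in vals.values() if v <= obs * (1 + 1e-12)) / total)


def test_hwe_monomorphic_is_one():
    assert hwe_exact_test(0, 0, 100) == 1.0
    assert hwe_exact_test(50, 0, 0) == 1.0


def test_hwe_equilibrium_counts_match_oracle():
    assert hwe_exact_test(25, 50, 25) == pytest.approx(
        hwe_enumeration_oracle(25, 50, 25), rel=1e-9
    )


def test_hwe_complete_het_deficit_fails_threshold():
    p = hwe_exact_test(50, 0, 50)
    assert p == pytest.approx(hwe_enumeration_oracle(50, 0, 50), rel=1e-9)
    assert p < 1e-4


def test_hwe_rejects_bad_input():
    with pytest.raises(QCError):
        hwe_exact_test(0, 0, 0)
    with pytest.raises(QCError):
        hwe_exact_test(-1, 2, 3)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    n_hom1=st.integers(0, 70), n_het=st.integers(0, 70), n_hom2=st.integers(0, 60)
)
def test_hwe_matches_enumeration_oracle(n_hom1, n_het, n_hom2):
    """Exact test equals the full-enumeration oracle for all totals <= 200."""
    if n_hom1 + n_het + n_hom2 == 0:
        return
    assert hwe_exact_test(n_hom1, n_het, n_hom2) == pytest.approx(
        hwe_enumeration_oracle(n_hom1, n_het, n_hom2), rel=1e-9, abs=1e-300
    )


def test_genotyped_qc_fail_reasons_and_fixture():
    matrix, status, manifest = qc_fixture()
    records, summary = genotyped_qc(matrix, status)
    assert summary["pass"] == 405
    intended = dict(zip(manifest.variant_id, manifest.intended_fail_reason))
    for rec in records:
        assert rec.fail_reason == intended[rec.variant_id]


def test_genotyped_qc_order_insensitive():
    matrix, status, _ = qc_fixture()
    rng = np.random.default_rng(3)
    sperm = rng.permutation(len(matrix.subjects))
    vperm = rng.permutation(len(matrix.variants))
    shuffled = DosageMatrix(
        [matrix.subjects[i] for i in sperm],
        [matrix.variants[j] for j in vperm],
        matrix.values[np.ix_(sperm, vperm)],
    )
    rec0, _ = genotyped_qc(matrix, status)
    rec1, _ = genotyped_qc(shuffled, status[sperm])
    passed0 = {r.variant_id: r.fail_reason for r in rec0}
    passed1 = {r.variant_id: r.fail_reason for r in rec1}
    assert passed0 == passed1


def test_genotyped_qc_requires_controls():
    matrix, status, _ = qc_fixture()
    with pytest.raises(QCError, match="control"):
        genotyped_qc(matrix, np.ones_like(status))


def _rec(i, maf, r2):
    return QCRecord(f"s{i}", 1.0, maf, 1.0, imputation_r2=r2)


def brute_force_cutoff(values, target=0.8):
    best = None
    for cut in sorted({0.0, *values}):
        kept = [v for v in values if v >= cut]
        if kept and np.mean(kept) > target:
            best = cut
            break
    return best


def test_maf_bin_cutoff_presatisfied():
    recs = [_rec(i, 0.02, 0.9) for i in range(10)]
    thr = maf_bin_thresholds(recs)
    assert thr.cutoffs[0] == 0.0
    assert thr.achieved_mean_r2[0] == pytest.approx(0.9)
    assert thr.n_retained[0] == 10


def test_maf_bin_cutoff_matches_brute_force():
    values = [0.5, 0.7, 0.95, 0.99]
    recs = [_rec(i, 0.04, v) for i, v in enumerate(values)]
    thr = maf_bin_thresholds(recs)
    assert thr.cutoffs[1] == pytest.approx(brute_force_cutoff(values))
    rng = np.random.default_rng(12)
    for trial in range(20):
        values = list(rng.uniform(0.1, 1.0, size=rng.integers(1, 30)))
        recs = [_rec(i, 0.10, v) for i, v in enumerate(values)]
        thr = maf_bin_thresholds(recs)
        assert thr.cutoffs[2] == pytest.approx(brute_force_cutoff(values))


def test_maf_bin_degenerate_bins():
    recs = [_rec(0, 0.02, 0.9)]  # bins 2 and 3 empty
    thr = maf_bin_thresholds(recs)
    assert thr.cutoffs[1] is None and "bin2:empty" in thr.flagged
    # unattainable: best single SNP still below the target mean
    recs = [_rec(0, 0.02, 0.5), _rec(1, 0.02, 0.6)]
    thr = maf_bin_thresholds(recs)
    assert thr.cutoffs[0] is None and "bin1:unattainable" in thr.flagged


def test_retained_bins_mean_above_target():
    recs = imputation_qc_records(seed=5)
    thr = maf_bin_thresholds(recs)
    for mean, n in zip(thr.achieved_mean_r2, thr.n_retained):
        if n:
            assert mean > 0.8


def test_apply_imputation_filter_recount():
    recs = imputation_qc_records(seed=7)
    # one sub-1% SNP must go regardless of its r^2
    recs.append(QCRecord("too_rare", 1.0, 0.005, 1.0, imputation_r2=0.99))
    thr = maf_bin_thresholds([r for r in recs if r.maf >= 0.01])
    matrix = DosageMatrix(
        ["s1"], [r.variant_id for r in recs], np.zeros((1, len(recs)))
    )
    filtered = apply_imputation_filter(matrix, recs, thr)
    assert "too_rare" not in filtered.variants
    expected = []
    for r in recs:
        if r.maf <= 0.01:
            continue
        for (lo, hi), cut in zip(MAF_BINS, thr.cutoffs):
            if lo <= r.maf < hi and cut is not None and r.imputation_r2 >= cut:
                expected.append(r.variant_id)
    assert filtered.variants == expected  # column order preserved
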