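"""Multivariate machinery: locus-sufficiency LRTs, stepwise AIC, LRT pruning."""

import itertools

import numpy as np
import pytest
import statsmodels.api as sm

from mhcfinemap.cohort import DosageMatrix
from mhcfinemap.encoding import allele_dosages, encode_cohort
from mhcfinemap.selection import (
    SelectionError,
    locus_sufficiency_test,
    lrt_prune,
    stepwise_aic_select,
)
from mhcfinemap.simulate import recovery_preset, simulate_cohort


def _hla_parts(sim):
    matrix, descs, _ = encode_cohort(sim.records, known_phases=sim.true_phases)
    return matrix, descs


def test_single_locus_effect_makes_baseline_sufficient():
    """With effects at HLA-B only, the B-baseline model explains every other
    locus: the other-locus LRT exceeds 0.05 for >=90% of (replicate, locus)
    pairs (each such LRT is a nominal-level null test)."""
    above = total = 0
    for seed in range(10):
        cfg = recovery_preset(seed=seed, n_cases=400, n_controls=400,
                              effects={"B*08": np.log(3.0)})
        sim = simulate_cohort(cfg)
        matrix, descs = _hla_parts(sim)
        tests, _ = locus_sufficiency_test(matrix, descs, sim.status, "B")
        for t in tests.values():
            above += t.p_value > 0.05
            total += 1
    assert above / total >= 0.9


def test_two_independent_loci_reject_every_single_baseline():
    """Independent effects at HLA-B and HLA-C: neither locus alone suffices."""
    rejected = 0
    for seed in range(6):
        cfg = recovery_preset(seed=100 + seed, n_cases=500, n_controls=500,
                              effects={"B*08": np.log(3.5), "C*06": np.log(3.0)})
        sim = simulate_cohort(cfg)
        matrix, descs = _hla_parts(sim)
        _, suff_b = locus_sufficiency_test(matrix, descs, sim.status, "B")
        _, suff_c = locus_sufficiency_test(matrix, descs, sim.status, "C")
        rejected += (not suff_b) and (not suff_c)
    assert rejected >= 5


def test_duplicate_baseline_columns_give_null_lrt(study_sim):
    """Adding columns collinear with the baseline yields LRT stat 0, p 1."""
    matrix, descs, _ = encode_cohort(study_sim.records)
    b_ids = [d.variant_id for d in descs
             if d.category == "hla_allele" and d.locus_or_region == "B"]
    dup = DosageMatrix(matrix.subjects,
                       b_ids + [f"dup_{v}" for v in b_ids],
                       np.hstack([matrix.subset_variants(b_ids).values] * 2))
    from mhcfinemap.cohort import VariantDescriptor
    dd = ([VariantDescriptor(v, "hla_allele", "B") for v in b_ids]
          + [VariantDescriptor(f"dup_{v}", "hla_allele", "Bdup") for v in b_ids])
    tests, _ = locus_sufficiency_test(dup, dd, study_sim.status, "B")
    assert tests["Bdup"].df == 0 and tests["Bdup"].p_value == 1.0


def exhaustive_best_subset_aic(candidates: DosageMatrix, status) -> float:
    """Brute-force best-subset AIC oracle over all 2^k candidate subsets."""
    y = np.asarray(status, dtype=float)
    ids = candidates.variants
    best = np.inf
    for k in range(len(ids) + 1):
        for subset in itertools.combinations(ids, k):
            cols = [candidates.column(v) for v in subset]
            X = np.column_stack([np.ones(len(y)), *cols]) if cols else np.ones((len(y), 1))
            try:
                fit = sm.Logit(y, X).fit(method="newton", maxiter=100, disp=0)
            except Exception:
                continue
            best = min(best, -2 * fit.llf + 2 * (len(subset) + 1))
    return best


def _small_candidates(seed=0, n=300, k=8, n_effects=2):
    rng = np.random.default_rng(seed)
    values = rng.integers(0, 3, size=(n, k)).astype(float)
    lp = -0.5 + 1.0 * values[:, 0] - 0.9 * values[:, 1] if n_effects else -0.0 * values[:, 0]
    status = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    ids = [f"c{i:02d}" for i in range(k)]
    return DosageMatrix([f"s{i}" for i in range(n)], ids, values), status


def test_stepwise_equals_exhaustive_best_subset():
    """For small candidate sets the greedy bidirectional search reaches the
    exhaustive best-subset AIC."""
    for seed in (0, 1, 2):
        cand, status = _small_candidates(seed=seed)
        trace = stepwise_aic_select(cand, status)
        oracle = exhaustive_best_subset_aic(cand, status)
        assert trace.final_aic == pytest.approx(oracle, abs=1e-6)


def test_stepwise_aic_strictly_decreases():
    cand, status = _small_candidates(seed=5)
    trace = stepwise_aic_select(cand, status)
    for _, _, before, after in trace.actions:
        assert after < before


def test_null_candidates_yield_empty_model_after_pruning():
    """Without planted effects, raw AIC admits the expected ~chi2>2 noise
    variables, but the full procedure (stepwise + LRT pruning at 0.01)
    returns an empty model in >=80% of replicates."""
    empty_after_prune = 0
    n_selected = []
    for seed in range(10):
        cand, status = _small_candidates(seed=30 + seed, n=400, k=10, n_effects=0)
        trace = stepwise_aic_select(cand, status)
        n_selected.append(len(trace.final_set))
        if not trace.final_set:
            empty_after_prune += 1
            continue
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final = lrt_prune(cand, trace.final_set, status, alpha=0.01)
        empty_after_prune += len(final) == 0
    assert empty_after_prune >= 8
    assert np.mean(n_selected) < 3  # AIC noise admissions stay small


def test_stepwise_finds_single_strong_effect():
    """A planted OR-4 variable at n=400+400 is selected in every replicate."""
    for seed in range(10):
        cfg = recovery_preset(seed=200 + seed, n_cases=400, n_controls=400,
                              effects={"B*08": np.log(4.0)})
        sim = simulate_cohort(cfg)
        matrix, descs = _hla_parts(sim)
        cand_ids = [d.variant_id for d in descs if d.category == "hla_allele"
                    and d.locus_or_region in ("A", "B", "C", "DRB3")]
        trace = stepwise_aic_select(matrix.subset_variants(cand_ids), sim.status)
        assert "B*08" in trace.final_set


def test_stepwise_collinear_candidates_deduplicated():
    cand, status = _small_candidates(seed=9, k=4)
    dup = DosageMatrix(cand.subjects, cand.variants + ["c00_copy"],
                       np.column_stack([cand.values, cand.column("c00")]))
    trace = stepwise_aic_select(dup, status)
    assert "c00_copy" in trace.dropped_collinear


def test_lrt_prune_drops_null_keeps_real():
    cand, status = _small_candidates(seed=11, n=600)
    selected = ["c00", "c01", "c05"]  # two real effects + one null
    final = lrt_prune(cand, selected, status, alpha=0.01)
    kept = {c.variant_id for c in final}
    assert {"c00", "c01"} <= kept
    assert "c05" not in kept
    with pytest.raises(SelectionError):
        lrt_prune(cand, [], status)


def test_prune_can_empty_model_with_warning():
    cand, status = _small_candidates(seed=13, n=500, n_effects=0)
    with pytest.warns(UserWarning, match="pruned"):
        final = lrt_prune(cand, ["c03"], status, alpha=0.01)
    assert final == []


def test_displacement_protection_is_not_selected():
    """A variable whose carriers are only displaced by risk haplotypes (no
    planted negative log-odds) must not survive selection + pruning, while a
    truly protective planted block must."""
    selected_false = 0
    selected_true = 0
    reps = 6
    for seed in range(reps):
        cfg = recovery_preset(seed=300 + seed,
                              effects={"B*08": np.log(4.3), "B*07": np.log(1.7),
                                       "C*06": np.log(2.5)})
        sim = simulate_cohort(cfg)
        matrix, descs = _hla_parts(sim)
        cand_ids = [d.variant_id for d in descs
                    if (d.category == "hla_allele"
                        and d.locus_or_region in ("A", "B", "C", "DRB3"))
                    or d.category == "haplotype_block"]
        trace = stepwise_aic_select(matrix.subset_variants(cand_ids), sim.status)
        final = {c.variant_id
                 for c in lrt_prune(matrix.subset_variants(cand_ids),
                                    trace.final_set, sim.status)} if trace.final_set else set()
        selected_false += "DRB1*04-DQB1*03" in final
        cfg2 = recovery_preset(seed=400 + seed)  # protective 0.4 really planted
        sim2 = simulate_cohort(cfg2)
        m2, d2 = _hla_parts(sim2)
        cand2 = [d.variant_id for d in d2
                 if (d.category == "hla_allele"
                     and d.locus_or_region in ("A", "B", "C", "DRB3"))
                 or d.category == "haplotype_block"]
        trace2 = stepwise_aic_select(m2.subset_variants(cand2), sim2.status)
        final2 = {c.variant_id
                  for c in lrt_prune(m2.subset_variants(cand2),
                                     trace2.final_set, sim2.status)}
        selected_true += "DRB1*04-DQB1*03" in final2
    assert selected_false <= 1
    assert selected_true >= reps - 1
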