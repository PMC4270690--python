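"""SNP quality control.

Two stages, mirroring standard practice for a genotyped-then-imputed panel:

1. genotyped-panel filters: per-SNP call rate >= 95%, minor allele frequency
   >= 1%, and an exact Hardy-Weinberg equilibrium test in controls at
   p >= 1e-4;
2. an imputation-quality filter where SNPs are stratified into three MAF bins
   (1-3%, 3-5%, >5%) and each bin's r^2 cutoff is set as low as possible
   subject to the mean r^2 of the retained SNPs exceeding 0.8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import DosageMatrix


class QCError(ValueError):
    pass


@dataclass
class QCThresholds:
    call_rate: float = 0.95   # fail if below
    maf: float = 0.01         # fail if below
    hwe_p: float = 1e-4       # fail if below, controls only


@dataclass
class QCRecord:
    variant_id: str
    call_rate: float
    maf: float
    hwe_p: float
    imputation_r2: float | None = None
    passed: bool = True
    fail_reason: str = "none"  # first failing filter: call_rate | maf | hwe | imputation_r2

    def __post_init__(self) -> None:
        if not (0 <= self.call_rate <= 1 and 0 <= self.maf <= 0.5):
            raise QCError(f"{self.variant_id}: call_rate/maf out of range")
        if (self.fail_reason == "none") != self.passed:
            raise QCError(f"{self.variant_id}: passed flag inconsistent with fail_reason")


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test on genotype counts.

    Two-sided exact p: the sum, over all heterozygote counts compatible
    with the observed allele totals, of probabilities no larger than that
    of the observed heterozygote count (probabilities conditional on the
    allele counts under random mating). A monomorphic sample has a single
    possible outcome and returns p = 1.
    """
    for v in (n_hom1, n_het, n_hom2):
        if v < 0 or v != int(v):
            raise QCError("genotype counts must be non-negative integers")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise QCError("all-zero genotype counts")
    rare = 2 * min(n_hom1, n_hom2) + n_het  # rare-allele count
    if rare == 0:
        return 1.0
    # heterozygote counts share the parity of the rare-allele count
    het_values = list(range(rare % 2, min(rare, 2 * n - rare) + 1, 2))
    # unnormalized conditional probabilities via the standard recurrence:
    # P(het+2)/P(het) = 4*hom_r*hom_c / ((het+2)*(het+1))
    logp = {het_values[0]: 0.0}
    for het in het_values[:-1]:
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        ratio = 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
        logp[het + 2] = logp[het] + math.log(ratio)
    mx = max(logp.values())
    probs = {h: math.exp(v - mx) for h, v in logp.items()}
    total = sum(probs.values())
    obs = probs[n_het]
    # tolerance guards equality under floating-point noise
    p = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


def genotyped_qc(
    matrix: DosageMatrix,
    status: np.ndarray,
    thresholds: QCThresholds | None = None,
) -> tuple[list[QCRecord], dict[str, int]]:
    """Apply the genotyped-panel filters to a hard-call dosage matrix.

    ``status`` is the per-subject 0/1 phenotype aligned with the matrix
    rows; HWE is computed in controls only. Each SNP's ``fail_reason``
    records the first failing filter in the order call_rate -> maf -> hwe.
    Returns the per-SNP records plus a pass/fail summary.
    """
    thresholds = thresholds or QCThresholds()
    status = np.asarray(status)
    if status.shape[0] != len(matrix.subjects):
        raise QCError("status vector does not match matrix subjects")
    controls = status == 0
    if not controls.any():
        raise QCError("no controls present: control HWE is undefined")
    records = []
    summary = {"pass": 0, "call_rate": 0, "maf": 0, "hwe": 0}
    for j, vid in enumerate(matrix.variants):
        col = matrix.values[:, j]
        seen = np.isfinite(col)
        hard = col[seen]
        if not np.isin(hard, (0.0, 1.0, 2.0)).all():
            raise QCError(f"{vid}: genotyped-panel QC requires hard calls in {{0,1,2}}")
        call_rate = seen.mean() if seen.size else 0.0
        af = hard.mean() / 2 if hard.size else 0.0
        maf = min(af, 1 - af)
        ctrl = col[controls & seen]
        counts = [int((ctrl == g).sum()) for g in (0.0, 1.0, 2.0)]
        hwe_p = hwe_exact_test(*counts) if sum(counts) else 1.0
        if call_rate < thresholds.call_rate:
            reason = "call_rate"
        elif maf < thresholds.maf:
            reason = "maf"
        elif hwe_p < thresholds.hwe_p:
            reason = "hwe"
        else:
            reason = "none"
        records.append(QCRecord(vid, call_rate, maf, hwe_p,
                                passed=reason == "none", fail_reason=reason))
        summary["pass" if reason == "none" else reason] += 1
    return records, summary


MAF_BINS: tuple[tuple[float, float], ...] = ((0.01, 0.03), (0.03, 0.05), (0.05, 0.5 + 1e-12))
#: half-open [low, high) bins; boundary MAFs (exactly 3%, 5%) join the upper bin.


@dataclass
class MafBinThresholds:
    """Per-MAF-bin r^2 cutoffs with the achieved mean r^2 of retained SNPs."""

    bins: tuple[tuple[float, float], ...] = MAF_BINS
    cutoffs: list[float | None] = field(default_factory=list)
    achieved_mean_r2: list[float | None] = field(default_factory=list)
    n_retained: list[int] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)  # empty / unattainable bins

    def bin_index(self, maf: float) -> int | None:
        for k, (lo, hi) in enumerate(self.bins):
            if lo <= maf < hi:
                return k
        return None


def maf_bin_thresholds(
    records: list[QCRecord],
    target_mean_r2: float = 0.8,
    mean_over_all: bool = False,
) -> MafBinThresholds:
    """Choose each MAF bin's r^2 cutoff.

    The cutoff is the smallest candidate (0 or an observed r^2 value) whose
    retained set (r^2 >= cutoff) has mean r^2 above ``target_mean_r2`` --
    i.e. the maximal retained set subject to the mean constraint. With
    ``mean_over_all`` the constraint is instead evaluated on all SNPs in
    the bin (an alternative reading of "average r^2 above 0.8"), in which
    case a bin either keeps everything or is unattainable.
    """
    out = MafBinThresholds()
    binned: list[list[float]] = [[] for _ in MAF_BINS]
    for rec in records:
        if rec.imputation_r2 is None:
            raise QCError(f"{rec.variant_id}: missing imputation r^2")
        if rec.maf < 0.01:
            raise QCError(f"{rec.variant_id}: MAF below 1% should be excluded upstream")
        k = out.bin_index(rec.maf)
        if k is not None:
            binned[k].append(rec.imputation_r2)
    for k, values in enumerate(binned):
        if not values:
            out.cutoffs.append(None)
            out.achieved_mean_r2.append(None)
            out.n_retained.append(0)
            out.flagged.append(f"bin{k + 1}:empty")
            continue
        if mean_over_all:
            mean_all = float(np.mean(values))
            if mean_all > target_mean_r2:
                out.cutoffs.append(0.0)
                out.achieved_mean_r2.append(mean_all)
                out.n_retained.append(len(values))
            else:
                out.cutoffs.append(None)
                out.achieved_mean_r2.append(None)
                out.n_retained.append(0)
                out.flagged.append(f"bin{k + 1}:unattainable")
            continue
        chosen = None
        for cut in sorted({0.0, *values}):
            retained = [v for v in values if v >= cut]
            if retained and np.mean(retained) > target_mean_r2:
                chosen = (cut, float(np.mean(retained)), len(retained))
                break
        if chosen is None:
            out.cutoffs.append(None)
            out.achieved_mean_r2.append(None)
            out.n_retained.append(0)
            out.flagged.append(f"bin{k + 1}:unattainable")
        else:
            out.cutoffs.append(chosen[0])
            out.achieved_mean_r2.append(chosen[1])
            out.n_retained.append(chosen[2])
    return out


def apply_imputation_filter(
    matrix: DosageMatrix,
    records: list[QCRecord],
    thresholds: MafBinThresholds,
) -> DosageMatrix:
    """Retain SNPs with MAF > 1% and r^2 at or above their bin's cutoff."""
    by_id = {r.variant_id: r for r in records}
    keep = []
    for vid in matrix.variants:
        rec = by_id.get(vid)
        if rec is None or rec.imputation_r2 is None or rec.maf <= 0.01:
            continue
        k = thresholds.bin_index(rec.maf)
        if k is None or thresholds.cutoffs[k] is None:
            continue
        if rec.imputation_r2 >= thresholds.cutoffs[k]:
            keep.append(vid)
    return matrix.subset_variants(keep)


def qc_report_frame(records: list[QCRecord]):
    """QC records as a tidy DataFrame (one row per SNP) for TSV export."""
    import pandas as pd

    return pd.DataFrame({
        "variant_id": [r.variant_id for r in records],
        "call_rate": [r.call_rate for r in records],
        "maf": [r.maf for r in records],
        "hwe_p": [r.hwe_p for r in records],
        "imputation_r2": [r.imputation_r2 for r in records],
        "passed": [int(r.passed) for r in records],
        "fail_reason": [r.fail_reason for r in records],
    })
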