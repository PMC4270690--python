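"""Synthetic case-control cohorts with MHC-like haplotype structure.

The generator draws each individual as two haplotypes from a declarative
pool of conserved multi-locus families (AH8.1-like, AH7.1-like, class II
risk/protective blocks, neutral fillers), applies a small per-interval
recombination leak so conserved haplotypes are mosaics rather than frozen
blocks, attaches SNP alleles through per-family emission probabilities
(tag SNPs in tunable LD with the class-I anchor, a perfectly-correlated
class III block that is independent of every HLA family, and null SNPs),
computes disease probability from a prospective logistic model over planted
per-copy log-odds effects, and then samples retrospectively until the target
case and control counts are reached. Retrospective sampling under a
logistic disease model preserves per-copy odds ratios, which is what makes
parameter-recovery testing against the planted truth meaningful.

All randomness flows from the config seed; nothing reads a clock.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import DosageMatrix, SubjectRecord, VariantDescriptor, allele_locus
from .encoding import AminoAcidTable, BlockDefinition, EpitopeTable, RESIDUE_NAMES, collate_allele
from .qc import QCRecord


class SimulationError(ValueError):
    pass


# genomic layout (build-37-like Mbp coordinates); CIII is the latent
# class III LD-block "locus" carried independently of the HLA families
SEGMENTS = ("A", "C", "B", "MICA", "CIII", "DRB3", "DRB1", "DQB1")
SEGMENT_POS = {
    "A": 29_910_000, "C": 31_240_000, "B": 31_320_000, "MICA": 31_400_000,
    "CIII": 32_193_000, "DRB3": 32_450_000, "DRB1": 32_550_000, "DQB1": 32_630_000,
}
_SEG_INDEX = {s: i for i, s in enumerate(SEGMENTS)}
_CIII = _SEG_INDEX["CIII"]


@dataclass(frozen=True)
class Haplotype:
    """One conserved multi-locus family: per-locus alleles and frequency.

    ``alleles['DRB3']`` may be None -- the DRB3 gene is only carried on a
    subset of DR haplotypes.
    """

    label: str
    alleles: dict[str, str | None]
    mica: str
    frequency: float


@dataclass(frozen=True)
class SNPSpec:
    """A SNP's allele-emission model: per-family Bernoulli rates, or an
    exact copy of the latent class III block allele (perfect within-block LD)."""

    variant_id: str
    position_bp: int
    emission: tuple[float, ...] | None = None  # per-family P(allele=1)
    copies_class3: bool = False


@dataclass
class HaplotypePool:
    haplotypes: list[Haplotype]
    snps: list[SNPSpec] = field(default_factory=list)
    class3_freq: float = 0.18
    recombination_leak: float = 0.01  # per adjacent-segment interval

    def __post_init__(self) -> None:
        total = sum(h.frequency for h in self.haplotypes)
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"haplotype frequencies sum to {total}, not 1")
        for h in self.haplotypes:
            for locus in ("A", "C", "B", "DRB1", "DQB1"):
                if not h.alleles.get(locus):
                    raise SimulationError(f"haplotype {h.label} missing {locus}")
            if "DRB3" not in h.alleles:
                raise SimulationError(f"haplotype {h.label} must set DRB3 (None=absent)")

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([h.frequency for h in self.haplotypes])


@dataclass
class SimulationConfig:
    pool: HaplotypePool
    effects: dict[str, float]       # variant id -> log-odds per copy
    intercept: float                # baseline log-odds of disease
    n_cases: int
    n_controls: int
    seed: int                       # mandatory; no wall-clock seeding
    max_population: int = 30_000_000

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise SimulationError("need at least one case and one control")
        if self.seed is None:
            raise SimulationError("a seed is mandatory")


@dataclass
class SimulatedCohort:
    records: list[SubjectRecord]
    snp_matrix: DosageMatrix
    snp_descriptors: list[VariantDescriptor]
    effects: dict[str, float]
    true_phases: dict[str, tuple[tuple[str, str], tuple[str, str]]]
    true_dosages: dict[str, np.ndarray]  # planted-variant dosage per subject
    population_case_rate: float          # MC estimate over screened draws

    @property
    def status(self) -> np.ndarray:
        return np.array([r.status for r in self.records])

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variant_id": list(self.effects),
            "beta": [self.effects[v] for v in self.effects],
            "odds_ratio": [math.exp(self.effects[v]) for v in self.effects],
        })


# ---------------------------------------------------------------------------
# effect-variable lookups (indicator of a variant on a single haplotype)
# ---------------------------------------------------------------------------

def _family_lookups(pool: HaplotypePool, effects: dict[str, float]):
    """Per-effect lookup structures evaluated on realized gametes.

    Returns a list of (beta, kind, payload) where kind is ``segment``
    (payload: segment index + per-family 0/1 vector), ``block``
    (payload: FxF indicator over (DRB1, DQB1) family pairs) or ``class3``.
    """
    defs = BlockDefinition.packaged()
    aa = AminoAcidTable.packaged()
    epi = EpitopeTable.packaged()
    fams = pool.haplotypes
    snp_ids = {s.variant_id: s for s in pool.snps}
    out = []
    for vid, beta in effects.items():
        if vid in snp_ids:
            if not snp_ids[vid].copies_class3:
                raise SimulationError(
                    f"effect on SNP {vid}: only class III block SNPs support effects"
                )
            out.append((beta, "class3", None))
            continue
        if "-DQB1" in vid:  # haplotype-block label
            M = np.zeros((len(fams), len(fams)))
            for i, hi in enumerate(fams):
                for j, hj in enumerate(fams):
                    if defs.match(hi.alleles["DRB1"], hj.alleles["DQB1"]) == vid:
                        M[i, j] = 1.0
            out.append((beta, "block", M))
            continue
        if vid[:-2] in RESIDUE_NAMES.values() and vid[-2:] in ("37", "86"):
            pos = int(vid[-2:])
            ind = np.array([
                1.0 if RESIDUE_NAMES[aa.residues[(h.alleles["DRB1"], pos)]] + vid[-2:] == vid
                else 0.0
                for h in fams
            ])
            out.append((beta, "segment", (_SEG_INDEX["DRB1"], ind)))
            continue
        if vid in ("Bw4", "Bw6", "C1", "C2"):
            locus = "B" if vid.startswith("B") else "C"
            mapping = epi.b_epitope if locus == "B" else epi.c_epitope
            ind = np.array([1.0 if mapping[h.alleles[locus]] == vid else 0.0 for h in fams])
            out.append((beta, "segment", (_SEG_INDEX[locus], ind)))
            continue
        if vid == "MICA5.1":
            ind = np.array([
                1.0 if epi.mica_class[h.mica] == "MICA5.1" else 0.0 for h in fams
            ])
            out.append((beta, "segment", (_SEG_INDEX["MICA"], ind)))
            continue
        if "*" in vid:
            locus = allele_locus(vid)
            level = "four_digit" if ":" in vid else "two_digit"
            ind = np.array([
                1.0 if h.alleles[locus] and collate_allele(h.alleles[locus], level) == vid
                else 0.0
                for h in fams
            ])
            out.append((beta, "segment", (_SEG_INDEX[locus], ind)))
            continue
        raise SimulationError(f"cannot interpret effect variant {vid!r}")
    return out


def _effect_dosages(lookups, fam1, fam2, c31, c32) -> list[np.ndarray]:
    doses = []
    for _, kind, payload in lookups:
        if kind == "class3":
            doses.append(c31 + c32.astype(float))
        elif kind == "segment":
            seg, ind = payload
            doses.append(ind[fam1[:, seg]] + ind[fam2[:, seg]])
        else:  # block
            M = payload
            d6, d7 = _SEG_INDEX["DRB1"], _SEG_INDEX["DQB1"]
            doses.append(M[fam1[:, d6], fam1[:, d7]] + M[fam2[:, d6], fam2[:, d7]])
    return doses


def _draw_gametes(pool: HaplotypePool, n: int, rng: np.random.Generator):
    """Draw n individuals' two mosaic haplotypes.

    Returns per-gamete (n, S) family-index arrays plus the class III latent
    alleles; a crossover in interval i (probability = recombination leak)
    swaps all downstream segments between the two gametes.
    """
    S = len(SEGMENTS)
    freqs = pool.frequencies
    h1 = rng.choice(len(freqs), size=n, p=freqs)
    h2 = rng.choice(len(freqs), size=n, p=freqs)
    c1 = rng.random(n) < pool.class3_freq
    c2 = rng.random(n) < pool.class3_freq
    swaps = rng.random((n, S - 1)) < pool.recombination_leak
    crossed = np.cumsum(swaps, axis=1) % 2 == 1  # state after interval i
    fam1 = np.tile(h1[:, None], (1, S))
    fam2 = np.tile(h2[:, None], (1, S))
    for s in range(1, S):
        cross = crossed[:, s - 1]
        fam1[cross, s], fam2[cross, s] = h2[cross], h1[cross]
    c31 = np.where(crossed[:, _CIII - 1], c2, c1)
    c32 = np.where(crossed[:, _CIII - 1], c1, c2)
    return fam1, fam2, c31.astype(float), c32.astype(float)


def simulate_population(
    config: SimulationConfig, n: int, rng: np.random.Generator | None = None
):
    """Draw n individuals prospectively; returns (fam1, fam2, c31, c32, y)."""
    rng = rng or np.random.default_rng(config.seed)
    lookups = _family_lookups(config.pool, config.effects)
    fam1, fam2, c31, c32 = _draw_gametes(config.pool, n, rng)
    lp = np.full(n, config.intercept, dtype=float)
    for (beta, _, _), dose in zip(lookups, _effect_dosages(lookups, fam1, fam2, c31, c32)):
        lp += beta * dose
    y = rng.random(n) < expit(lp)
    return fam1, fam2, c31, c32, y


def _materialize(
    config: SimulationConfig,
    rng: np.random.Generator,
    fam1: np.ndarray, fam2: np.ndarray, c31: np.ndarray, c32: np.ndarray,
    status: np.ndarray,
    population_case_rate: float,
) -> SimulatedCohort:
    pool = config.pool
    fams = pool.haplotypes
    n = fam1.shape[0]
    ids = []
    n_case = n_ctrl = 0
    for s in status:
        if s == 1:
            n_case += 1
            ids.append(f"case_{n_case:04d}")
        else:
            n_ctrl += 1
            ids.append(f"ctrl_{n_ctrl:04d}")

    records = []
    phases = {}
    for i in range(n):
        hla: dict[str, tuple[str, ...]] = {}
        for locus in ("A", "C", "B", "DRB3", "DRB1", "DQB1"):
            seg = _SEG_INDEX[locus]
            calls = []
            for fam in (fam1[i, seg], fam2[i, seg]):
                allele = fams[fam].alleles[locus]
                if allele is not None:
                    calls.append(allele)
            hla[locus] = tuple(calls)
        seg = _SEG_INDEX["MICA"]
        hla["MICA"] = (fams[fam1[i, seg]].mica, fams[fam2[i, seg]].mica)
        records.append(SubjectRecord(ids[i], int(status[i]), hla))
        d6, d7 = _SEG_INDEX["DRB1"], _SEG_INDEX["DQB1"]
        phases[ids[i]] = (
            (fams[fam1[i, d6]].alleles["DRB1"], fams[fam1[i, d7]].alleles["DQB1"]),
            (fams[fam2[i, d6]].alleles["DRB1"], fams[fam2[i, d7]].alleles["DQB1"]),
        )

    seg_positions = np.array([SEGMENT_POS[s] for s in SEGMENTS])
    columns = []
    descriptors = []
    for spec in pool.snps:
        seg = int(np.searchsorted(seg_positions, spec.position_bp, side="right") - 1)
        seg = max(seg, 0)
        if spec.copies_class3:
            a1, a2 = c31, c32
        else:
            em = np.asarray(spec.emission)
            a1 = (rng.random(n) < em[fam1[:, seg]]).astype(float)
            a2 = (rng.random(n) < em[fam2[:, seg]]).astype(float)
        columns.append(a1 + a2)
        descriptors.append(VariantDescriptor(
            spec.variant_id, "snp", "chr6", spec.position_bp, "copies of allele 1"
        ))
    values = np.column_stack(columns) if columns else np.empty((n, 0))
    matrix = DosageMatrix(ids, [s.variant_id for s in pool.snps], values)

    lookups = _family_lookups(pool, config.effects)
    doses = _effect_dosages(lookups, fam1, fam2, c31, c32)
    true_dosages = {vid: d for vid, d in zip(config.effects, doses)}
    return SimulatedCohort(records, matrix, descriptors, dict(config.effects),
                           phases, true_dosages, population_case_rate)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Retrospective case-control sampling from the prospective disease model.

    Individuals are screened in seeded batches until the configured case and
    control counts are reached; exceeding ``max_population`` screened
    individuals raises (an intercept so low that cases are vanishingly rare).
    """
    rng = np.random.default_rng(config.seed)
    need_case, need_ctrl = config.n_cases, config.n_controls
    got_case = got_ctrl = 0
    parts: list[tuple] = []
    screened = 0
    cases_seen = 0
    batch = 200_000
    while got_case < need_case or got_ctrl < need_ctrl:
        if screened >= config.max_population:
            raise SimulationError(
                f"attempt cap: screened {screened} individuals and found only "
                f"{got_case}/{need_case} cases; raise the intercept"
            )
        fam1, fam2, c31, c32, y = simulate_population(config, batch, rng)
        screened += batch
        cases_seen += int(y.sum())
        take = np.zeros(batch, dtype=bool)
        case_idx = np.flatnonzero(y)[: need_case - got_case]
        ctrl_idx = np.flatnonzero(~y)[: need_ctrl - got_ctrl]
        take[case_idx] = True
        take[ctrl_idx] = True
        got_case += len(case_idx)
        got_ctrl += len(ctrl_idx)
        parts.append((fam1[take], fam2[take], c31[take], c32[take], y[take]))
        rate = max(cases_seen / screened, 1e-7)
        still = need_case - got_case
        if still > 0:
            batch = int(min(2_000_000, max(100_000, 1.3 * still / rate)))
    fam1 = np.concatenate([p[0] for p in parts])
    fam2 = np.concatenate([p[1] for p in parts])
    c31 = np.concatenate([p[2] for p in parts])
    c32 = np.concatenate([p[3] for p in parts])
    y = np.concatenate([p[4] for p in parts]).astype(int)
    # stable order: cases first, then controls
    order = np.concatenate([np.flatnonzero(y == 1), np.flatnonzero(y == 0)])
    return _materialize(config, rng, fam1[order], fam2[order], c31[order],
                        c32[order], y[order], cases_seen / screened)


# ---------------------------------------------------------------------------
# imputation-noise overlay
# ---------------------------------------------------------------------------

def add_imputation_noise(
    matrix: DosageMatrix,
    target_r2,
    seed: int,
    tolerance: float = 0.03,
) -> tuple[DosageMatrix, dict[str, float]]:
    """Blur hard calls into fractional dosages with a target imputation r^2.

    ``target_r2`` is a scalar or a per-MAF-bin mapping ``{(lo, hi): r2}``.
    Per SNP the noisy dosage is the hard call plus Gaussian noise truncated
    to [0, 2], with the noise scale bisected so the realized squared
    correlation with the truth matches the bin target (within *tolerance*;
    checked when n >= 1000, where the calibration is reliable). A target of
    1 returns the column unchanged. Returns the fractional matrix and the
    realized per-SNP r^2.
    """
    rng = np.random.default_rng(seed)
    n = len(matrix.subjects)
    values = matrix.values.copy()
    realized: dict[str, float] = {}

    def target_for(maf: float) -> float:
        if np.isscalar(target_r2):
            return float(target_r2)
        for (lo, hi), t in target_r2.items():
            if lo <= maf < hi:
                return float(t)
        raise SimulationError(f"no imputation-noise target for MAF {maf:.4f}")

    for j, vid in enumerate(matrix.variants):
        x = matrix.values[:, j]
        ok = np.isfinite(x)
        af = x[ok].mean() / 2 if ok.any() else 0.0
        maf = min(af, 1 - af)
        t = target_for(maf)
        if not 0 < t <= 1:
            raise SimulationError(f"{vid}: target r^2 must be in (0,1]")
        if t == 1.0 or x[ok].std() == 0:
            realized[vid] = 1.0
            continue
        eps = rng.standard_normal(n)

        def realized_r2(sigma: float) -> float:
            y = np.clip(x + sigma * eps, 0, 2)
            r = np.corrcoef(x[ok], y[ok])[0, 1]
            return r * r

        lo_s, hi_s = 1e-4, 0.05
        while realized_r2(hi_s) > t and hi_s < 64:
            hi_s *= 2
        if realized_r2(hi_s) > t:
            raise SimulationError(f"{vid}: target r^2 {t} unachievable")
        sigma = brentq(lambda s: realized_r2(s) - t, lo_s, hi_s, xtol=1e-5)
        got = realized_r2(sigma)
        if n >= 1000 and abs(got - t) > tolerance:
            raise SimulationError(
                f"{vid}: calibration missed target {t} (realized {got:.3f})"
            )
        values[:, j] = np.clip(x + sigma * eps, 0, 2)
        realized[vid] = float(got)
    return DosageMatrix(matrix.subjects, matrix.variants, values), realized


# ---------------------------------------------------------------------------
# deterministic QC fixture: 471 genotyped SNPs, 66 planted violations
# ---------------------------------------------------------------------------

def qc_fixture() -> tuple[DosageMatrix, np.ndarray, pd.DataFrame]:
    """Deterministic genotyped panel: 405 clean SNPs + 66 single-filter violators.

    Violations: 30 SNPs with call rate ~92% (<95%), 20 with MAF ~0.5% (<1%),
    16 with a complete heterozygote deficit in controls (exact HWE p << 1e-4)
    at MAF ~20%. Genotype counts are rounded Hardy-Weinberg expectations, so
    the construction is arithmetic and byte-identical across runs. Returns
    (matrix, status, manifest of intended fail reasons); 365 cases precede
    368 controls.
    """
    n_case, n_ctrl = 365, 368
    n = n_case + n_ctrl
    status = np.array([1] * n_case + [0] * n_ctrl)

    def hwe_column(p: float, n_sub: int) -> np.ndarray:
        het = round(2 * p * (1 - p) * n_sub)
        hom2 = round(p * p * n_sub)
        hom1 = n_sub - het - hom2
        return np.array([0.0] * hom1 + [1.0] * het + [2.0] * hom2)

    columns, ids, reasons = [], [], []

    def add(vid: str, case_col: np.ndarray, ctrl_col: np.ndarray, reason: str) -> None:
        ids.append(vid)
        reasons.append(reason)
        columns.append(np.concatenate([case_col, ctrl_col]))

    for i in range(405):
        p = 0.05 + 0.45 * (i / 404)
        add(f"qc_clean_{i + 1:03d}", hwe_column(p, n_case), hwe_column(p, n_ctrl), "none")
    for i in range(30):
        p = 0.10 + 0.01 * i
        col = np.concatenate([hwe_column(p, n_case), hwe_column(p, n_ctrl)])
        col[: int(0.08 * n)] = np.nan  # 8% missing -> call rate 92%
        ids.append(f"qc_lowcall_{i + 1:02d}")
        reasons.append("call_rate")
        columns.append(col)
    for i in range(20):
        add(f"qc_rare_{i + 1:02d}", hwe_column(0.005, n_case),
            hwe_column(0.005, n_ctrl), "maf")
    for i in range(16):
        p = 0.15 + 0.005 * i
        minor = round(2 * p * n_ctrl)
        hom2 = minor // 2
        het = minor - 2 * hom2
        ctrl = np.array([0.0] * (n_ctrl - het - hom2) + [1.0] * het + [2.0] * hom2)
        add(f"qc_hwe_{i + 1:02d}", hwe_column(p, n_case), ctrl, "hwe")

    matrix = DosageMatrix([f"case_{i + 1:04d}" for i in range(n_case)]
                          + [f"ctrl_{i + 1:04d}" for i in range(n_ctrl)],
                          ids, np.column_stack(columns))
    manifest = pd.DataFrame({"variant_id": ids, "intended_fail_reason": reasons})
    return matrix, status, manifest


def imputation_qc_records(seed: int = 0, n_per_bin: int = 120) -> list[QCRecord]:
    """Synthetic per-SNP imputation-quality records across the three MAF bins,
    with r^2 drawn so that each bin needs a non-trivial cutoff to reach a
    retained-set mean above 0.8 (low-MAF SNPs impute worse)."""
    rng = np.random.default_rng(seed)
    records = []
    for k, (lo, hi, loc) in enumerate([(0.01, 0.03, 0.62), (0.03, 0.05, 0.72),
                                       (0.05, 0.5, 0.82)]):
        for i in range(n_per_bin):
            maf = rng.uniform(lo, min(hi, 0.5))
            r2 = float(np.clip(rng.normal(loc, 0.18), 0.02, 1.0))
            records.append(QCRecord(f"imp_bin{k + 1}_{i:03d}", 1.0, maf, 1.0,
                                    imputation_r2=r2))
    return records


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

# (label, freq, A, C, B, DRB3 (None = gene absent), DRB1, DQB1, MICA)
_FAMILIES = [
    ("AH8.1",     "A*01:01", "C*07:01", "B*08:01", "DRB3*01:01", "DRB1*03:01", "DQB1*02:01", "MICA*008"),
    ("B8-DR1",    "A*02:01", "C*07:01", "B*08:01", None,         "DRB1*01:01", "DQB1*05:01", "MICA*008"),
    ("DR13:01",   "A*02:01", "C*03:04", "B*40:01", "DRB3*02:02", "DRB1*13:01", "DQB1*06:03", "MICA*004"),
    ("DR4-DQ301", "A*02:01", "C*05:01", "B*44:02", None,         "DRB1*04:01", "DQB1*03:01", "MICA*004"),
    ("DR4-DQ302", "A*03:01", "C*03:03", "B*15:01", None,         "DRB1*04:04", "DQB1*03:02", "MICA*009"),
    ("AH7.1",     "A*03:01", "C*07:02", "B*07:02", None,         "DRB1*15:01", "DQB1*06:02", "MICA*009"),
    ("AH7.1b",    "A*02:01", "C*07:02", "B*07:02", None,         "DRB1*15:01", "DQB1*06:02", "MICA*009"),
    ("DR13:02",   "A*24:02", "C*04:01", "B*35:01", "DRB3*03:01", "DRB1*13:02", "DQB1*06:04", "MICA*004"),
    ("DR7-DQ303", "A*29:02", "C*16:01", "B*44:03", None,         "DRB1*07:01", "DQB1*03:03", "MICA*004"),
    ("C6-B57",    "A*02:01", "C*06:02", "B*57:01", None,         "DRB1*07:01", "DQB1*02:02", "MICA*002"),
    ("DR11",      "A*02:01", "C*07:02", "B*18:01", "DRB3*02:02", "DRB1*11:01", "DQB1*03:01", "MICA*008"),
    ("DR11b",     "A*02:01", "C*03:03", "B*15:01", "DRB3*02:02", "DRB1*11:01", "DQB1*03:01", "MICA*004"),
    ("DR8",       "A*23:01", "C*04:01", "B*44:03", None,         "DRB1*08:01", "DQB1*04:02", "MICA*009"),
    ("DR1-A11",   "A*11:01", "C*04:01", "B*35:01", None,         "DRB1*01:01", "DQB1*05:01", "MICA*004"),
    ("DR1-A3",    "A*03:01", "C*04:01", "B*35:01", None,         "DRB1*01:01", "DQB1*05:01", "MICA*008"),
    ("DR12",      "A*24:02", "C*03:03", "B*15:01", "DRB3*01:01", "DRB1*12:01", "DQB1*03:01", "MICA*009"),
    ("DR10",      "A*03:01", "C*15:02", "B*51:01", None,         "DRB1*10:01", "DQB1*05:01", "MICA*004"),
    ("DR13:03",   "A*30:01", "C*05:01", "B*44:02", "DRB3*01:01", "DRB1*13:03", "DQB1*03:01", "MICA*009"),
    ("DR14:02",   "A*24:02", "C*03:04", "B*40:01", "DRB3*02:02", "DRB1*14:02", "DQB1*05:03", "MICA*004"),
    ("DR9",       "A*24:02", "C*12:03", "B*18:01", None,         "DRB1*09:01", "DQB1*03:03", "MICA*009"),
    ("DR16",      "A*01:01", "C*15:02", "B*51:01", None,         "DRB1*16:01", "DQB1*05:02", "MICA*004"),
    ("DR15:02",   "A*11:01", "C*12:03", "B*18:01", None,         "DRB1*15:02", "DQB1*06:01", "MICA*009"),
]

#: cohort-frequency vector emulating a Scandinavian population: a common
#: AH8.1, an AH7.1 pair totalling 8% B*07, a 5.5% DRB1*13:01-DQB1*06:03
#: haplotype, 14% DRB1*04-DQB1*03, and rare protective blocks whose
#: frequencies are consistent with the wide multivariate CIs they produce.
_STUDY_FREQS = {
    "AH8.1": 0.105, "B8-DR1": 0.030, "DR13:01": 0.055, "DR4-DQ301": 0.080,
    "DR4-DQ302": 0.060, "AH7.1": 0.075, "AH7.1b": 0.005, "DR13:02": 0.015,
    "DR7-DQ303": 0.005, "C6-B57": 0.020, "DR11": 0.120, "DR11b": 0.080,
    "DR8": 0.030, "DR1-A11": 0.100, "DR1-A3": 0.100, "DR12": 0.040,
    "DR10": 0.020, "DR13:03": 0.010, "DR14:02": 0.010, "DR9": 0.010,
    "DR16": 0.020, "DR15:02": 0.010,
}

#: planted per-copy odds ratios for the study preset
STUDY_EFFECTS = {
    "B*08": math.log(4.3),
    "B*07": math.log(1.7),
    "C*06": math.log(2.5),
    "DRB1*13:01-DQB1*06:03": math.log(4.9),
    "DRB1*04-DQB1*03": math.log(0.4),
    "DRB1*07:01-DQB1*03:03": math.log(0.1),
    "DRB1*13:XX-DQB1*06": math.log(0.3),
    "cIII_tag": math.log(2.32),
}


def _haplotypes(freqs: dict[str, float]) -> list[Haplotype]:
    out = []
    for label, a, c, b, drb3, drb1, dqb1, mica in _FAMILIES:
        out.append(Haplotype(label, {
            "A": a, "C": c, "B": b, "DRB3": drb3, "DRB1": drb1, "DQB1": dqb1,
        }, mica, freqs.get(label, 0.0)))
    return out


def _background_rate_for_r2(p_anchor: float, a: float, target: float) -> float:
    """Background emission b so a binary SNP tags the anchor set at target r^2."""
    def r2_of(b: float) -> float:
        pb = p_anchor * a + (1 - p_anchor) * b
        d = p_anchor * (1 - p_anchor) * (a - b)
        return d * d / (p_anchor * (1 - p_anchor) * pb * (1 - pb))

    if r2_of(0.0) < target:
        raise SimulationError(f"target r^2 {target} unreachable with emission {a}")
    return float(brentq(lambda b: r2_of(b) - target, 0.0, a - 1e-9, xtol=1e-12))


_TAG_POSITIONS = [31_000_000, 31_150_000, 31_280_000, 31_350_000, 31_500_000,
                  31_800_000, 32_100_000, 32_300_000, 32_450_000, 32_600_000]
# the class III LD block spans the 1.6 kb region the tag SNP sits in
_CIII_POSITIONS = [32_193_220, 32_193_492, 32_193_765, 32_194_037,
                   32_194_310, 32_194_582, 32_194_854]


def _study_snps(haplotypes: list[Haplotype], n_null: int = 103) -> list[SNPSpec]:
    F = len(haplotypes)
    anchor = np.array([1.0 if h.alleles["B"].startswith("B*08") else 0.0
                       for h in haplotypes])
    p_anchor = float(sum(h.frequency for h, a in zip(haplotypes, anchor) if a))
    snps: list[SNPSpec] = []
    # tag SNPs: r^2 with the B*08 anchor decays with distance from HLA-B
    b_pos = SEGMENT_POS["B"]
    order = np.argsort([abs(p - b_pos) for p in _TAG_POSITIONS])
    targets = np.linspace(0.83, 0.43, len(_TAG_POSITIONS))
    tag_r2 = np.empty(len(_TAG_POSITIONS))
    tag_r2[order] = targets
    for i, (pos, t) in enumerate(zip(_TAG_POSITIONS, tag_r2)):
        a = 0.98
        b = _background_rate_for_r2(p_anchor, a, t)
        emission = tuple(np.where(anchor == 1, a, b))
        snps.append(SNPSpec(f"tagB8_{i + 1:02d}", pos, emission))
    for i, pos in enumerate(_CIII_POSITIONS):
        vid = "cIII_tag" if i == 0 else f"cIII_{i + 1}"
        snps.append(SNPSpec(vid, pos, None, copies_class3=True))
    # null SNPs: family-independent frequencies on a deterministic grid
    for i in range(n_null):
        pos = 29_600_000 + int(i * 3_500_000 / max(n_null - 1, 1))
        q = 0.05 + 0.4 * ((i * 37) % n_null) / n_null
        snps.append(SNPSpec(f"null_{i + 1:03d}", pos, (q,) * F))
    return snps


def study_preset(seed: int, n_cases: int = 365, n_controls: int = 368) -> SimulationConfig:
    """The default study conditions: 365/368 Scandinavian-style cohort.

    Nine signal-bearing haplotype families plus neutral fillers; planted
    per-copy odds ratios 4.3 (B*08), 1.7 (B*07), 2.5 (C*06), 4.9
    (DRB1*13:01-DQB1*06:03), 0.4, 0.1 and 0.3 (protective class II blocks)
    and 2.32 (class III tag SNP, independent of every HLA family); baseline
    prevalence 1/10,000.
    """
    haplotypes = _haplotypes(_STUDY_FREQS)
    pool = HaplotypePool(haplotypes, _study_snps(haplotypes), class3_freq=0.18)
    return SimulationConfig(
        pool=pool,
        effects=dict(STUDY_EFFECTS),
        intercept=float(np.log(1e-4 / (1 - 1e-4))),
        n_cases=n_cases,
        n_controls=n_controls,
        seed=seed,
    )


#: parameter-recovery pool: every planted variable (B*08, B*07, C*06, the
#: DRB1*04-DQB1*03 and DRB1*13:XX-DQB1*06 blocks) spans several families with
#: mixed backgrounds, so no candidate column is a strong proxy of a planted one
_RECOVERY_FAMILIES = [
    ("r01", 0.05, "A*01:01", "C*07:01", "B*08:01", None,         "DRB1*01:01", "DQB1*05:01", "MICA*008"),
    ("r02", 0.05, "A*02:01", "C*04:01", "B*08:01", "DRB3*02:02", "DRB1*11:01", "DQB1*03:01", "MICA*004"),
    ("r03", 0.03, "A*03:01", "C*03:03", "B*08:01", "DRB3*01:01", "DRB1*03:01", "DQB1*02:01", "MICA*008"),
    ("r04", 0.08, "A*02:01", "C*07:01", "B*07:02", None,         "DRB1*15:01", "DQB1*06:02", "MICA*009"),
    ("r05", 0.08, "A*03:01", "C*05:01", "B*07:02", None,         "DRB1*01:01", "DQB1*05:01", "MICA*004"),
    ("r06", 0.08, "A*24:02", "C*03:03", "B*07:02", None,         "DRB1*04:01", "DQB1*03:01", "MICA*009"),
    ("r07", 0.05, "A*02:01", "C*06:02", "B*57:01", None,         "DRB1*07:01", "DQB1*02:02", "MICA*002"),
    ("r08", 0.05, "A*24:02", "C*06:02", "B*35:01", None,         "DRB1*01:01", "DQB1*05:01", "MICA*004"),
    ("r09", 0.05, "A*01:01", "C*05:01", "B*44:02", None,         "DRB1*04:01", "DQB1*03:01", "MICA*008"),
    ("r10", 0.06, "A*03:01", "C*05:01", "B*57:01", None,         "DRB1*04:04", "DQB1*03:02", "MICA*009"),
    ("r11", 0.06, "A*02:01", "C*04:01", "B*35:01", "DRB3*03:01", "DRB1*13:02", "DQB1*06:04", "MICA*004"),
    ("r12", 0.06, "A*24:02", "C*03:03", "B*15:01", "DRB3*02:02", "DRB1*13:02", "DQB1*06:04", "MICA*009"),
    ("r13", 0.06, "A*01:01", "C*04:01", "B*15:01", "DRB3*03:01", "DRB1*11:01", "DQB1*03:01", "MICA*004"),
    ("r14", 0.13, "A*03:01", "C*03:03", "B*35:01", None,         "DRB1*07:01", "DQB1*02:02", "MICA*008"),
    ("r15", 0.04, "A*24:02", "C*03:03", "B*15:01", "DRB3*01:01", "DRB1*03:01", "DQB1*02:01", "MICA*009"),
    ("r16", 0.07, "A*01:01", "C*04:01", "B*44:02", None,         "DRB1*15:01", "DQB1*06:02", "MICA*004"),
]

RECOVERY_EFFECTS = {
    "B*08": math.log(4.3),
    "B*07": math.log(1.7),
    "C*06": math.log(2.5),
    "DRB1*04-DQB1*03": math.log(0.4),
    "DRB1*13:XX-DQB1*06": math.log(0.3),
}


def recovery_preset(
    seed: int,
    n_cases: int = 600,
    n_controls: int = 600,
    effects: dict[str, float] | None = None,
) -> SimulationConfig:
    """Parameter-recovery conditions: identifiable planted variables, prevalence 5%.

    Uses a dedicated low-confounding pool (each planted variable spans
    several families, no strong proxies among candidate columns) and a high
    recombination leak so class I decorrelates from class II.
    Retrospective sampling leaves per-copy odds ratios invariant to the
    intercept, so the moderate prevalence only speeds up case accrual
    without changing what is being estimated.
    """
    haplotypes = [
        Haplotype(label, {"A": a, "C": c, "B": b, "DRB3": drb3,
                          "DRB1": drb1, "DQB1": dqb1}, mica, freq)
        for (label, freq, a, c, b, drb3, drb1, dqb1, mica) in _RECOVERY_FAMILIES
    ]
    pool = HaplotypePool(haplotypes, [], class3_freq=0.18, recombination_leak=0.12)
    return SimulationConfig(
        pool=pool,
        effects=dict(RECOVERY_EFFECTS if effects is None else effects),
        intercept=float(np.log(0.05 / 0.95)),
        n_cases=n_cases,
        n_controls=n_controls,
        seed=seed,
    )


def null_preset(
    seed: int, n_cases: int = 200, n_controls: int = 200, n_snps: int = 50
) -> SimulationConfig:
    """No planted effects: 50 family-independent SNPs for type-I calibration."""
    haplotypes = _haplotypes(_STUDY_FREQS)
    F = len(haplotypes)
    snps = []
    for i in range(n_snps):
        pos = 29_700_000 + i * 60_000
        q = 0.10 + 0.35 * (i % 10) / 9
        snps.append(SNPSpec(f"nullcal_{i + 1:03d}", pos, (q,) * F))
    pool = HaplotypePool(haplotypes, snps, class3_freq=0.18)
    return SimulationConfig(
        pool=pool, effects={}, intercept=float(np.log(0.3 / 0.7)),
        n_cases=n_cases, n_controls=n_controls, seed=seed,
    )


def category_count_fixture(n_subjects: int = 8):
    """Dosage parts with the study's variable-category sizes.

    18,644 SNPs + 95 HLA alleles + 20 DRB1-DQB1 blocks + 7 amino-acid
    residues + 4 KIR epitopes + MICA5.1; values are arbitrary dosages (the
    fixture exists to exercise manifest assembly and the family-wise
    threshold, not association).
    """
    rng = np.random.default_rng(12345)
    subjects = [f"s{i + 1:02d}" for i in range(n_subjects)]

    def part(ids: list[str], category: str, positions=None):
        vals = rng.uniform(0, 2, size=(n_subjects, len(ids)))
        descs = [
            VariantDescriptor(v, category, "chr6",
                              positions[k] if positions else 0, "")
            for k, v in enumerate(ids)
        ]
        return DosageMatrix(subjects, ids, vals), descs

    snp_ids = [f"fix_snp_{i + 1:05d}" for i in range(18_644)]
    snp_pos = [29_600_000 + i * 240 for i in range(18_644)]
    hla_ids = [f"fix_hla_{i + 1:03d}" for i in range(95)]
    block_ids = [f"fix_block_{i + 1:02d}" for i in range(20)]
    aa_ids = ["Asn37", "Leu37", "Phe37", "Ser37", "Tyr37", "Gly86", "Val86"]
    kir_ids = ["Bw4", "Bw6", "C1", "C2"]
    return [
        part(snp_ids, "snp", snp_pos),
        part(hla_ids, "hla_allele"),
        part(block_ids, "haplotype_block"),
        part(aa_ids, "amino_acid"),
        part(kir_ids, "kir_epitope"),
        part(["MICA5.1"], "mica"),
    ]
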