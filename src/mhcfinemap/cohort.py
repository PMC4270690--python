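"""Cohort data model and file I/O.

The study container is a list of :class:`SubjectRecord` (case/control status
plus HLA typings) joined against a :class:`DosageMatrix` of additively coded
variables, where every tested variable -- SNP, classical HLA allele,
DRB1-DQB1 haplotype block, DR-beta amino acid, MICA5.1 or KIR epitope -- is a
column of per-subject allele-copy counts in [0, 2] (fractional after
imputation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HLA_LOCI = ("A", "C", "B", "DRB3", "DRB1", "DQB1")

#: variable taxonomy; fixed vocabulary
CATEGORIES = ("snp", "hla_allele", "haplotype_block", "amino_acid", "mica", "kir_epitope")

_ALLELE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)\*(\d+)(?::(\d+))?$")


class CohortError(ValueError):
    """Malformed cohort input (bad allele string, duplicate id, bad status...)."""


def normalize_allele(raw: str, locus: str | None = None) -> str:
    """Normalize an HLA allele string to ``LOCUS*FF`` or ``LOCUS*FF:FF``.

    Locus is uppercased and numeric fields are zero-padded to two digits,
    so ``a*1:1`` becomes ``A*01:01``. If *locus* is given, the allele's
    locus must match it (case-insensitively).
    """
    m = _ALLELE_RE.match(raw.strip())
    if m is None:
        raise CohortError(f"malformed HLA allele string: {raw!r}")
    loc, f1, f2 = m.group(1).upper(), m.group(2), m.group(3)
    if locus is not None and loc != locus.upper():
        raise CohortError(f"allele {raw!r} does not belong to locus {locus}")

    def pad(f: str) -> str:
        # zero-pad to two digits; wider fields (e.g. MICA*008) keep their width
        return f"{int(f):0{max(2, len(f))}d}"

    out = f"{loc}*{pad(f1)}"
    if f2 is not None:
        out += f":{pad(f2)}"
    return out


def allele_locus(allele: str) -> str:
    m = _ALLELE_RE.match(allele)
    if m is None:
        raise CohortError(f"malformed HLA allele string: {allele!r}")
    return m.group(1).upper()


@dataclass
class SubjectRecord:
    """One study subject: id, binary phenotype and HLA typings.

    ``hla`` maps locus name to an unordered tuple of 0-2 allele strings.
    An empty tuple at DRB3 is a legitimate state: the DRB3 gene is only
    carried on a subset of DR haplotypes, and its absence contributes
    dosage 0 to every DRB3 allele variable.
    """

    subject_id: str
    status: int
    hla: dict[str, tuple[str, ...]] = field(default_factory=dict)
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in (0, 1):
            raise CohortError(
                f"subject {self.subject_id}: status must be 0 or 1, got {self.status!r}"
            )
        for locus, alleles in self.hla.items():
            if len(alleles) > 2:
                raise CohortError(
                    f"subject {self.subject_id}: locus {locus} has more than two calls"
                )


@dataclass(frozen=True)
class VariantDescriptor:
    """Metadata for one additive variable in the manifest."""

    variant_id: str
    category: str
    locus_or_region: str = ""
    position_bp: int = 0  # 1-based build-37 coordinate; 0 when unknown / non-SNP
    effect_unit: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise CohortError(
                f"variant {self.variant_id}: unknown category {self.category!r}"
            )
        if self.position_bp < 0:
            raise CohortError(f"variant {self.variant_id}: negative position")


class DosageMatrix:
    """Dense subjects x variants grid of dosages in [0, 2]; NaN = missing."""

    def __init__(self, subjects: list[str], variants: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(subjects), len(variants)):
            raise CohortError(
                f"dosage grid shape {values.shape} does not match "
                f"{len(subjects)} subjects x {len(variants)} variants"
            )
        if len(set(subjects)) != len(subjects):
            raise CohortError("duplicate subject ids in dosage matrix")
        if len(set(variants)) != len(variants):
            dup = sorted({v for v in variants if variants.count(v) > 1})
            raise CohortError(f"duplicate variant ids in dosage matrix: {dup[:5]}")
        finite = values[np.isfinite(values)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            bad = np.argwhere(~np.isnan(values) & ((values < 0) | (values > 2)))[0]
            raise CohortError(
                f"dosage outside [0,2] at subject {subjects[bad[0]]!r}, "
                f"variant {variants[bad[1]]!r}: {values[bad[0], bad[1]]}"
            )
        self.subjects = list(subjects)
        self.variants = list(variants)
        self.values = values
        self._vindex = {v: i for i, v in enumerate(self.variants)}

    def __repr__(self) -> str:  # pragma: no cover
        return f"DosageMatrix({len(self.subjects)} subjects x {len(self.variants)} variants)"

    def column(self, variant_id: str) -> np.ndarray:
        try:
            return self.values[:, self._vindex[variant_id]]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in matrix") from None

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._vindex

    def subset_variants(self, keep: list[str]) -> "DosageMatrix":
        idx = [self._vindex[v] for v in keep]
        return DosageMatrix(self.subjects, list(keep), self.values[:, idx])

    def subset_subjects(self, keep: list[str]) -> "DosageMatrix":
        sindex = {s: i for i, s in enumerate(self.subjects)}
        idx = [sindex[s] for s in keep]
        return DosageMatrix(list(keep), self.variants, self.values[idx, :])

    @staticmethod
    def concat(parts: list["DosageMatrix"]) -> "DosageMatrix":
        """Column-concatenate parts sharing the same subject order."""
        if not parts:
            raise CohortError("nothing to concatenate")
        subjects = parts[0].subjects
        for p in parts[1:]:
            if p.subjects != subjects:
                raise CohortError("dosage parts do not share the subject universe")
        variants: list[str] = []
        for p in parts:
            variants.extend(p.variants)
        return DosageMatrix(subjects, variants, np.hstack([p.values for p in parts]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subjects, columns=self.variants)


@dataclass
class AssociationResult:
    """Per-variant additive logistic regression outcome.

    ``beta`` is the log-odds per dosage copy, ``conditioning_set`` the ordered
    covariate variants the fit adjusted for. Non-converged fits (separation,
    constant dosage, ...) carry ``converged=False``, a ``reason`` and no OR.
    """

    variant_id: str
    n_used: int = 0
    beta: float = float("nan")
    se: float = float("nan")
    or_point: float = float("nan")
    ci95: tuple[float, float] = (float("nan"), float("nan"))
    p_value: float = float("nan")
    conditioning_set: tuple[str, ...] = ()
    converged: bool = False
    reason: str = ""


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_hla_table(path) -> list[SubjectRecord]:
    """Read the TSV HLA typing table into SubjectRecords.

    Expected header: ``subject_id``, ``status``, then two columns per locus
    (``A_1``, ``A_2``, ..., ``DQB1_2``). Empty cells mean no call (gene
    absence for DRB3). The status column is the single source of truth for
    the case/control phenotype.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "subject_id" not in df.columns or "status" not in df.columns:
        raise CohortError(f"{path}: HLA table needs subject_id and status columns")
    loci: list[str] = []
    for col in df.columns:
        if col.endswith("_1"):
            locus = col[:-2]
            if f"{locus}_2" not in df.columns:
                raise CohortError(f"{path}: column {col} has no matching {locus}_2")
            loci.append(locus)
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise CohortError(f"{path}: duplicate subject_id {dup!r}")
    records = []
    for row_i, row in enumerate(df.itertuples(index=False), start=2):
        rowd = row._asdict()
        status_raw = rowd["status"].strip()
        if status_raw not in ("0", "1"):
            raise CohortError(
                f"{path} line {row_i}: status must be 0 or 1, got {status_raw!r}"
            )
        hla: dict[str, tuple[str, ...]] = {}
        for locus in loci:
            calls = []
            for suffix in ("_1", "_2"):
                cell = rowd[f"{locus}{suffix}"].strip()
                if cell:
                    try:
                        calls.append(normalize_allele(cell, locus))
                    except CohortError as exc:
                        raise CohortError(
                            f"{path} line {row_i}, column {locus}{suffix}: {exc}"
                        ) from None
            hla[locus] = tuple(calls)
        records.append(SubjectRecord(rowd["subject_id"], int(status_raw), hla))
    return records


def write_hla_table(records: list[SubjectRecord], path) -> None:
    loci = list(records[0].hla.keys()) if records else list(HLA_LOCI)
    cols: dict[str, list] = {"subject_id": [], "status": []}
    for locus in loci:
        cols[f"{locus}_1"] = []
        cols[f"{locus}_2"] = []
    for rec in records:
        cols["subject_id"].append(rec.subject_id)
        cols["status"].append(rec.status)
        for locus in loci:
            calls = rec.hla.get(locus, ())
            cols[f"{locus}_1"].append(calls[0] if len(calls) > 0 else "")
            cols[f"{locus}_2"].append(calls[1] if len(calls) > 1 else "")
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def _tsv_dosage(path) -> tuple[DosageMatrix, list[VariantDescriptor]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    bad = np.argwhere(~np.isnan(values) & ((values < 0) | (values > 2)))
    if bad.size:
        i, j = bad[0]
        raise CohortError(
            f"{path}: dosage {values[i, j]} outside [0,2] at subject "
            f"{df.index[i]!r}, SNP {df.columns[j]!r}"
        )
    variants = []
    descriptors = []
    for col in df.columns:
        # optional embedded coordinate: "rs123@32193220"
        if "@" in col:
            vid, pos = col.split("@", 1)
            position = int(pos)
        else:
            vid, position = col, 0
        variants.append(vid)
        descriptors.append(
            VariantDescriptor(vid, "snp", "chr6", position, "copies of coded allele")
        )
    return DosageMatrix([str(s) for s in df.index], variants, values), descriptors


def _vcf_dosage(path) -> tuple[DosageMatrix, list[VariantDescriptor]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    variants: list[str] = []
    descriptors: list[VariantDescriptor] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        ds = None
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(len(subjects))
        else:
            gts = rec.genotype.array() if rec.genotype is not None else None
            if gts is None:
                raise CohortError(f"{path}: record {vid} has neither GT nor DS")
            alleles = np.asarray(gts)[:, :2].astype(float)
            alleles[alleles < 0] = np.nan  # missing call
            col = alleles.sum(axis=1)
        if np.nanmin(col) < 0 or np.nanmax(col) > 2:
            raise CohortError(f"{path}: dosage outside [0,2] for SNP {vid}")
        variants.append(vid)
        descriptors.append(
            VariantDescriptor(vid, "snp", str(rec.CHROM), int(rec.POS), "ALT allele copies")
        )
        columns.append(col)
    values = np.column_stack(columns) if columns else np.empty((len(subjects), 0))
    return DosageMatrix(subjects, variants, values), descriptors


def read_snp_genotypes(path, format: str = "tsv_dosage"):
    """Read SNP dosages from a wide TSV or a VCF.

    VCF records use the DS format field when present and fall back to
    hard-calling from GT. Values outside [0,2] are a hard error, never
    clipped.
    """
    if format == "tsv_dosage":
        return _tsv_dosage(path)
    if format == "vcf":
        return _vcf_dosage(path)
    raise CohortError(f"unknown SNP genotype format {format!r}")


def align_to_cohort(
    records: list[SubjectRecord], matrix: DosageMatrix
) -> tuple[list[SubjectRecord], DosageMatrix, list[str]]:
    """Intersect HLA and SNP subject universes, in HLA-table order.

    Returns the aligned records, the re-ordered matrix and the list of
    subject ids dropped from either side.
    """
    snp_ids = set(matrix.subjects)
    kept = [r for r in records if r.subject_id in snp_ids]
    kept_ids = [r.subject_id for r in kept]
    hla_ids = {r.subject_id for r in records}
    dropped = [r.subject_id for r in records if r.subject_id not in snp_ids]
    dropped += [s for s in matrix.subjects if s not in hla_ids]
    return kept, matrix.subset_subjects(kept_ids), dropped


_ASSOC_COLUMNS = [
    "variant_id", "category", "position_bp", "n_used", "beta", "se",
    "OR", "CI_low", "CI_high", "P", "conditioning_set", "converged",
]


def write_association_table(
    results: list[AssociationResult],
    path,
    descriptors: dict[str, VariantDescriptor] | None = None,
) -> None:
    """Serialize scan results to TSV, lossless to 12 significant digits."""
    if not results:
        raise CohortError("refusing to write an empty association table")
    descriptors = descriptors or {}

    def fmt(x: float) -> str:
        return "NA" if not np.isfinite(x) else f"{x:.12g}"

    rows = []
    for r in results:
        d = descriptors.get(r.variant_id)
        rows.append({
            "variant_id": r.variant_id,
            "category": d.category if d else "",
            "position_bp": d.position_bp if d else 0,
            "n_used": r.n_used,
            "beta": fmt(r.beta),
            "se": fmt(r.se),
            "OR": fmt(r.or_point),
            "CI_low": fmt(r.ci95[0]),
            "CI_high": fmt(r.ci95[1]),
            "P": fmt(r.p_value),
            "conditioning_set": ";".join(r.conditioning_set),
            "converged": int(r.converged),
        })
    pd.DataFrame(rows, columns=_ASSOC_COLUMNS).to_csv(path, sep="\t", index=False)


def read_association_table(path) -> list[AssociationResult]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    def num(x: str) -> float:
        return float("nan") if x in ("", "NA") else float(x)

    out = []
    for row in df.itertuples(index=False):
        cond = tuple(row.conditioning_set.split(";")) if row.conditioning_set else ()
        out.append(AssociationResult(
            variant_id=row.variant_id,
            n_used=int(row.n_used),
            beta=num(row.beta),
            se=num(row.se),
            or_point=num(row.OR),
            ci95=(num(row.CI_low), num(row.CI_high)),
            p_value=num(row.P),
            conditioning_set=cond,
            converged=bool(int(row.converged)),
        ))
    return out
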