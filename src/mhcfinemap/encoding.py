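"""Derived-variable encoding: from HLA typings to additive dosage columns.

Every analysis variable is a per-subject count of copies in [0, 2]:

* classical HLA alleles, collated to serotype-equivalent two-digit groups at
  HLA-A/-B/-C and kept at four-digit resolution at DRB3/DRB1/DQB1;
* DRB1-DQB1 haplotype blocks (strong-LD two-locus haplotypes), phase-resolved
  by a control-frequency EM when a subject is heterozygous at both loci;
* DR-beta amino-acid residues at positions 37 and 86;
* the four KIR-ligand epitopes (Bw4/Bw6 on HLA-B, C1/C2 on HLA-C);
* MICA5.1 carriage.

The reference tables (residues, epitopes, serotypes, block rules) ship as
versioned fixture files under ``mhcfinemap/data``; alleles missing from a
table raise rather than guess.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .cohort import (
    CohortError,
    DosageMatrix,
    SubjectRecord,
    VariantDescriptor,
    allele_locus,
    normalize_allele,
)

RESIDUE_NAMES = {
    "N": "Asn", "L": "Leu", "F": "Phe", "S": "Ser", "Y": "Tyr",
    "G": "Gly", "V": "Val",
}
_POS37_RESIDUES = set("NLFSY")
_POS86_RESIDUES = set("GV")


def _data_path(name: str):
    return resources.files("mhcfinemap.data").joinpath(name)


def _read_table(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype=str)


class EncodingError(ValueError):
    """Allele absent from a reference table, or inconsistent encoding input."""


# ---------------------------------------------------------------------------
# reference tables
# ---------------------------------------------------------------------------

@dataclass
class AminoAcidTable:
    """DR-beta residues at positions 37 and 86 per DRB1 allele."""

    residues: dict[tuple[str, int], str]
    provenance: str = "IMGT/HLA 3.11.0-era curated subset"

    def __post_init__(self) -> None:
        alleles37 = {a for (a, p) in self.residues if p == 37}
        alleles86 = {a for (a, p) in self.residues if p == 86}
        if alleles37 != alleles86:
            raise EncodingError("every allele must carry both position 37 and 86")
        for (a, p), res in self.residues.items():
            ok = _POS37_RESIDUES if p == 37 else _POS86_RESIDUES
            if res not in ok:
                raise EncodingError(f"residue {res!r} invalid at position {p} ({a})")

    @property
    def alleles(self) -> set[str]:
        return {a for (a, p) in self.residues if p == 37}

    @classmethod
    def packaged(cls) -> "AminoAcidTable":
        df = _read_table("amino_acids_drb1.tsv")
        residues: dict[tuple[str, int], str] = {}
        for row in df.itertuples(index=False):
            allele = normalize_allele(row.allele, "DRB1")
            residues[(allele, 37)] = row.pos37
            residues[(allele, 86)] = row.pos86
        return cls(residues)


@dataclass
class EpitopeTable:
    """KIR-ligand dichotomies for HLA-B/-C plus the MICA5.1 class."""

    b_epitope: dict[str, str]
    c_epitope: dict[str, str]
    mica_class: dict[str, str]

    def __post_init__(self) -> None:
        for allele, e in self.b_epitope.items():
            if e not in ("Bw4", "Bw6"):
                raise EncodingError(f"B allele {allele} must map to Bw4 or Bw6")
        for allele, e in self.c_epitope.items():
            if e not in ("C1", "C2"):
                raise EncodingError(f"C allele {allele} must map to C1 or C2")

    @classmethod
    def packaged(cls) -> "EpitopeTable":
        df = _read_table("kir_epitopes.tsv")
        b, c, mica = {}, {}, {}
        for row in df.itertuples(index=False):
            allele = normalize_allele(row.allele)
            locus = allele_locus(allele)
            {"B": b, "C": c, "MICA": mica}[locus][allele] = row.epitope
        return cls(b, c, mica)


@dataclass
class BlockDefinition:
    """Grouping rules mapping a (DRB1, DQB1) haplotype to a block label.

    Patterns are four-digit alleles or two-digit groups (e.g. ``DRB1*04``
    matches every DRB1*04:XX allele). Rules must be disjoint; a pairing
    matching no rule falls into the explicit ``other`` block.
    """

    rules: list[tuple[str, str, str]] = field(default_factory=list)
    other_label: str = "other-DRB1-DQB1"

    def match(self, drb1: str, dqb1: str) -> str:
        hits = [
            label for (pd_, pq, label) in self.rules
            if _pattern_match(pd_, drb1) and _pattern_match(pq, dqb1)
        ]
        labels = sorted(set(hits))
        if len(labels) > 1:
            raise EncodingError(
                f"block rules not disjoint: {drb1}/{dqb1} matches {labels}"
            )
        return labels[0] if labels else self.other_label

    def check_disjoint(self, drb1_universe: set[str], dqb1_universe: set[str]) -> None:
        for d in drb1_universe:
            for q in dqb1_universe:
                self.match(d, q)  # raises on overlap

    @classmethod
    def packaged(cls) -> "BlockDefinition":
        df = _read_table("blocks.tsv")
        rules = [
            (normalize_allele(r.drb1_pattern, "DRB1"),
             normalize_allele(r.dqb1_pattern, "DQB1"),
             r.block)
            for r in df.itertuples(index=False)
        ]
        return cls(rules)


def _pattern_match(pattern: str, allele: str) -> bool:
    if ":" in pattern:
        return pattern == allele
    return allele.split(":")[0] == pattern


_SEROTYPES: dict[str, str] | None = None


def _serotype_map() -> dict[str, str]:
    global _SEROTYPES
    if _SEROTYPES is None:
        df = _read_table("serotypes.tsv")
        _SEROTYPES = {
            normalize_allele(r.pattern): r.serotype for r in df.itertuples(index=False)
        }
    return _SEROTYPES


# ---------------------------------------------------------------------------
# collation and per-category dosage encoders
# ---------------------------------------------------------------------------

def collate_allele(allele: str, level: str) -> str:
    """Collate an allele to ``serotype``, ``two_digit`` or ``four_digit`` level.

    Serotype collation is only defined for HLA-A and HLA-B (the loci the
    packaged map covers); four-digit entries take precedence over the
    two-digit group (B*15:01 -> B62 while B*15 alone has no serotype here).
    """
    allele = normalize_allele(allele)
    if level == "four_digit":
        return allele
    if level == "two_digit":
        return allele.split(":")[0]
    if level == "serotype":
        smap = _serotype_map()
        if allele in smap:
            return smap[allele]
        group = allele.split(":")[0]
        if group in smap:
            return smap[group]
        locus = allele_locus(allele)
        if locus not in ("A", "B"):
            raise EncodingError(f"no serotype map packaged for locus {locus}")
        raise EncodingError(f"allele {allele} missing from the serotype map")
    raise EncodingError(f"unknown collation level {level!r}")


#: collation level used per locus when building the study manifest; HLA-A and
#: HLA-B are analyzed as two-digit groups (serotype-equivalent on the packaged
#: universe, keeping field-standard labels like B*08), HLA-C at two-digit, the
#: class II loci at four-digit.
PIPELINE_LEVELS = {
    "A": "two_digit", "B": "two_digit", "C": "two_digit",
    "DRB3": "four_digit", "DRB1": "four_digit", "DQB1": "four_digit",
}


def allele_dosages(
    records: list[SubjectRecord], locus: str, level: str = "four_digit"
) -> tuple[DosageMatrix, list[VariantDescriptor]]:
    """One additive column per distinct collated allele observed at *locus*.

    Per subject the column value is the count of that allele among the
    subject's calls, so the per-subject row sum equals the number of calls
    (2 everywhere except DRB3, where gene absence gives 0 or 1).
    """
    labels: list[str] = []
    per_subject: list[list[str]] = []
    for rec in records:
        calls = [collate_allele(a, level) for a in rec.hla.get(locus, ())]
        per_subject.append(calls)
        labels.extend(calls)
    columns = sorted(set(labels))
    values = np.zeros((len(records), len(columns)))
    index = {c: j for j, c in enumerate(columns)}
    for i, calls in enumerate(per_subject):
        for c in calls:
            values[i, index[c]] += 1
    descriptors = [
        VariantDescriptor(c, "hla_allele", locus, 0, f"copies of {c}") for c in columns
    ]
    return DosageMatrix([r.subject_id for r in records], columns, values), descriptors


def translate_drb1(allele: str, position: int, table: AminoAcidTable) -> str:
    """Residue carried by a DRB1 allele at position 37 or 86."""
    if position not in (37, 86):
        raise EncodingError(f"position must be 37 or 86, got {position}")
    allele = normalize_allele(allele, "DRB1")
    try:
        return table.residues[(allele, position)]
    except KeyError:
        raise EncodingError(
            f"DRB1 allele {allele} absent from the amino-acid table"
        ) from None


def amino_acid_dosages(
    records: list[SubjectRecord], table: AminoAcidTable | None = None
) -> tuple[DosageMatrix, list[VariantDescriptor]]:
    """Residue-dosage columns (e.g. ``Asn37``); per-position row sums are 2."""
    table = table or AminoAcidTable.packaged()
    columns: list[str] = []
    rows: list[dict[str, int]] = []
    for rec in records:
        alleles = rec.hla.get("DRB1", ())
        if len(alleles) != 2:
            raise EncodingError(
                f"subject {rec.subject_id}: amino-acid encoding needs two DRB1 calls"
            )
        counts: dict[str, int] = {}
        for pos in (37, 86):
            for allele in alleles:
                res = translate_drb1(allele, pos, table)
                vid = f"{RESIDUE_NAMES[res]}{pos}"
                counts[vid] = counts.get(vid, 0) + 1
        rows.append(counts)
        columns.extend(counts)
    cols = sorted(set(columns), key=lambda v: (v[-2:], v))
    values = np.zeros((len(records), len(cols)))
    index = {c: j for j, c in enumerate(cols)}
    for i, counts in enumerate(rows):
        for c, n in counts.items():
            values[i, index[c]] = n
    descriptors = [
        VariantDescriptor(c, "amino_acid", "DRB1", 0, f"DR-beta {c} copies")
        for c in cols
    ]
    return DosageMatrix([r.subject_id for r in records], cols, values), descriptors


def kir_epitope_dosages(
    records: list[SubjectRecord], table: EpitopeTable | None = None
) -> tuple[DosageMatrix, list[VariantDescriptor]]:
    """Bw4/Bw6 and C1/C2 dosage columns; each pair partitions 2 copies."""
    table = table or EpitopeTable.packaged()
    cols = ["Bw4", "Bw6", "C1", "C2"]
    values = np.zeros((len(records), 4))
    index = {c: j for j, c in enumerate(cols)}
    for i, rec in enumerate(records):
        for locus, mapping in (("B", table.b_epitope), ("C", table.c_epitope)):
            alleles = rec.hla.get(locus, ())
            if len(alleles) != 2:
                raise EncodingError(
                    f"subject {rec.subject_id}: KIR encoding needs two {locus} calls"
                )
            for allele in alleles:
                if allele not in mapping:
                    raise EncodingError(
                        f"{locus} allele {allele} absent from the epitope table"
                    )
                values[i, index[mapping[allele]]] += 1
    descriptors = [
        VariantDescriptor(c, "kir_epitope", "B" if c.startswith("B") else "C", 0,
                          f"copies of {c}-bearing alleles")
        for c in cols
    ]
    return DosageMatrix([r.subject_id for r in records], cols, values), descriptors


def mica_dosages(
    records: list[SubjectRecord], table: EpitopeTable | None = None
) -> tuple[DosageMatrix, list[VariantDescriptor]]:
    """Single MICA5.1 dosage column (copies of A5.1-class MICA alleles)."""
    table = table or EpitopeTable.packaged()
    values = np.zeros((len(records), 1))
    for i, rec in enumerate(records):
        for allele in rec.hla.get("MICA", ()):
            if allele not in table.mica_class:
                raise EncodingError(f"MICA allele {allele} absent from the epitope table")
            if table.mica_class[allele] == "MICA5.1":
                values[i, 0] += 1
    desc = [VariantDescriptor("MICA5.1", "mica", "MICA", 0, "MICA5.1 copies")]
    return DosageMatrix([r.subject_id for r in records], ["MICA5.1"], values), desc


# ---------------------------------------------------------------------------
# DRB1-DQB1 block assignment (two-locus EM phasing)
# ---------------------------------------------------------------------------

def _em_haplotype_freqs(
    genotypes: list[tuple[tuple[str, str], tuple[str, str]]],
    max_iter: int = 200,
    tol: float = 1e-10,
) -> dict[tuple[str, str], float]:
    """Two-locus haplotype-frequency EM on unphased genotype pairs."""
    # initialize from independent pairing of observed alleles
    freqs: dict[tuple[str, str], float] = {}
    for (d1, d2), (q1, q2) in genotypes:
        for d in (d1, d2):
            for q in (q1, q2):
                freqs[(d, q)] = freqs.get((d, q), 0.0) + 1.0
    total = sum(freqs.values())
    freqs = {h: v / total for h, v in freqs.items()}
    n = len(genotypes)
    for _ in range(max_iter):
        counts = {h: 0.0 for h in freqs}
        for (d1, d2), (q1, q2) in genotypes:
            pa = freqs.get((d1, q1), 0.0) * freqs.get((d2, q2), 0.0)
            pb = freqs.get((d1, q2), 0.0) * freqs.get((d2, q1), 0.0)
            ambiguous = d1 != d2 and q1 != q2
            if not ambiguous or pa + pb == 0.0:
                wa = wb = 0.5
                if not ambiguous:
                    wa, wb = 1.0, 0.0
            else:
                wa = pa / (pa + pb)
                wb = 1.0 - wa
            counts[(d1, q1)] = counts.get((d1, q1), 0.0) + wa
            counts[(d2, q2)] = counts.get((d2, q2), 0.0) + wa
            counts[(d1, q2)] = counts.get((d1, q2), 0.0) + wb
            counts[(d2, q1)] = counts.get((d2, q1), 0.0) + wb
        new = {h: c / (2 * n) for h, c in counts.items()}
        delta = max(abs(new[h] - freqs.get(h, 0.0)) for h in new)
        freqs = new
        if delta < tol:
            break
    return freqs


def resolve_block_phase(
    records: list[SubjectRecord],
    defs: BlockDefinition,
    known_phases: dict[str, tuple[tuple[str, str], tuple[str, str]]] | None = None,
) -> dict[str, tuple[tuple[str, str], tuple[str, str]]]:
    """Resolve each subject's two (DRB1, DQB1) haplotypes.

    Phase is forced whenever at most one of the two loci is heterozygous.
    Double heterozygotes are resolved by haplotype-frequency EM fitted on
    the control subset only, followed by most-probable-phase hard
    assignment; exact ties break lexicographically on the resulting block
    label pair. ``known_phases`` (e.g. simulation truth) bypasses the EM.
    """
    if known_phases is not None:
        return dict(known_phases)
    genos = []
    control_genos = []
    for rec in records:
        d = rec.hla.get("DRB1", ())
        q = rec.hla.get("DQB1", ())
        if len(d) != 2 or len(q) != 2:
            raise EncodingError(
                f"subject {rec.subject_id}: block assignment needs two calls "
                "at DRB1 and DQB1"
            )
        genos.append((tuple(sorted(d)), tuple(sorted(q))))
        if rec.status == 0:
            control_genos.append(genos[-1])
    ambiguous = any(d1 != d2 and q1 != q2 for (d1, d2), (q1, q2) in genos)
    freqs = _em_haplotype_freqs(control_genos) if (ambiguous and control_genos) else {}
    phases = {}
    for rec, ((d1, d2), (q1, q2)) in zip(records, genos):
        if d1 == d2 or q1 == q2:
            phases[rec.subject_id] = ((d1, q1), (d2, q2))
            continue
        pa = freqs.get((d1, q1), 0.0) * freqs.get((d2, q2), 0.0)
        pb = freqs.get((d1, q2), 0.0) * freqs.get((d2, q1), 0.0)
        opt_a = ((d1, q1), (d2, q2))
        opt_b = ((d1, q2), (d2, q1))
        if pa > pb:
            phases[rec.subject_id] = opt_a
        elif pb > pa:
            phases[rec.subject_id] = opt_b
        else:  # tie: lexicographic on sorted block-label pair
            la = tuple(sorted(defs.match(*h) for h in opt_a))
            lb = tuple(sorted(defs.match(*h) for h in opt_b))
            phases[rec.subject_id] = opt_a if la <= lb else opt_b
    return phases


def assign_blocks(
    records: list[SubjectRecord],
    defs: BlockDefinition | None = None,
    known_phases: dict[str, tuple[tuple[str, str], tuple[str, str]]] | None = None,
) -> tuple[DosageMatrix, list[VariantDescriptor]]:
    """DRB1-DQB1 block dosage columns (0/1/2) after phase resolution."""
    defs = defs or BlockDefinition.packaged()
    phases = resolve_block_phase(records, defs, known_phases)
    per_subject = []
    labels: set[str] = set()
    for rec in records:
        haps = phases[rec.subject_id]
        ls = [defs.match(d, q) for (d, q) in haps]
        labels.update(ls)
        per_subject.append(ls)
    cols = sorted(labels)
    values = np.zeros((len(records), len(cols)))
    index = {c: j for j, c in enumerate(cols)}
    for i, ls in enumerate(per_subject):
        for label in ls:
            values[i, index[label]] += 1
    descriptors = [
        VariantDescriptor(c, "haplotype_block", "DRB1-DQB1", 0, f"copies of {c}")
        for c in cols
    ]
    return DosageMatrix([r.subject_id for r in records], cols, values), descriptors


# ---------------------------------------------------------------------------
# manifest assembly
# ---------------------------------------------------------------------------

def assemble_manifest(
    *parts: tuple[DosageMatrix, list[VariantDescriptor]],
) -> tuple[DosageMatrix, list[VariantDescriptor], dict[str, int]]:
    """Column-concatenate encoded parts into the unified variable manifest.

    Returns the combined matrix, the descriptor list and a per-category
    count summary. Duplicate variant ids across parts are a hard error;
    an empty SNP part only warns.
    """
    nonempty = [(m, d) for (m, d) in parts if m.variants]
    if len(nonempty) < len(parts):
        warnings.warn("assemble_manifest: one or more empty parts skipped")
    if not nonempty:
        raise EncodingError("no variables to assemble")
    matrices = [m for m, _ in nonempty]
    descriptors: list[VariantDescriptor] = []
    for _, d in nonempty:
        descriptors.extend(d)
    seen: set[str] = set()
    for desc in descriptors:
        if desc.variant_id in seen:
            raise EncodingError(f"duplicate variant id across parts: {desc.variant_id}")
        seen.add(desc.variant_id)
    combined = DosageMatrix.concat(matrices)
    summary: dict[str, int] = {}
    for desc in descriptors:
        summary[desc.category] = summary.get(desc.category, 0) + 1
    summary["total"] = len(descriptors)
    return combined, descriptors, summary


def encode_cohort(
    records: list[SubjectRecord],
    snp_part: tuple[DosageMatrix, list[VariantDescriptor]] | None = None,
    known_phases=None,
) -> tuple[DosageMatrix, list[VariantDescriptor], dict[str, int]]:
    """Full study encoding: SNPs + HLA alleles + blocks + residues + KIR + MICA."""
    hla_parts = [
        allele_dosages(records, locus, PIPELINE_LEVELS[locus])
        for locus in ("A", "C", "B", "DRB3", "DRB1", "DQB1")
    ]
    hla = (
        DosageMatrix.concat([m for m, _ in hla_parts]),
        [d for _, ds in hla_parts for d in ds],
    )
    blocks = assign_blocks(records, known_phases=known_phases)
    aa = amino_acid_dosages(records)
    kir = kir_epitope_dosages(records)
    mica = mica_dosages(records)
    parts = [hla, blocks, aa, kir, mica]
    if snp_part is not None:
        parts.insert(0, snp_part)
    return assemble_manifest(*parts)
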