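"""HLA-derived variable encoding: collation, dosages, residues, epitopes, blocks."""

import numpy as np
import pytest

from mhcfinemap.cohort import SubjectRecord
from mhcfinemap.encoding import (
    AminoAcidTable,
    BlockDefinition,
    EncodingError,
    EpitopeTable,
    allele_dosages,
    amino_acid_dosages,
    assemble_manifest,
    assign_blocks,
    collate_allele,
    encode_cohort,
    kir_epitope_dosages,
    resolve_block_phase,
    translate_drb1,
)
from mhcfinemap.simulate import simulate_cohort, study_preset


@pytest.mark.parametrize("allele,level,expected", [
    ("B*08:01", "serotype", "B8"),
    ("B*07:02", "serotype", "B7"),
    ("B*15:01", "serotype", "B62"),
    ("A*01:01", "serotype", "A1"),
    ("C*06:02", "two_digit", "C*06"),
    ("DRB1*13:01", "four_digit", "DRB1*13:01"),
])
def test_collation(allele, level, expected):
    assert collate_allele(allele, level) == expected


def test_collation_idempotent_and_guarded():
    assert collate_allele("B*08", "two_digit") == "B*08"  # already collated
    with pytest.raises(EncodingError, match="serotype"):
        collate_allele("DQB1*06:03", "serotype")


def _subject(sid, status=0, **hla):
    return SubjectRecord(sid, status, {k: tuple(v) for k, v in hla.items()})


def test_allele_dosages_counts_and_absence():
    records = [
        _subject("s1", A=["A*01:01", "A*01:01"], DRB3=[]),
        _subject("s2", A=["A*01:01", "A*02:01"], DRB3=["DRB3*01:01"]),
    ]
    mat, descs = allele_dosages(records, "A", "two_digit")
    np.testing.assert_allclose(mat.column("A*01"), [2, 1])  # homozygote counts 2
    drb3, _ = allele_dosages(records, "DRB3", "four_digit")
    np.testing.assert_allclose(drb3.column("DRB3*01:01"), [0, 1])
    assert all(d.category == "hla_allele" for d in descs)


def test_dosage_conservation_per_locus(study_sim):
    """Per locus, allele columns sum to the number of calls for every subject."""
    for locus, expected in (("A", 2), ("B", 2), ("DQB1", 2)):
        mat, _ = allele_dosages(study_sim.records, locus, "two_digit")
        np.testing.assert_allclose(mat.values.sum(axis=1), expected)
    drb3, _ = allele_dosages(study_sim.records, "DRB3", "four_digit")
    calls = np.array([len(r.hla["DRB3"]) for r in study_sim.records])
    np.testing.assert_allclose(drb3.values.sum(axis=1), calls)
    assert set(calls) == {0, 1, 2}  # DRB3 absence really occurs


@pytest.mark.parametrize("allele,position,residue", [
    ("DRB1*03:01", 37, "N"),
    ("DRB1*15:01", 37, "S"),
    ("DRB1*13:03", 37, "Y"),
    ("DRB1*07:01", 37, "F"),
    ("DRB1*12:01", 37, "L"),
])
def test_drb1_residue_translation(allele, position, residue):
    table = AminoAcidTable.packaged()
    assert translate_drb1(allele, position, table) == residue


def test_unknown_allele_errors_not_drops():
    table = AminoAcidTable.packaged()
    with pytest.raises(EncodingError, match="DRB1\\*99:99"):
        translate_drb1("DRB1*99:99", 37, table)


def test_amino_acid_dosages_additive():
    records = [
        _subject("s1", DRB1=["DRB1*03:01", "DRB1*13:01"]),  # both Asn37
        _subject("s2", DRB1=["DRB1*03:01", "DRB1*15:01"]),  # Asn37 + Ser37
    ]
    mat, _ = amino_acid_dosages(records)
    assert mat.column("Asn37")[0] == 2
    assert mat.column("Asn37")[1] == 1 and mat.column("Ser37")[1] == 1
    # per-position row sums are 2
    pos37 = [v for v in mat.variants if v.endswith("37")]
    np.testing.assert_allclose(mat.subset_variants(pos37).values.sum(axis=1), 2)


def test_study_residue_class_counts(study_sim):
    """The packaged allele universe spans 5 residue classes at position 37
    and 2 at position 86."""
    mat, _ = amino_acid_dosages(study_sim.records)
    assert sum(v.endswith("37") for v in mat.variants) == 5
    assert sum(v.endswith("86") for v in mat.variants) == 2


def test_kir_epitope_partition():
    records = [
        _subject("s1", B=["B*08:01", "B*08:01"], C=["C*07:01", "C*06:02"]),
        _subject("s2", B=["B*44:02", "B*57:01"], C=["C*04:01", "C*05:01"]),
    ]
    mat, _ = kir_epitope_dosages(records)
    assert mat.column("Bw6")[0] == 2 and mat.column("Bw4")[0] == 0  # B*08 is Bw6
    assert mat.column("Bw4")[1] == 2
    np.testing.assert_allclose(mat.column("Bw4") + mat.column("Bw6"), 2)
    np.testing.assert_allclose(mat.column("C1") + mat.column("C2"), 2)


def test_block_assignment_forced_phases():
    defs = BlockDefinition.packaged()
    hom = _subject("s1", DRB1=["DRB1*13:01", "DRB1*13:01"],
                   DQB1=["DQB1*06:03", "DQB1*06:03"])
    single_het = _subject("s2", DRB1=["DRB1*13:01", "DRB1*03:01"],
                          DQB1=["DQB1*06:03", "DQB1*06:03"])
    mat, _ = assign_blocks([hom, single_het], defs)
    assert mat.column("DRB1*13:01-DQB1*06:03")[0] == 2
    assert mat.column("DRB1*13:01-DQB1*06:03")[1] == 1  # phase forced, no EM


def test_unmatched_pairing_goes_to_other_block():
    defs = BlockDefinition.packaged()
    rec = _subject("s1", DRB1=["DRB1*09:01", "DRB1*09:01"],
                   DQB1=["DQB1*03:03", "DQB1*03:03"])
    mat, _ = assign_blocks([rec], defs)
    assert mat.column("other-DRB1-DQB1")[0] == 2


def test_em_phase_matches_simulation_truth(study_sim):
    """EM + hard assignment recovers >=99% of true phases when one pairing
    dominates (conserved blocks)."""
    defs = BlockDefinition.packaged()
    phases = resolve_block_phase(study_sim.records, defs)
    agree = 0
    for rec in study_sim.records:
        truth = {tuple(sorted(study_sim.true_phases[rec.subject_id]))}
        got = tuple(sorted(phases[rec.subject_id]))
        agree += got in truth
    assert agree / len(study_sim.records) >= 0.99


def test_block_never_exceeds_component_alleles(study_sim):
    """Block dosage for a label is bounded by the dosage of its DRB1 and
    DQB1 patterns for every subject."""
    blocks, _ = assign_blocks(study_sim.records)
    drb1, _ = allele_dosages(study_sim.records, "DRB1", "four_digit")
    dqb1, _ = allele_dosages(study_sim.records, "DQB1", "four_digit")
    b = blocks.column("DRB1*13:01-DQB1*06:03")
    assert (b <= drb1.column("DRB1*13:01") + 1e-12).all()
    assert (b <= dqb1.column("DQB1*06:03") + 1e-12).all()


def test_block_rules_disjoint_on_universe():
    defs = BlockDefinition.packaged()
    table = AminoAcidTable.packaged()
    dqb1 = {"DQB1*02:01", "DQB1*03:01", "DQB1*03:02", "DQB1*03:03",
            "DQB1*05:01", "DQB1*06:02", "DQB1*06:03", "DQB1*06:04"}
    defs.check_disjoint(table.alleles, dqb1)  # raises on overlap


def test_assemble_manifest_contracts(study_sim):
    matrix, descs, summary = encode_cohort(study_sim.records)
    assert summary["total"] == len(matrix.variants) == len(descs)
    assert summary["kir_epitope"] == 4 and summary["mica"] == 1
    # duplicate ids across parts are a hard error
    mat, d = allele_dosages(study_sim.records, "A", "two_digit")
    with pytest.raises(EncodingError, match="duplicate"):
        assemble_manifest((mat, d), (mat, d))
    # empty part warns but assembles
    empty = mat.subset_variants([])
    with pytest.warns(UserWarning, match="empty"):
        combined, _, _ = assemble_manifest((mat, d), (empty, []))
    assert combined.variants == mat.variants


def test_mica_epitope_tables_consistent():
    epi = EpitopeTable.packaged()
    assert epi.mica_class["MICA*008"] == "MICA5.1"
    assert all(e in ("Bw4", "Bw6") for e in epi.b_epitope.values())
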