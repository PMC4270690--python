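#!/usr/bin/env python
"""Encode the simulated cohort into the unified additive-dosage manifest:
SNPs + classical HLA alleles (two-digit at A/B/C, four-digit at class II) +
DRB1-DQB1 blocks (EM-phased on controls) + DR-beta residues 37/86 + KIR
epitopes + MICA5.1. Reports category counts and EM phasing accuracy against
the generator's true phases."""

import json
from pathlib import Path

import pandas as pd

from mhcfinemap.cohort import read_hla_table, read_snp_genotypes
from mhcfinemap.encoding import BlockDefinition, encode_cohort, resolve_block_phase

SIM = Path("results/sim")
OUT = Path("results")


def main() -> None:
    records = read_hla_table(SIM / "hla_typing.tsv")
    snps, snp_descs = read_snp_genotypes(SIM / "snp_dosages.tsv", "tsv_dosage")
    matrix, descriptors, summary = encode_cohort(records, (snps, snp_descs))

    phases = resolve_block_phase(records, BlockDefinition.packaged())
    truth = pd.read_csv(SIM / "true_phases.tsv", sep="\t")
    agree = 0
    for row in truth.itertuples(index=False):
        want = tuple(sorted([(row.hap1_drb1, row.hap1_dqb1),
                             (row.hap2_drb1, row.hap2_dqb1)]))
        agree += tuple(sorted(phases[row.subject_id])) == want
    accuracy = agree / len(truth)

    OUT.mkdir(exist_ok=True)
    manifest = pd.DataFrame({
        "variant_id": [d.variant_id for d in descriptors],
        "category": [d.category for d in descriptors],
        "locus_or_region": [d.locus_or_region for d in descriptors],
        "position_bp": [d.position_bp for d in descriptors],
    })
    manifest.to_csv(OUT / "variant_manifest.tsv", sep="\t", index=False)
    (OUT / "manifest_summary.json").write_text(json.dumps(
        {**summary, "em_phase_accuracy": accuracy}, indent=2) + "\n")

    print(f"manifest: {summary['total']} variables "
          f"({summary['snp']} SNPs, {summary['hla_allele']} HLA alleles, "
          f"{summary['haplotype_block']} blocks, {summary['amino_acid']} residues, "
          f"{summary['kir_epitope']} KIR epitopes, {summary['mica']} MICA)")
    print(f"EM phase assignment matches simulation truth for "
          f"{accuracy:.1%} of subjects")


if __name__ == "__main__":
    main()
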