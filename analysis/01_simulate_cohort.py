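#!/usr/bin/env python
"""Simulate the study cohort: 365 cases / 368 controls with nine
signal-bearing MHC haplotype families, planted per-copy odds ratios
(risk 4.3 / 1.7 / 2.5 / 4.9 / 2.32, protective 0.4 / 0.1 / 0.3), tag SNPs in
LD 0.43-0.83 with the B*08 anchor and an independent class III block.

Writes the HLA typing table, the SNP dosage table, the truth table and the
true phase file under results/sim/.
"""

from pathlib import Path

import pandas as pd

from mhcfinemap.cohort import write_hla_table
from mhcfinemap.simulate import simulate_cohort, study_preset

OUT = Path("results/sim")
SEED = 17


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = study_preset(seed=SEED)
    sim = simulate_cohort(config)

    write_hla_table(sim.records, OUT / "hla_typing.tsv")

    frame = sim.snp_matrix.to_frame()
    frame.columns = [
        f"{d.variant_id}@{d.position_bp}" for d in sim.snp_descriptors
    ]
    frame.to_csv(OUT / "snp_dosages.tsv", sep="\t", index_label="subject_id")

    sim.truth_frame().to_csv(OUT / "truth.tsv", sep="\t", index=False)
    rows = [
        {"subject_id": sid,
         "hap1_drb1": h1[0], "hap1_dqb1": h1[1],
         "hap2_drb1": h2[0], "hap2_dqb1": h2[1]}
        for sid, (h1, h2) in sim.true_phases.items()
    ]
    pd.DataFrame(rows).to_csv(OUT / "true_phases.tsv", sep="\t", index=False)

    n_case = sum(r.status for r in sim.records)
    print(f"simulated {len(sim.records)} subjects ({n_case} cases) with seed {SEED}")
    print(f"screened population case rate: {sim.population_case_rate:.2e} "
          f"(baseline prevalence 1e-4, risk enrichment above it)")
    print(f"SNP panel: {len(sim.snp_matrix.variants)} markers "
          f"(10 B*08 tags, 7 class III block SNPs, 103 null)")
    print(f"planted effects:\n{sim.truth_frame().to_string(index=False)}")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    main()
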