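"""Generate the synthetic study inputs with known ground truth.

Writes a proteome (FASTA + disorder/PTM/motif truth tables) and the
three-condition pull-down LFQ matrix (WT PH domain, R40A mutant,
WT + RNase III; 3 replicates each) under results/synthetic/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import pandas as pd

from rdpa import write_quant_table
from rdpa.simulate import generate_proteome, generate_pulldown_experiment

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    truth = generate_proteome(seed=SEED)
    truth.write(OUT)
    n_motifs = sum(len(v) for v in truth.motif_truth.values())
    print(
        f"proteome: {len(truth.records)} proteins, {len(truth.idr_truth)} "
        f"planted IDRs, {n_motifs} planted K/R motifs, "
        f"{len(truth.ptm_truth)} PTM sites -> {OUT}"
    )

    matrix, exp_truth = generate_pulldown_experiment(seed=SEED)
    write_quant_table(matrix, OUT / "pulldown_lfq.tsv", {"seed": SEED})
    pd.DataFrame(
        {
            "protein_id": sorted(exp_truth.pip2_associated),
            "dsrna_plus": [p in exp_truth.dsrna_plus
                           for p in sorted(exp_truth.pip2_associated)],
            "dsrna_minus": [p in exp_truth.dsrna_minus
                            for p in sorted(exp_truth.pip2_associated)],
        }
    ).to_csv(OUT / "pulldown_truth.tsv", sep="\t", index=False)
    print(
        f"pull-down: {matrix.data.shape[0]} protein groups x "
        f"{matrix.data.shape[1]} samples, "
        f"{matrix.n_missing()} missing cells "
        f"({100 * matrix.n_missing() / matrix.data.size:.1f}%); planted "
        f"{len(exp_truth.pip2_associated)} PIP2-associated "
        f"({len(exp_truth.dsrna_plus)} dsRNA+, {len(exp_truth.dsrna_minus)} dsRNA-)"
    )


if __name__ == "__main__":
    main()
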