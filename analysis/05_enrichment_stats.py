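"""Set enrichment and between-dataset comparisons.

Builds a protein "dataset" from the motif-in-IDR calls, tests its
over-representation among IDR-containing proteins with the exact
hypergeometric tail, and compares per-IDR pI/GRAVY distributions between
acidic and basic IDRs with BH-corrected rank-sum tests.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import pandas as pd

from rdpa import (
    DatasetDefinition,
    annotate_membership,
    pairwise_wilcoxon_bh,
    read_fasta,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_fasta(ROOT / "synthetic" / "proteome.fasta")
    background = DatasetDefinition("background", {r.protein_id for r in records})
    hits = pd.read_csv(ROOT / "motif_hits.tsv", sep="\t")
    physchem = pd.read_csv(ROOT / "idr_physchem.tsv", sep="\t")

    motif_proteins = set(hits.loc[hits.in_idr, "protein_id"])
    idr_proteins = set(physchem.protein_id)
    ds = DatasetDefinition("motif-in-IDR", motif_proteins)
    res = annotate_membership(ds, idr_proteins, background,
                              feature_name="has-consensus-IDR")
    pd.DataFrame([res.__dict__]).to_csv(ROOT / "enrichment.tsv", sep="\t",
                                        index=False)
    print(
        f"proteins with a K/R motif inside an IDR: {res.n}; of these "
        f"{res.k} carry a consensus IDR (background rate {res.K}/{res.N})"
        f"\nhypergeometric P(X >= {res.k}) = {res.p_value:.3g} ({res.direction})"
    )

    groups = {
        f"{metric}:{cls}": physchem.loc[physchem.charge_class == cls, metric].to_numpy()
        for metric in ("pI", "gravy", "length")
        for cls in ("acidic", "basic")
    }
    comparisons = []
    for metric in ("pI", "gravy", "length"):
        pair = pairwise_wilcoxon_bh(
            {c: groups[f"{metric}:{c}"] for c in ("acidic", "basic")}
        )
        pair.insert(0, "metric", metric)
        comparisons.append(pair)
    table = pd.concat(comparisons, ignore_index=True)
    table.to_csv(ROOT / "idr_metric_comparisons.tsv", sep="\t", index=False)
    print("\nacidic vs basic IDR comparisons (two-sided rank-sum, BH):")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
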