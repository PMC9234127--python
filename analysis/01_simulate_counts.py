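#!/usr/bin/env python
"""Generate the platelet-like RNA-seq count matrix used by the shortlist analysis.

Emulates a pan-cancer platelet profiling cohort: 50 healthy + 50 tumor
samples over 500 genes, with ten planted housekeeping genes (seven of
them named after known reference genes so the downstream intersection is
meaningful) among fold-shifted, noisy and zero-heavy decoys. The bulky
matrix and sample sheet go under scratch/sim/ (regenerable intermediate
data); the compact ground-truth table goes to results/sim/.
"""

from pathlib import Path

from tepnorm import simulate_counts, write_counts

SEED = 20220613
BASE = Path(__file__).resolve().parent.parent
OUT = BASE / "scratch" / "sim"
RESULTS = BASE / "results" / "sim"

HK_NAMES = ["YWHAZ", "GNAS", "GAPDH", "OAZ1", "PTMA", "B2M", "ACTB",
            "PLTSTB1", "PLTSTB2", "PLTSTB3"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    cm, truth = simulate_counts(
        n_genes=500, n_normal=50, n_tumor=50, seed=SEED, hk_gene_names=HK_NAMES
    )
    write_counts(cm, OUT / "counts.tsv", OUT / "samples.tsv")
    truth.genes.to_csv(RESULTS / "truth_genes.tsv", sep="\t")
    roles = truth.genes["role"].value_counts().to_dict()
    print(f"wrote {cm.n_genes} genes x {cm.n_samples} samples to {OUT}")
    print(f"planted roles: {roles}")
    print(f"housekeeping genes: {', '.join(truth.housekeeping_genes)}")


if __name__ == "__main__":
    main()
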