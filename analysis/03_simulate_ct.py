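#!/usr/bin/env python
"""Generate the RT-qPCR stability panel: 7 genes, 5 subject groups of 6.

Mirrors a validation cohort of one healthy and four tumor groups. One
planted gene is stable (no group shift, 0.1-cycle noise); three genes
carry group shifts of at least one cycle and three have inflated
replicate noise (>= 0.8 cycles). A shared per-sample loading effect
(SD 0.5 cycles) emulates input-amount variation. Three replicates per
measurement. Writes the long-format panel and truth under results/ct/.
"""

from pathlib import Path

from tepnorm import simulate_ct, write_ct

SEED = 913886
OUT = Path(__file__).resolve().parent.parent / "results" / "ct"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel, truth = simulate_ct(seed=SEED)
    write_ct(panel, OUT / "ct_panel.tsv")
    truth.genes.to_csv(OUT / "truth_genes.tsv", sep="\t")
    print(f"wrote {len(panel.genes)} genes x {len(panel.sample_ids)} samples "
          f"x 3 replicates to {OUT}")
    print(truth.genes.to_string())


if __name__ == "__main__":
    main()
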