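#!/usr/bin/env python
"""Generate the synthetic aging study: genome, annotations, counts, fragments.

Writes the full input set for the downstream analyses under
results/study/ — BED annotations, truth tables, ATAC/RNA/H3K9me3 count
matrices and the barcoded fragments file. Everything downstream of this
script reads only these files or regenerates them from the same seed.
"""

import pathlib

from chromage.counts import write_fragments
from chromage.genome import write_bed
from chromage.simulate import (SimConfig, generate_annotation,
                               generate_counts, generate_fragments)

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    ann = generate_annotation(cfg)
    sim = generate_counts(ann, cfg)
    frags, _ = generate_fragments(ann, cfg)

    cfg.to_yaml(OUT / "config.yaml")
    write_bed(OUT / "ccres.bed", ann.ccres)
    write_bed(OUT / "tss.bed", ann.genes)
    write_bed(OUT / "domains.bed", ann.domains)
    ann.truth.write(OUT / "truth")
    sim.atac.write_tsv(OUT / "counts_atac.tsv")
    sim.rna.write_tsv(OUT / "counts_rna.tsv")
    sim.k9_domains.write_tsv(OUT / "counts_k9_domains.tsv")
    sim.cell_domain_reads.to_csv(OUT / "cell_domain_reads.tsv", sep="\t",
                                 index=False)
    write_fragments(OUT / "fragments.tsv.gz", frags)

    n_up = (ann.truth.ccres["direction"] == "up").sum()
    n_down = (ann.truth.ccres["direction"] == "down").sum()
    print(f"study at seed {SEED}: {len(ann.ccres)} cCREs "
          f"({n_up} planted age-up, {n_down} age-down), "
          f"{len(ann.genes)} genes, {len(ann.domains)} H3K9me3 domains "
          f"({ann.truth.domains['decaying'].sum()} decaying), "
          f"{len(ann.truth.clusters)} planted clusters, "
          f"{len(frags)} fragments -> {OUT}")


if __name__ == "__main__":
    main()
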