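#!/usr/bin/env python
"""Build the synthetic FGFR3-like reference and write its FASTA + layout.

The gene is a deterministic stand-in for the real target (806 sense codons
over 13 exons, ten ~440 bp targeted subregions totalling 4405 positions)
whose pinned codons reproduce well-known receptor-kinase substitutions
(p.R248C, p.S249C, p.P250R, p.A334T, p.Y373C, p.G380R, p.N540K).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from duplexpipe import duplexsim as sim
from duplexpipe.refmodel import write_layout

OUT = Path(__file__).resolve().parents[1] / "results" / "reference"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    model, layout = sim.synthetic_gene()
    write_layout(model, layout, OUT / "gene_synthetic.fa", OUT / "layout.yaml")

    subs = pd.DataFrame(
        [{"subregion": n, "start": s, "end": e, "size": e - s} for n, (s, e) in layout.subregions]
    )
    subs.to_csv(OUT / "subregions.tsv", sep="\t", index=False)
    doms = pd.DataFrame(
        [{"domain": n, "aa_start": s, "aa_end": e} for n, (s, e) in layout.domains]
    )
    doms.to_csv(OUT / "domains.tsv", sep="\t", index=False)

    pinned = []
    for aa, codon in sorted(sim.PINNED_CODONS.items()):
        if aa == 1:
            continue
        gpos = sim.genomic_of_cds(model, 3 * (aa - 1) + 1)
        pinned.append(
            {"aa_index": aa, "codon": codon, "cds_start": 3 * (aa - 1) + 1,
             "genomic_start": gpos, "subregion": layout.subregion_of(gpos),
             "domain": layout.domain_of(aa)}
        )
    pd.DataFrame(pinned).to_csv(OUT / "pinned_codons.tsv", sep="\t", index=False)

    print(f"gene: {len(model)} bp, CDS {len(model.coding_sequence)} nt, "
          f"{len(model.exons)} exons, targeted positions {layout.region_size}")
    print(f"wrote FASTA/layout and tables to {OUT}")


if __name__ == "__main__":
    main()
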