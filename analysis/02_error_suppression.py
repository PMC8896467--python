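#!/usr/bin/env python
"""Single-strand vs duplex consensus error rates on a damage-bearing null
library (no true variants; deamination, oxo-G, PCR and sequencing error on).

Demonstrates the core duplex-sequencing property: strand-confined artifacts
dominate the single-strand consensus level and vanish at the duplex level,
because a true variant must appear on both strands of the source molecule.
"""

import sys
import tempfile
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from duplexpipe import consensus as cns
from duplexpipe import duplexsim as sim
from duplexpipe import pipeline as pl

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    model, layout = sim.synthetic_gene()
    cfg = sim.SimConfig(seed=303, n_molecules=22800, subregions=("Up4",))
    with tempfile.TemporaryDirectory() as tmp:
        lib = sim.simulate_library(cfg, model, layout, tmp, "null")
        lc = cns.consensus_library(lib.r1_path, lib.r2_path, model, layout, library_id="null")
    es = pl.error_suppression_summary(lc, model, layout)

    rows = [
        {"level": "SSCS", "bases": es.sscs_bases, "alt_calls": es.sscs_alt,
         "freq": es.sscs_freq, **{f"n_{k}": v for k, v in es.sscs_class_counts.items()}},
        {"level": "DCS", "bases": es.dcs_bases, "alt_calls": es.dcs_alt,
         "freq": es.dcs_freq, **{f"n_{k}": v for k, v in es.dcs_class_counts.items()}},
    ]
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "error_suppression.tsv", sep="\t", index=False)

    damage = es.sscs_class_counts["C>A"] + es.sscs_class_counts["C>T"]
    print(df.to_string(index=False))
    print(f"\nSSCS variant frequency {es.sscs_freq:.2e} vs DCS {es.dcs_freq:.2e} "
          f"(suppression >= {es.suppression_ratio:.0f}x with the DCS count floored at 1)")
    print(f"damage classes (C>A oxo-G, C>T/G>A deamination) are "
          f"{damage / max(es.sscs_alt, 1):.1%} of single-strand calls")


if __name__ == "__main__":
    main()
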