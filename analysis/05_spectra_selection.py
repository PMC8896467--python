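#!/usr/bin/env python
"""Mutational spectra and selection over the cohort's final variant table.

Compares the younger and older donor groups' 6-class spectra by cosine
similarity against the bootstrap expectation, reports the strand assignment
of the folded classes (transcription bias check), the CpG-transition
marginal of the 96-channel signature, and prints the headline dN/dS strata
from the cohort report.  Requires 04_study_cohort.py to have run.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from duplexpipe import duplexsim as sim
from duplexpipe import freqstats as fs
from duplexpipe import spectra as spc
from duplexpipe import varcall as vc

COHORT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    final = vc.read_variant_table(COHORT / "variants_final.tsv")
    if final.empty:
        sys.exit("cohort variant table is empty; run 04_study_cohort.py first")
    model, layout = sim.synthetic_gene()
    exonic = fs.scope_mask(model, layout, None, "exonic")

    final["age_group"] = np.where(final["library_id"].str.startswith("Y"), "younger", "older")
    by_age = {}
    for age, grp in final.groupby("age_group"):
        by_age[age] = spc.spectrum(grp, model, 6, exonic)
    frames = []
    for age, s in by_age.items():
        df = s.to_frame()
        df.insert(0, "age_group", age)
        frames.append(df)
    pd.concat(frames).to_csv(COHORT / "spectra_by_age.tsv", sep="\t", index=False)

    young, old = by_age["younger"], by_age["older"]
    n_query = int(min(young.counts.sum(), old.counts.sum()))
    boot = spc.cosine_with_bootstrap(old.counts, young.counts, iterations=1000, seed=13)
    pd.DataFrame(
        [{
            "observed_cosine": boot.observed,
            "n": boot.n,
            "null_q025": boot.quantile(0.025),
            "null_median": boot.quantile(0.5),
            "null_q975": boot.quantile(0.975),
        }]
    ).to_csv(COHORT / "cosine_young_vs_old.tsv", sep="\t", index=False)
    print(f"younger vs older 6-class spectra: cosine {boot.observed:.3f} "
          f"(bootstrap expectation median {boot.quantile(0.5):.3f}, "
          f"2.5-97.5% [{boot.quantile(0.025):.3f}, {boot.quantile(0.975):.3f}], n={n_query})")

    strand = spc.strand_spectrum(final, model)
    strand.to_csv(COHORT / "strand_spectrum.tsv", sep="\t")
    print("\nstrand assignment of folded classes (transcription-bias check):")
    print(strand.to_string())

    s96 = spc.spectrum(final, model, 96, exonic)
    cpg = spc.cpg_transition_count(s96)
    total_ct = int(spc.marginalize96(s96).counts[2])
    print(f"\nCpG-context C>T transitions: {cpg} of {total_ct} C>T calls")

    dnds = pd.read_csv(COHORT / "dnds.tsv", sep="\t")
    head = dnds[(dnds["age_group"] == "all") | (dnds["domain"] == "all")]
    print("\ndN/dS strata (observed vs randomization null):")
    cols = ["domain", "age_group", "n_nonsyn", "n_syn", "dnds",
            "null_median", "null_lower", "null_upper"]
    print(head[cols].to_string(index=False))


if __name__ == "__main__":
    main()
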