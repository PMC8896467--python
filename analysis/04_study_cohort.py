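#!/usr/bin/env python
"""Simulate and analyse a study-like cohort: twelve libraries (six younger,
six older donor pools, each targeting the Up or Down half of the gene) with
planted clonal-expansion-candidate variants enriched in older donors,
shared postzygotic-mosaic-like variants, one pool polymorphism, and random
low-frequency mutations.

Desk-scale note: duplex coverage is ~800x per library and planted molecular
fractions are scaled up accordingly (5e-3..5e-2), preserving the expected
alternate-allele counts of the study regime; the coverage filter is scaled
to 300 in step.  Reports land in results/cohort/.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from duplexpipe import duplexsim as sim
from duplexpipe import freqstats as fs
from duplexpipe import pipeline as pl
from duplexpipe import varcall as vc

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"

N_MOLECULES = 1700  # per subregion: ~800x duplex coverage
UP = ("Up1", "Up2", "Up3", "Up4", "Up5")
DOWN = ("Down1", "Down2", "Down3", "Down4", "Down5")

#: (cds position, alt, fraction, libraries) — the planted narrative
PLANTED = [
    # clonal-expansion candidates: exclusively or more frequent in older donors
    (1118, "G", 0.030, ["O1", "O2", "O3"]),   # p.Y373C analogue
    (1138, "A", 0.012, ["O1", "O2"]),          # p.G380R analogue
    (1620, "A", 0.008, ["O4"]),                # p.N540K via C>A
    (1620, "G", 0.020, ["O5"]),                # p.N540K via C>G
    # postzygotic-mosaic-like: both age groups at similar fractions
    (742, "T", 0.012, ["Y1", "Y2", "O1", "O2"]),
    (1000, "A", 0.008, ["Y3", "O3"]),
    # younger-only
    (749, "G", 0.010, ["Y1"]),
    (746, "G", 0.006, ["Y2"]),
]

#: a pool polymorphism: ~10% in every younger-Up library (must be masked)
SNP_CDS, SNP_FRACTION = 600, 0.10


def build_cohort(model) -> list[pl.LibrarySpec]:
    rng = np.random.default_rng(2024)
    exonic = model.site_class == 0
    specs = []
    for i in range(1, 7):
        for age, prefix, pool in (("younger", "Y", "pool_Y"), ("older", "O", "pool_O")):
            lid = f"{prefix}{i}"
            target = "Up" if i <= 3 else "Down"
            subs = UP if target == "Up" else DOWN
            lo, hi = (0, 2203) if target == "Up" else (2203, 4405)
            variants = []
            for cds, alt, frac, libs in PLANTED:
                pos = sim.genomic_of_cds(model, cds)
                if lid in libs and lo <= pos < hi:
                    variants.append(sim.TrueVariant(pos, model.sequence[pos], alt, frac))
            if age == "younger" and target == "Up":
                pos = sim.genomic_of_cds(model, SNP_CDS)
                variants.append(sim.TrueVariant(pos, model.sequence[pos], "T" if model.sequence[pos] != "T" else "A", SNP_FRACTION))
            # three random background mutations per library
            cand = np.flatnonzero(exonic[lo:hi]) + lo
            taken = {v.position for v in variants}
            added = 0
            while added < 3:
                pos = int(rng.choice(cand))
                if pos in taken:
                    continue
                ref = model.sequence[pos]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                variants.append(sim.TrueVariant(pos, ref, alt, float(rng.uniform(0.005, 0.03))))
                taken.add(pos)
                added += 1
            cfg = sim.SimConfig(
                seed=1000 + 17 * i + (0 if prefix == "Y" else 500),
                n_molecules=N_MOLECULES,
                true_variants=tuple(variants),
                subregions=subs,
            )
            specs.append(pl.LibrarySpec(vc.LibraryMeta(lid, pool, age, target), cfg))
    return specs


def main() -> None:
    model, layout = sim.synthetic_gene()
    cfg = pl.RunConfig(
        out_dir=OUT,
        libraries=build_cohort(model),
        min_coverage=300,
        iterations=1000,
        stats_seed=7,
        keep_fastq=False,
    )
    res = pl.run_pipeline(cfg)

    uniq, npos, collapsed = fs.unique_variant_counts(res.final_calls)
    print(f"final variants: {collapsed} per-library counts, {uniq} unique at {npos} positions")
    print(f"overall mutation frequency: {res.overall.frequency:.3e} per bp "
          f"[{res.overall.ci_low:.3e}, {res.overall.ci_high:.3e}]")
    for age, r in res.by_age.items():
        print(f"  {age}: {r.frequency:.3e} per bp (n={r.numerator})")
    for dom, r in res.by_domain.items():
        print(f"  {dom}: {r.frequency:.3e} per bp (n={r.numerator})")

    strata = {a: (r.numerator, r.denominator) for a, r in res.by_age.items()}
    age_tests = fs.pairwise_chisq_holm(strata)
    age_tests.to_csv(OUT / "age_group_tests.tsv", sep="\t", index=False)
    dom_strata = {d: (r.numerator, r.denominator) for d, r in res.by_domain.items() if r.denominator}
    dom_tests = fs.pairwise_chisq_holm(dom_strata)
    dom_tests.to_csv(OUT / "domain_tests.tsv", sep="\t", index=False)
    print("\nage-group comparison (chi-square, Holm):")
    print(age_tests.to_string(index=False))

    snp_pos = sim.genomic_of_cds(model, SNP_CDS)
    masked = res.all_calls[(res.all_calls["position"] == snp_pos) & res.all_calls["flag_snp"]]
    print(f"\npool polymorphism at genomic {snp_pos}: masked in {len(masked)} libraries")
    print(f"reports written to {OUT}")


if __name__ == "__main__":
    main()
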