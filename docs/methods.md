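# Methods

`duplexpipe` implements a duplex-sequencing (DS) analysis chain for a single
targeted gene — consensus calling, tiered substitution filtering, mutation
frequency estimation, mutational spectra, and dN/dS selection analysis — and a
synthetic duplex-read generator that reproduces the statistical structure those
methods rely on. This note records the models, the defaults and why, and what
the synthetic data can and cannot show.

## Duplex consensus model

Every source DNA molecule carries a double barcode: a random tag at each end.
Reads from the two strands of one molecule carry the same tag pair in opposite
order, so the canonical (sorted) pair identifies the molecule and the order
identifies the strand.

1. **Mate merging.** The two mates of a read pair observe the same fragment;
   they are merged position-wise first (disagreement → N), so the unit of
   family size is the read pair.
2. **SSCS.** Per strand family, the single-strand consensus keeps base *b* at a
   position only when count(*b*) strictly exceeds `majority` × (non-N
   observations); a tie at exactly the threshold yields N (conservative).
   Families below `min_family_size` read pairs are rejected.
   Defaults: `majority = 0.7`, `min_family_size = 3` — conventional values for
   duplex pipelines; both are config-exposed and logged, since published duplex
   tools do not agree on a single setting.
3. **DCS.** The duplex consensus keeps a base only where the two strand
   consensuses agree on a non-N base. A single-strand artifact — a DNA lesion
   present in the template of one strand, or a PCR jackpot — therefore becomes
   N and never yields a variant call, which is the core error-suppression
   property of DS.

Coverage at a position is the number of non-N DCS bases; VAF is the
alternate-supporting DCS count divided by that coverage.

Simulated reads are generated coordinate-anchored to their subregion (the read
name carries the subregion and mate orientation, the information a mapper
would provide). A real-data path would need read mapping, which is out of
scope here; there are no indels anywhere in the model.

## Variant tiers and filtering

Each call's supporting duplex families are re-examined: tier 1 requires every
supporting DCS to have ≥ 3 read pairs per strand and alternate support
≥ 0.75 on both strands; tier 2 requires ≥ 1 pair per strand with full
agreement; anything weaker is `lower`. A variant is masked as a SNP when it
appears in **all** libraries sharing a donor-pool/target combination at
VAF ≥ 0.05 in each (the threshold implements an "about 10 %" heterozygote in a
five-donor pool, halved for sampling noise; configurable). The final table
keeps non-intronic, non-SNP calls at DCS coverage ≥ 1000 that are tier 1, or
tier 2 detected more than once. "More than once" counts identical
(position, ref, alt) across all libraries of the analysis set — a per-library
recurrence of the same substitution is one detection per library — and is
invariant to library order.

Splice-region calls (within `splice_pad = 2` bases of an exon edge, the
canonical splice dinucleotides) are non-intronic and survive filtering, but
carry no codon consequence and are excluded from dN/dS.

## Mutation frequency

For libraries *i* with `variant_count_i` (within-library duplicates collapsed;
cross-library recurrences counted once per library), mean DCS coverage
`mean_coverage_i` over the in-scope positions and `region_size_i` in-scope
positions:

    mutation_frequency = Σ variant_count_i / Σ (mean_coverage_i × region_size_i)

The default scope counts **exonic** targeted positions, consistent with
exonic-variant numerators; `scope="all"` uses every sequenced position and the
reports name the mode. Domain strata restrict both the numerator and the
denominator footprint to the domain's codons. Intervals are exact Garwood
(chi-square quantile) Poisson intervals — normal approximations are useless at
counts of order 1–10. Group comparisons are chi-square tests of count against
exposure (sequenced bases) with Holm step-down correction; Fisher's exact test
is provided for 2×2 tables.

## Spectra

Substitutions fold to six pyrimidine-centred classes (fixed order C>A, C>G,
C>T, T>A, T>C, T>G); the 96-channel signature adds the 5′/3′ neighbours, with
contexts ordered alphabetically within class. Opportunities count the
reference bases (C+G for C-classes, T+A for T-classes) or trinucleotide
contexts in the region; the class frequency normalisation is

    freq_type = count_type / (n_ref_allele / region_size × Σ mean_coverage_i × region_size_i)

The bootstrap expectation for a cosine comparison resamples *n* mutations
(*n* = the query's mutation count) from the reference's category distribution
1000 times and takes the cosine of each resample against the **original**
reference. The alternative reading — resampling both spectra each iteration —
is available as `resample_both=True`; the default is the version whose
distribution tightens monotonically with *n*, which is the property used when
judging an observed cosine. A CpG-transition marginal (N[C>T]G channels) is
reported because strong-to-weak transitions at CpG sites are the dominant
germline signal.

## dN/dS with a spectrum-preserving randomization null

Site counts follow Nei–Gojobori: each codon position contributes
(synonymous single-base changes)/3 synonymous sites, so N + S = 3 per codon.
Regions are assumed sense-codon-only (a stop codon in the region is an error);
stop-*creating* changes count as nonsynonymous, and dN = nonsynonymous
mutations / N sites, dS likewise. dS = 0 leaves the ratio undefined, never
infinite.

The neutral reference distribution places the observed number of mutations at
random sites compatible with the observed 6-class spectrum (96-context
available as a switch) and recomputes dN/dS, 1000 iterations. Because
placements are i.i.d. uniform within a class, the synonymous tally per
iteration is exactly a per-class binomial with the class's enumerated
synonymous fraction; the implementation samples that binomial, which is
distributionally identical to materialising each site and much cheaper. Under
a spectrum uniform over **all** possible changes the null centres on 1 — the
defining property of the NG normalisation, and an acceptance test. The
reported "lower/upper range" of the null is the 2.5/97.5 percentile by
default; `range_mode="minmax"` gives the extremes of the draws instead.
Null placement samples with replacement (n ≪ sites; the difference is
negligible and the contract simpler). Per-stratum nulls preserve that
stratum's own spectrum and mutation count over the stratum's targeted codons.

## Synthetic data generator

The generator emulates, per subregion and molecule:

| parameter | default | rationale |
|---|---|---|
| `n_molecules` | 22 800 | yields ≈ 11 000× DCS coverage (the study regime) at the family-size default, since P(both strands ≥ 3 pairs) ≈ 0.48 |
| `family_size_law` | geometric, mean 6 | no published family-size law for these libraries; geometric captures the long right tail of PCR-seeded families |
| `tag_length` | 12 | double-barcode adapter length; collisions of full tag *pairs* are negligible |
| `damage_rate_deam` | 1.5 × 10⁻⁴ /C/strand | calibrated so single-strand consensus artifact frequency ≈ 5 × 10⁻⁵ per base with ~90 % of calls in the two damage classes, the regime targeted libraries show |
| `damage_rate_oxoG` | 5 × 10⁻⁵ /G/strand | same calibration; oxo-G (read as G>T / C>A) is the smaller component |
| `pcr_error_rate` | 10⁻⁶ /base/duplication | high-fidelity polymerase class |
| `pcr_cycles` | 8 | depth of the branching duplication tree |
| `seq_error_rate` | 10⁻³ /base/mate | Illumina substitution regime |

True variants are planted on **both** strands of carrier molecules (carriers
drawn per molecule at the configured fraction; the realised fraction is
recorded as the expected VAF). Damage lesions are planted on **one** strand:
deamination C>T appears as C>T on one strand template and G>A on the other
strand's pileup; oxo-G as G>T / C>A. PCR jackpots are modelled by lineage
sampling of the duplication tree: an error arising at cycle *c* is inherited
by each sampled read of the family independently with probability 2⁻ᶜ, which
matches the full tree in distribution. Sequencing errors are independent per
mate. Base qualities are constant Q37, so quality trimming is a no-op unless
the generator is configured otherwise.

The spike-in series spikes the **same four variants** into every library at
the library's dilution (1:10 … 1:10 000), all four inside one targeted
subregion so a series costs one subregion per library. The four libraries
share one donor pool and target set, which exercises the SNP mask correctly
(the 1:10 variant is not masked because it is not ≥ 5 % in *all* sharing
libraries).

**What the generator does not emulate:** read mapping ambiguity and soft
clipping, indels, tag errors and tag-family collisions requiring error-tolerant
clustering, capture-efficiency differences between subregions, restriction
fragment end effects, and per-cycle quality decay. Passing tests therefore
demonstrate the correctness of the consensus/filtering/statistics chain under
the assumed error structure, not robustness to alignment or chemistry
artifacts of real libraries.

## Synthetic reference gene

The real target gene's sequence is not bundled; `synthetic_gene()` builds a
deterministic stand-in: 806 sense codons over 13 exons (12 introns of 170 bp
with GT…AG ends), ten targeted subregions of ~440 bp totalling 4405 positions,
and domain intervals IgI-III (aa 1–360), TM + inter-domains (361–450), TK
(451–806) at cartoon granularity — the exact boundaries are assumptions.
Pinned codons reproduce the classic receptor-kinase substitutions (p.R248C,
p.S249C, p.P250R, p.A334T, p.Y373C, p.G380R, p.N540K via both c.1620C>A and
c.1620C>G), so HGVS-style outputs match the field's familiar coordinates.
Analyses run in CDS orientation; that the real gene lies on the genomic minus
strand is recorded as a flag only.

## Problem sizes

The acceptance checks run the dilution series at the full study coverage
(≈ 11 000× DCS, four libraries per replicate; three replicates in the
acceptance script, two in the test suite) and one damage-bearing null library
at the same scale. The cohort analysis (`analysis/04`) uses twelve libraries
at ≈ 800× DCS with planted molecular fractions scaled up to 5 × 10⁻³…5 × 10⁻²,
preserving expected alternate-allele counts, and scales the coverage filter to
300 in step; unit and property tests use tens to hundreds of molecules.

## Degenerate inputs and numerical choices

- Zero-carrier draws at extreme dilutions are legal and recorded in the truth
  table; such variants are undetectable by construction.
- The SSCS/DCS suppression ratio floors the DCS count at one event so a clean
  duplex level reports a finite, conservative ratio.
- An empty stratum reports frequency 0 with a one-sided Poisson interval;
  confidence level 0 degenerates to the point estimate.
- Spectrum classes with zero opportunity and zero count report frequency 0;
  a count without opportunity is an error (it indicates a region/variant
  mismatch).
- Tag pairs containing N, or with both tags identical (strand ambiguous), are
  discarded and counted.
- All randomness flows through seeded `numpy` generators; identical configs
  produce byte-identical FASTQ and reports.

## Known limitations

Single-gene, substitution-only scope; no real-data alignment path; tier
thresholds and the SNP VAF cutoff are conventions, not fitted quantities; the
synthetic gene's base composition is uniform-random where real exons are not,
so opportunity-normalised spectra on synthetic cohorts should not be read as
biology.
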