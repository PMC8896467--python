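"""Substitution calling from duplex pileups, tier assignment and filtering.

Calls are kept in a pandas DataFrame with one row per (library, position,
alt); multi-allelic sites yield one row per alternate base.  The confidence
tier of a call summarises the duplex evidence behind it: tier 1 requires
every supporting duplex consensus to rest on large, clean families on both
strands, tier 2 tolerates weaker but fully concordant evidence, everything
else is 'lower'.  Library-shared high-frequency variants are masked as SNPs,
and the final analysis table keeps non-intronic, non-SNP calls at duplex
coverage >= 1000 that are tier 1, or tier 2 seen more than once across the
analysis set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from ._seqcodes import BASES, encode
from .consensus import LibraryConsensus, Pileup
from .refmodel import CATEGORY_INTRONIC, ReferenceModel, TargetLayout

TIER1 = "tier1"
TIER2 = "tier2"
TIER_LOWER = "lower"

SNP_VAF_THRESHOLD = 0.05  # per sharing library; the study quotes "~10%"
MIN_DCS_COVERAGE = 1000

CALL_COLUMNS = [
    "library_id",
    "position",
    "ref",
    "alt",
    "alt_count",
    "dcs_coverage",
    "vaf",
]


@dataclass(frozen=True)
class LibraryMeta:
    """Per-library metadata used for SNP masking and age stratification."""

    library_id: str
    donor_pool_id: str
    age_group: str  # "younger" | "older"
    target_set: str  # "Up" | "Down"


@dataclass(frozen=True)
class TierThresholds:
    tier1_min_reads: int = 3
    tier1_min_fraction: float = 0.75
    tier2_min_reads: int = 1
    tier2_min_fraction: float = 1.0


def call_variants(pile: Pileup, model: ReferenceModel, library_id: str = "lib") -> pd.DataFrame:
    """One call per (position, alt) with at least one supporting DCS."""
    rows = []
    pos_idx = np.flatnonzero(pile.coverage > 0)
    for pos in pos_idx:
        ref_code = model.codes[pos]
        for alt_code in range(4):
            if alt_code == ref_code:
                continue
            n = int(pile.counts[alt_code, pos])
            if n == 0:
                continue
            cov = int(pile.coverage[pos])
            rows.append(
                {
                    "library_id": library_id,
                    "position": int(pos),
                    "ref": BASES[ref_code],
                    "alt": BASES[alt_code],
                    "alt_count": n,
                    "dcs_coverage": cov,
                    "vaf": n / cov,
                }
            )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def assign_tier(
    evidence: Sequence[tuple[int, int, float, float]],
    thresholds: TierThresholds = TierThresholds(),
) -> str:
    """Tier from per-supporting-DCS evidence tuples
    (reads strand a, reads strand b, alt support fraction a, fraction b).

    Tier 1 if every supporting duplex family is large and concordant on both
    strands; tier 2 if every family at least meets the weaker floor; else
    'lower'.  Raises on missing evidence.
    """
    if not evidence:
        raise ValueError("no supporting evidence supplied")

    def passes(ev, min_reads, min_frac):
        ka, kb, fa, fb = ev
        return ka >= min_reads and kb >= min_reads and fa >= min_frac and fb >= min_frac

    t = thresholds
    if all(passes(ev, t.tier1_min_reads, t.tier1_min_fraction) for ev in evidence):
        return TIER1
    if all(passes(ev, t.tier2_min_reads, t.tier2_min_fraction) for ev in evidence):
        return TIER2
    return TIER_LOWER


def collect_evidence(
    lib: LibraryConsensus, position: int, alt: str
) -> list[tuple[int, int, float, float]]:
    """Evidence tuples for every DCS calling ``alt`` at ``position``."""
    alt_code = encode(alt)[0]
    out = []
    for sub in lib.subregions.values():
        if not sub.start <= position < sub.start + sub.length:
            continue
        col = position - sub.start
        rows = np.flatnonzero(sub.dcs[:, col] == alt_code)
        for r in rows:
            depths = sub.strand_depth[:, r, col].astype(float)
            fracs = np.where(depths > 0, sub.strand_support[:, r, col] / np.maximum(depths, 1), 0.0)
            out.append(
                (int(sub.fam_sizes[r, 0]), int(sub.fam_sizes[r, 1]), float(fracs[0]), float(fracs[1]))
            )
    return out


def assign_tiers(
    calls: pd.DataFrame,
    lib: LibraryConsensus,
    thresholds: TierThresholds = TierThresholds(),
) -> pd.DataFrame:
    """Attach a ``tier`` column by re-examining the consensus evidence."""
    tiers = [
        assign_tier(collect_evidence(lib, row.position, row.alt), thresholds)
        for row in calls.itertuples()
    ]
    out = calls.copy()
    out["tier"] = tiers
    return out


def annotate_calls(calls: pd.DataFrame, model: ReferenceModel, layout: TargetLayout) -> pd.DataFrame:
    """Attach site class, consequence (category, HGVS strings), and domain."""
    cats, hgvs_c, hgvs_p, aa_idx, domains, site = [], [], [], [], [], []
    for row in calls.itertuples():
        csq = model.consequence(row.position, row.ref, row.alt)
        cats.append(csq.category)
        hgvs_c.append(csq.hgvs_c)
        hgvs_p.append(csq.hgvs_p)
        aa_idx.append(csq.aa_index)
        domains.append(layout.domain_of(csq.aa_index))
        site.append(model.classify_site(row.position))
    out = calls.copy()
    out["site_class"] = site
    out["category"] = cats
    out["hgvs_c"] = hgvs_c
    out["hgvs_p"] = hgvs_p
    out["aa_index"] = pd.array(aa_idx, dtype="Int64")
    out["domain"] = domains
    return out


def mask_snps(
    calls: pd.DataFrame,
    meta: Iterable[LibraryMeta],
    snp_vaf_threshold: float = SNP_VAF_THRESHOLD,
) -> pd.DataFrame:
    """Flag variants present in *all* libraries sharing a donor-pool/target
    combination at VAF >= threshold in each (polymorphisms of the pool)."""
    meta_map = {m.library_id: m for m in meta}
    unknown = set(calls["library_id"]) - set(meta_map)
    if unknown:
        raise KeyError(f"unknown library ids {sorted(unknown)}")
    combo_libs: dict[tuple[str, str], set[str]] = {}
    for m in meta_map.values():
        combo_libs.setdefault((m.donor_pool_id, m.target_set), set()).add(m.library_id)

    out = calls.copy()
    out["flag_snp"] = False
    if out.empty:
        return out
    key = ["position", "ref", "alt"]
    for _, grp in out.groupby(key):
        for combo, libs in combo_libs.items():
            in_combo = grp[grp["library_id"].isin(libs)]
            hits = in_combo[in_combo["vaf"] >= snp_vaf_threshold]
            if len(libs) > 0 and set(hits["library_id"]) == libs:
                out.loc[grp.index[grp["library_id"].isin(libs)], "flag_snp"] = True
    return out


def filter_variants(calls: pd.DataFrame, min_coverage: int = MIN_DCS_COVERAGE) -> pd.DataFrame:
    """Final analysis table.

    Keeps non-intronic, non-SNP calls with DCS coverage >= ``min_coverage``
    that are tier 1, or tier 2 detected more than once (same position/ref/alt
    across the whole analysis set, invariant to library order).
    """
    required = {"tier", "category", "flag_snp"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"calls missing columns {sorted(missing)}; annotate and tier first")
    ok = (
        (calls["category"] != CATEGORY_INTRONIC)
        & ~calls["flag_snp"]
        & (calls["dcs_coverage"] >= min_coverage)
        & calls["tier"].isin([TIER1, TIER2])
    )
    passing = calls[ok]
    n_detect = passing.groupby(["position", "ref", "alt"])["library_id"].transform("size")
    keep = (passing["tier"] == TIER1) | ((passing["tier"] == TIER2) & (n_detect >= 2))
    return passing[keep].reset_index(drop=True)


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------


def write_variant_table(calls: pd.DataFrame, path: str | Path) -> None:
    out = calls.copy()
    out["position"] = out["position"] + 1  # 1-based in reports
    out.to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> pd.DataFrame:
    out = pd.read_csv(path, sep="\t")
    if out.empty:
        return out
    out["position"] = out["position"] - 1
    return out


def write_vcf(calls: pd.DataFrame, model: ReferenceModel, path: str | Path) -> None:
    """VCF-like output: CHROM = transcript name, POS 1-based, one record per
    (library, position, alt)."""
    header = pysam.VariantHeader()
    header.contigs.add(model.name, length=len(model))
    header.info.add("LIB", 1, "String", "Library the call was made in")
    header.info.add("TIER", 1, "String", "Confidence tier")
    header.info.add("VAF", 1, "Float", "Variant allele frequency (alt DCS / DCS coverage)")
    header.info.add("AC", "A", "Integer", "Alternate-supporting DCS count")
    header.info.add("DP", 1, "Integer", "DCS coverage at the position")
    header.info.add("CSQ", 1, "String", "category|hgvs_c|hgvs_p|domain")
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for row in calls.itertuples():
            rec = vf.new_record(
                contig=model.name,
                start=int(row.position),
                stop=int(row.position) + 1,
                alleles=(row.ref, row.alt),
            )
            rec.info["LIB"] = row.library_id
            rec.info["TIER"] = getattr(row, "tier", TIER_LOWER)
            rec.info["VAF"] = float(row.vaf)
            rec.info["AC"] = (int(row.alt_count),)
            rec.info["DP"] = int(row.dcs_coverage)
            csq = "|".join(
                str(getattr(row, f, "") or "") for f in ("category", "hgvs_c", "hgvs_p", "domain")
            )
            rec.info["CSQ"] = csq
            vf.write(rec)
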