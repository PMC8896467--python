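"""dN/dS selection analysis with a spectrum-preserving randomization null.

Nonsynonymous and synonymous site counts follow the Nei-Gojobori method:
each codon position contributes (synonymous single-base changes)/3 synonymous
sites, so every codon carries exactly three sites in total.  dN is the number
of observed nonsynonymous substitutions per nonsynonymous site, dS the
synonymous analogue; stop-creating changes count as nonsynonymous and
splice-region variants are excluded.

The neutral reference distribution is built by placing the observed number of
mutations at random compatible sites of the region, preserving the observed
6-class (optionally 96-context) substitution spectrum, and recomputing dN/dS
each iteration.  Because placements are i.i.d. uniform within a class, the
synonymous tally of an iteration is a per-class binomial draw with the
class's enumerated synonymous fraction — the implementation samples that
binomial directly, which is distributionally identical to materialising the
sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .refmodel import (
    CATEGORY_MISSENSE,
    CATEGORY_STOP_GAINED,
    CATEGORY_SYNONYMOUS,
    ReferenceModel,
    TargetLayout,
)
from .spectra import CLASSES6, class6_index, context96_index

_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"

NONSYN_CATEGORIES = (CATEGORY_MISSENSE, CATEGORY_STOP_GAINED)


@dataclass(frozen=True)
class SiteCounts:
    """Nei-Gojobori fractional site counts (N + S = 3 x codons)."""

    n_sites: float
    s_sites: float


@dataclass
class DnDsResult:
    n_nonsyn: int
    n_syn: int
    dn: float
    ds: float
    ratio: float | None  # None when dS == 0 (undefined, not infinite)
    null_draws: np.ndarray = field(default_factory=lambda: np.empty(0))
    null_median: float = float("nan")
    null_lower: float = float("nan")
    null_upper: float = float("nan")


def _check_sense(cds: str) -> None:
    if len(cds) % 3:
        raise ValueError(f"coding region length {len(cds)} is not a multiple of 3")
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if _CODON_TO_AA.get(codon) in (None, "*"):
            raise ValueError(f"codon {codon!r} at offset {i} is not a sense codon")


def ng_site_counts(cds_region: str) -> SiteCounts:
    """Fractional synonymous/nonsynonymous sites of an in-frame sense-codon
    sequence, by enumeration of the three alternatives at each position."""
    _check_sense(cds_region)
    s_total = 0.0
    for i in range(0, len(cds_region), 3):
        codon = cds_region[i : i + 3]
        aa = _CODON_TO_AA[codon]
        for w in range(3):
            syn = sum(
                1
                for b in "ACGT"
                if b != codon[w] and _CODON_TO_AA[codon[:w] + b + codon[w + 1 :]] == aa
            )
            s_total += syn / 3.0
    return SiteCounts(n_sites=len(cds_region) - s_total, s_sites=s_total)


def dnds(variants: pd.DataFrame, counts: SiteCounts) -> DnDsResult:
    """Observed dN/dS from a variant table carrying a ``category`` column."""
    cats = variants["category"]
    n_nonsyn = int(cats.isin(NONSYN_CATEGORIES).sum())
    n_syn = int((cats == CATEGORY_SYNONYMOUS).sum())
    dn = n_nonsyn / counts.n_sites if counts.n_sites > 0 else 0.0
    ds = n_syn / counts.s_sites if counts.s_sites > 0 else 0.0
    ratio = (dn / ds) if ds > 0 else None
    return DnDsResult(n_nonsyn, n_syn, dn, ds, ratio)


def enumerate_changes(cds_region: str, context: int = 6) -> pd.DataFrame:
    """All 9L/3 single-base changes of the region with their substitution
    class and synonymous status (the exhaustive basis of the null)."""
    _check_sense(cds_region)
    rows = []
    n = len(cds_region)
    for i in range(n):
        codon_i, w = divmod(i, 3)
        codon = cds_region[3 * codon_i : 3 * codon_i + 3]
        aa = _CODON_TO_AA[codon]
        ref = cds_region[i]
        for alt in "ACGT":
            if alt == ref:
                continue
            mutant = codon[:w] + alt + codon[w + 1 :]
            if context == 6:
                cls = class6_index(ref, alt)
            else:
                five = cds_region[i - 1] if i > 0 else None
                three = cds_region[i + 1] if i < n - 1 else None
                if five is None or three is None:
                    continue  # edge positions lack context in 96-mode
                cls = context96_index(ref, alt, five, three)
            rows.append(
                {"position": i, "ref": ref, "alt": alt, "class": cls, "synonymous": _CODON_TO_AA[mutant] == aa}
            )
    return pd.DataFrame(rows)


def dnds_null(
    spectrum_counts: np.ndarray | None,
    cds_region: str,
    n_mutations: int,
    iterations: int = 1000,
    seed: int = 0,
    context: int = 6,
    range_mode: str = "percentile",
) -> DnDsResult:
    """Randomization reference distribution of dN/dS.

    ``spectrum_counts`` weights the substitution classes (the observed
    spectrum); None means uniform over all possible single-base changes of
    the region.  Each iteration places ``n_mutations`` (with replacement)
    and recomputes dN/dS.  ``range_mode`` 'percentile' reports the 2.5/97.5
    percentiles as lower/upper, 'minmax' the extremes of the draws.
    """
    if n_mutations < 1:
        raise ValueError("n_mutations must be >= 1")
    counts = ng_site_counts(cds_region)
    changes = enumerate_changes(cds_region, context=context)
    n_classes = 6 if context == 6 else 96
    m = np.zeros(n_classes, dtype=np.int64)
    syn_frac = np.zeros(n_classes, dtype=float)
    for cls, grp in changes.groupby("class"):
        m[cls] = len(grp)
        syn_frac[cls] = grp["synonymous"].mean()

    if spectrum_counts is None:
        weights = m.astype(float)
    else:
        weights = np.asarray(spectrum_counts, dtype=float)
        if weights.size != n_classes:
            raise ValueError(f"spectrum has {weights.size} classes, expected {n_classes}")
        bad = (weights > 0) & (m == 0)
        if bad.any():
            labels = CLASSES6 if context == 6 else tuple(str(i) for i in range(96))
            raise ValueError(
                f"spectrum class {labels[int(np.flatnonzero(bad)[0])]} has mass but no compatible site"
            )
    p = weights / weights.sum()

    rng = np.random.default_rng(seed)
    draws = np.empty(iterations, dtype=float)
    for i in range(iterations):
        k = rng.multinomial(n_mutations, p)
        syn = int(rng.binomial(k, syn_frac).sum())
        nonsyn = n_mutations - syn
        dn = nonsyn / counts.n_sites
        ds = syn / counts.s_sites if counts.s_sites > 0 else 0.0
        draws[i] = dn / ds if ds > 0 else np.nan
    med = float(np.nanmedian(draws))
    if range_mode == "percentile":
        lo, hi = (float(np.nanpercentile(draws, q)) for q in (2.5, 97.5))
    elif range_mode == "minmax":
        lo, hi = float(np.nanmin(draws)), float(np.nanmax(draws))
    else:
        raise ValueError(f"unknown range_mode {range_mode!r}")
    return DnDsResult(0, 0, float("nan"), float("nan"), None, draws, med, lo, hi)


def targeted_coding_region(
    model: ReferenceModel,
    layout: TargetLayout,
    domain: str | None = None,
) -> str:
    """Concatenated sense codons fully covered by the targeted subregions
    (optionally restricted to one protein domain)."""
    target = layout.target_mask(len(model))
    cds = model.coding_sequence
    n_codons = len(cds) // 3
    aa_iv = dict(layout.domains).get(domain) if domain else None
    kept = []
    for j in range(n_codons):
        if aa_iv and not (aa_iv[0] <= j + 1 <= aa_iv[1]):
            continue
        gpos = model.cds_to_genomic[model.cds_start_offset + 3 * j : model.cds_start_offset + 3 * j + 3]
        if target[gpos].all():
            kept.append(cds[3 * j : 3 * j + 3])
    return "".join(kept)


def dnds_report(
    final_calls: pd.DataFrame,
    model: ReferenceModel,
    layout: TargetLayout,
    age_of: dict[str, str] | None = None,
    iterations: int = 1000,
    seed: int = 0,
    range_mode: str = "percentile",
) -> pd.DataFrame:
    """dN/dS per stratum (all, per domain, per age group, domain x age) with
    the spectrum-preserving randomization null of each stratum.

    A stratum's null preserves that stratum's observed 6-class spectrum and
    mutation count over the domain's targeted codons.  Strata without
    synonymous observations report an undefined ratio; strata without any
    codon-classified variant report an empty row.
    """
    calls = final_calls[final_calls["category"].isin([*NONSYN_CATEGORIES, CATEGORY_SYNONYMOUS])]
    ages = sorted(set(age_of.values())) if age_of else []
    strata: list[tuple[str, str]] = [("all", "all")]
    strata += [(d, "all") for d, _ in layout.domains]
    strata += [("all", a) for a in ages]
    strata += [(d, a) for d, _ in layout.domains for a in ages]

    rng = np.random.default_rng(seed)
    rows = []
    for domain, age in strata:
        sel = calls
        if domain != "all":
            sel = sel[sel["domain"] == domain]
        if age != "all":
            libs = [lib for lib, a in (age_of or {}).items() if a == age]
            sel = sel[sel["library_id"].isin(libs)]
        region = targeted_coding_region(model, layout, None if domain == "all" else domain)
        counts = ng_site_counts(region) if region else SiteCounts(0.0, 0.0)
        obs = dnds(sel, counts) if region else DnDsResult(0, 0, 0.0, 0.0, None)
        n_mut = obs.n_nonsyn + obs.n_syn
        if region and n_mut >= 1:
            cls_counts = np.zeros(6, dtype=np.int64)
            for r in sel.itertuples():
                cls_counts[class6_index(r.ref, r.alt)] += 1
            null = dnds_null(
                cls_counts,
                region,
                n_mut,
                iterations=iterations,
                seed=int(rng.integers(2**31 - 1)),
                range_mode=range_mode,
            )
        else:
            null = DnDsResult(0, 0, float("nan"), float("nan"), None)
        outside = (
            obs.ratio is not None
            and np.isfinite(null.null_lower)
            and not (null.null_lower <= obs.ratio <= null.null_upper)
        )
        rows.append(
            {
                "domain": domain,
                "age_group": age,
                "n_nonsyn": obs.n_nonsyn,
                "n_syn": obs.n_syn,
                "n_sites": counts.n_sites,
                "s_sites": counts.s_sites,
                "dn": obs.dn,
                "ds": obs.ds,
                "dnds": obs.ratio if obs.ratio is not None else np.nan,
                "null_median": null.null_median,
                "null_lower": null.null_lower,
                "null_upper": null.null_upper,
                "outside_null": bool(outside),
            }
        )
    return pd.DataFrame(rows)
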