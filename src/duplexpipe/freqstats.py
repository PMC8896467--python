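"""Mutation-frequency estimation and group comparisons.

The overall mutation frequency (substitutions per sequenced base pair) is

    sum_i variant_count_i / sum_i (mean_coverage_i * region_size_i)

over libraries i, where variant_count_i collapses within-library duplicates
but counts cross-library recurrences once per library, mean_coverage_i is the
mean duplex (DCS) coverage over the in-scope positions of the library's
targets, and region_size_i the number of those positions.  Confidence
intervals are exact (Garwood) Poisson intervals on the count; group tests are
chi-square comparisons of count against exposure with Holm step-down
correction, plus Fisher's exact test for 2x2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .consensus import Pileup
from .refmodel import ReferenceModel, TargetLayout


@dataclass(frozen=True)
class LibrarySummary:
    """The per-library symbols of the mutation-frequency formula."""

    library_id: str
    variant_count: int
    mean_coverage: float
    region_size: int

    @property
    def exposure(self) -> float:
        return self.mean_coverage * self.region_size


@dataclass(frozen=True)
class MutFreqResult:
    frequency: float
    numerator: int
    denominator: float
    ci_low: float
    ci_high: float


def vaf(alt_count: int, coverage: int) -> float:
    """Variant allele frequency: alt-supporting DCS over DCS coverage."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0 <= alt_count <= coverage:
        raise ValueError("alt_count must be in [0, coverage]")
    return alt_count / coverage


def poisson_ci(count: int, exposure: float, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) two-sided interval on the Poisson rate count/exposure."""
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    if count < 0:
        raise ValueError("count must be >= 0")
    if level == 0:
        return (count / exposure, count / exposure)
    alpha = 1.0 - level
    lo = 0.0 if count == 0 else stats.chi2.ppf(alpha / 2, 2 * count) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2
    return (lo / exposure, hi / exposure)


def scope_mask(
    model: ReferenceModel,
    layout: TargetLayout,
    subregions: list[str] | None = None,
    scope: str = "exonic",
) -> np.ndarray:
    """Boolean mask of in-scope positions: targeted and (by default) exonic.

    ``scope`` is 'exonic' (default, matching exonic-variant numerators) or
    'all' (every sequenced position).
    """
    mask = np.zeros(len(model), dtype=bool)
    for name, (s, e) in layout.subregions:
        if subregions is None or name in subregions:
            mask[s:e] = True
    if scope == "exonic":
        mask &= model.site_class == 0
    elif scope != "all":
        raise ValueError(f"unknown scope {scope!r}")
    return mask


def domain_mask(model: ReferenceModel, layout: TargetLayout, domain: str) -> np.ndarray:
    """Exonic positions whose residue lies in the named domain."""
    (aa_s, aa_e) = dict(layout.domains)[domain]
    mask = np.zeros(len(model), dtype=bool)
    exonic = model.cds_index >= 0
    c0 = model.cds_index[exonic] - model.cds_start_offset
    aa = np.where(c0 >= 0, c0 // 3 + 1, 0)
    mask[np.flatnonzero(exonic)[(aa >= aa_s) & (aa <= aa_e)]] = True
    return mask


def library_summary(
    final_calls: pd.DataFrame,
    pile: Pileup,
    model: ReferenceModel,
    layout: TargetLayout,
    library_id: str,
    subregions: list[str] | None = None,
    scope: str = "exonic",
    mask: np.ndarray | None = None,
) -> LibrarySummary:
    """Collapse a library's final calls and coverage into formula terms."""
    if mask is None:
        mask = scope_mask(model, layout, subregions, scope)
    mine = final_calls[final_calls["library_id"] == library_id]
    in_scope = mine[mask[mine["position"].to_numpy(dtype=int)]] if not mine.empty else mine
    count = len(in_scope.drop_duplicates(["position", "ref", "alt"]))
    mean_cov = float(pile.coverage[mask].mean()) if mask.any() else 0.0
    return LibrarySummary(library_id, count, mean_cov, int(mask.sum()))


def mutation_frequency(summaries: list[LibrarySummary], level: float = 0.95) -> MutFreqResult:
    """Pooled frequency over libraries with an exact Poisson interval."""
    if not summaries:
        raise ValueError("at least one library summary required")
    numerator = sum(s.variant_count for s in summaries)
    denominator = sum(s.exposure for s in summaries)
    if denominator <= 0:
        raise ValueError("zero denominator: no sequenced bases")
    lo, hi = poisson_ci(numerator, denominator, level)
    return MutFreqResult(numerator / denominator, numerator, denominator, lo, hi)


def unique_variant_counts(final_calls: pd.DataFrame) -> tuple[int, int, int]:
    """(unique variants, unique positions, per-library-collapsed count).

    The collapsed count sums each library's distinct variants — the numerator
    semantics of the frequency formula."""
    if final_calls.empty:
        return (0, 0, 0)
    uniq = final_calls.drop_duplicates(["position", "ref", "alt"])
    collapsed = len(final_calls.drop_duplicates(["library_id", "position", "ref", "alt"]))
    return (len(uniq), final_calls["position"].nunique(), collapsed)


def frequency_by_group(
    final_calls: pd.DataFrame,
    summaries: dict[str, LibrarySummary],
    groups: dict[str, str],
    level: float = 0.95,
) -> dict[str, MutFreqResult]:
    """Stratify by a per-library label (e.g. age group): numerators and
    denominators restricted to the stratum's libraries."""
    out: dict[str, MutFreqResult] = {}
    for label in sorted(set(groups.values())):
        libs = [lib for lib, g in groups.items() if g == label]
        subs = [summaries[lib] for lib in libs]
        out[label] = mutation_frequency(subs, level)
    return out


def frequency_by_domain(
    final_calls: pd.DataFrame,
    pileups: dict[str, Pileup],
    model: ReferenceModel,
    layout: TargetLayout,
    lib_subregions: dict[str, list[str] | None] | None = None,
    level: float = 0.95,
) -> dict[str, MutFreqResult]:
    """Stratify by protein domain: region_size restricted to the domain
    footprint within each library's targets."""
    out: dict[str, MutFreqResult] = {}
    for domain, _ in layout.domains:
        summaries = []
        for lib, pile in pileups.items():
            subs = None if lib_subregions is None else lib_subregions.get(lib)
            mask = scope_mask(model, layout, subs, "exonic") & domain_mask(model, layout, domain)
            in_dom = final_calls[
                (final_calls["library_id"] == lib) & (final_calls["domain"] == domain)
            ]
            count = len(in_dom.drop_duplicates(["position", "ref", "alt"]))
            mean_cov = float(pile.coverage[mask].mean()) if mask.any() else 0.0
            summaries.append(LibrarySummary(lib, count, mean_cov, int(mask.sum())))
        if any(s.exposure > 0 for s in summaries):
            out[domain] = mutation_frequency([s for s in summaries if s.exposure > 0], level)
        else:
            out[domain] = MutFreqResult(0.0, 0, 0.0, 0.0, 0.0)
    return out


def frequency_by_category(
    final_calls: pd.DataFrame,
    summaries: list[LibrarySummary],
    level: float = 0.95,
) -> dict[str, MutFreqResult]:
    """Stratify numerators by consequence category over the shared denominator."""
    denominator = sum(s.exposure for s in summaries)
    out: dict[str, MutFreqResult] = {}
    for cat, grp in final_calls.groupby("category"):
        n = len(grp.drop_duplicates(["library_id", "position", "ref", "alt"]))
        lo, hi = poisson_ci(n, denominator, level)
        out[str(cat)] = MutFreqResult(n / denominator, n, denominator, lo, hi)
    return out


def pairwise_chisq_holm(strata: dict[str, tuple[int, float]]) -> pd.DataFrame:
    """All pairwise chi-square rate comparisons with Holm correction.

    ``strata`` maps label -> (count, exposure in sequenced bases).  Returns a
    DataFrame with raw and Holm-adjusted p-values, one row per pair."""
    if len(strata) < 2:
        raise ValueError("need at least two strata")
    for label, (_, e) in strata.items():
        if e <= 0:
            raise ValueError(f"stratum {label!r} has zero exposure")
    labels = sorted(strata)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            ca, ea = strata[a]
            cb, eb = strata[b]
            table = np.array([[ca, ea - ca], [cb, eb - cb]], dtype=float)
            if table[:, 0].sum() == 0:
                p = 1.0
            else:
                _, p, _, _ = stats.chi2_contingency(table, correction=False)
            rows.append({"stratum_a": a, "stratum_b": b, "p_raw": float(p)})
    df = pd.DataFrame(rows)
    df["p_holm"] = multipletests(df["p_raw"], method="holm")[1]
    return df


def fisher_2x2(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 count table."""
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integers")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])
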