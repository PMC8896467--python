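"""End-to-end orchestration: simulate -> consensus -> call -> filter -> stats.

A :class:`RunConfig` pins every seed and threshold; a run writes its variant
tables (TSV + VCF-like), frequency/spectra/selection reports, the serialised
config and a log into the output directory, and identical configs produce
byte-identical reports.  Also provides the spike-in dilution evaluation
(detection count and log-log R^2 against ground truth) and the single-strand
vs duplex error-suppression summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import consensus as cns
from . import duplexsim as sim
from . import freqstats as fs
from . import selection as sel
from . import spectra as spc
from . import varcall as vc
from .refmodel import ReferenceModel, TargetLayout, load_reference


@dataclass(frozen=True)
class LibrarySpec:
    """One library of a run: its metadata plus its simulation settings."""

    meta: vc.LibraryMeta
    sim: sim.SimConfig


@dataclass
class RunConfig:
    out_dir: Path
    libraries: list[LibrarySpec]
    reference_fasta: Path | None = None  # None: built-in synthetic gene
    layout_config: Path | None = None
    gene_seed: int = 2021
    consensus: cns.ConsensusParams = field(default_factory=cns.ConsensusParams)
    tiers: vc.TierThresholds = field(default_factory=vc.TierThresholds)
    snp_vaf_threshold: float = vc.SNP_VAF_THRESHOLD
    min_coverage: int = vc.MIN_DCS_COVERAGE
    scope: str = "exonic"  # denominator mode of the frequency formula
    run_spectra: bool = True
    run_selection: bool = True
    iterations: int = 1000
    stats_seed: int = 0
    keep_fastq: bool = True


@dataclass
class PipelineResult:
    out_dir: Path
    model: ReferenceModel
    layout: TargetLayout
    truths: dict[str, sim.GroundTruth]
    pileups: dict[str, cns.Pileup]
    all_calls: pd.DataFrame
    final_calls: pd.DataFrame
    summaries: dict[str, fs.LibrarySummary]
    overall: fs.MutFreqResult | None
    by_age: dict[str, fs.MutFreqResult]
    by_domain: dict[str, fs.MutFreqResult]
    spectrum6: spc.SpectrumMatrix | None
    spectrum96: spc.SpectrumMatrix | None
    dnds_table: pd.DataFrame | None
    error_stats: dict[str, "ErrorSuppression"]


@dataclass(frozen=True)
class ErrorSuppression:
    """Single-strand vs duplex consensus error rates over the targeted region."""

    sscs_bases: int
    sscs_alt: int
    dcs_bases: int
    dcs_alt: int
    sscs_class_counts: dict[str, int]
    dcs_class_counts: dict[str, int]

    @property
    def sscs_freq(self) -> float:
        return self.sscs_alt / self.sscs_bases if self.sscs_bases else 0.0

    @property
    def dcs_freq(self) -> float:
        return self.dcs_alt / self.dcs_bases if self.dcs_bases else 0.0

    @property
    def suppression_ratio(self) -> float:
        """SSCS over DCS variant frequency, with the DCS count floored at one
        event so a clean duplex level yields a finite (conservative) ratio."""
        if self.sscs_bases == 0 or self.dcs_bases == 0:
            return float("nan")
        floor = max(self.dcs_alt, 1) / self.dcs_bases
        return self.sscs_freq / floor


def _fold_matrix(mat: np.ndarray) -> dict[str, int]:
    """4x4 (ref, alt) count matrix -> pyrimidine-folded 6-class counts."""
    out = {}
    for label in spc.CLASSES6:
        r, a = label[0], label[2]
        ri, ai = "ACGT".index(r), "ACGT".index(a)
        rc, ac = 3 - ri, 3 - ai
        out[label] = int(mat[ri, ai] + mat[rc, ac])
    return dict(out)


def error_suppression_summary(
    lib: cns.LibraryConsensus, model: ReferenceModel, layout: TargetLayout
) -> ErrorSuppression:
    target = layout.target_mask(len(model))
    sscs_p = cns.sscs_pileup(lib, model)
    dcs_p = cns.dcs_pileup(lib, model)
    ref = model.codes

    def tally(p: cns.Pileup) -> tuple[int, int]:
        bases = int(p.coverage[target].sum())
        alts = int(p.alt_counts(ref)[target].sum())
        return bases, alts

    sb, sa = tally(sscs_p)
    db, da = tally(dcs_p)
    return ErrorSuppression(
        sb, sa, db, da,
        _fold_matrix(cns.substitution_matrix(sscs_p, model)),
        _fold_matrix(cns.substitution_matrix(dcs_p, model)),
    )


def _resolve_reference(cfg: RunConfig) -> tuple[ReferenceModel, TargetLayout]:
    if cfg.reference_fasta is not None:
        return load_reference(cfg.reference_fasta, cfg.layout_config)
    return sim.synthetic_gene(cfg.gene_seed)


def _config_json(cfg: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    return json.dumps(dataclasses.asdict(cfg), default=default, indent=2, sort_keys=True)


def process_library(
    lib: sim.SimulatedLibrary,
    model: ReferenceModel,
    layout: TargetLayout,
    params: cns.ConsensusParams,
    tiers: vc.TierThresholds,
) -> tuple[cns.LibraryConsensus, cns.Pileup, pd.DataFrame]:
    """Consensus, pileup and tier-annotated calls for one simulated library."""
    libcons = cns.consensus_library(lib.r1_path, lib.r2_path, model, layout, params, lib.library_id)
    pile = cns.dcs_pileup(libcons, model)
    calls = vc.call_variants(pile, model, lib.library_id)
    calls = vc.assign_tiers(calls, libcons, tiers)
    calls = vc.annotate_calls(calls, model, layout)
    return libcons, pile, calls


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full analysis over the configured libraries."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_json = _config_json(cfg)
    (out_dir / "run_config.json").write_text(cfg_json)
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
    log_lines = [f"config_hash\t{cfg_hash}"]

    model, layout = _resolve_reference(cfg)
    fastq_dir = out_dir / "fastq"

    truths: dict[str, sim.GroundTruth] = {}
    pileups: dict[str, cns.Pileup] = {}
    error_stats: dict[str, ErrorSuppression] = {}
    call_frames: list[pd.DataFrame] = []
    lib_subregions: dict[str, list[str] | None] = {}

    for spec in cfg.libraries:
        lid = spec.meta.library_id
        simulated = sim.simulate_library(spec.sim, model, layout, fastq_dir, lid)
        truths[lid] = simulated.truth
        libcons, pile, calls = process_library(simulated, model, layout, cfg.consensus, cfg.tiers)
        pileups[lid] = pile
        error_stats[lid] = error_suppression_summary(libcons, model, layout)
        call_frames.append(calls)
        lib_subregions[lid] = list(spec.sim.subregions) if spec.sim.subregions else None
        log_lines.append(
            f"library\t{lid}\tseed={spec.sim.seed}\tread_pairs={simulated.truth.n_read_pairs}"
            f"\tdiscarded={libcons.n_discarded_pairs}\tcalls={len(calls)}"
        )
        if not cfg.keep_fastq:
            simulated.r1_path.unlink()
            simulated.r2_path.unlink()

    all_calls = (
        pd.concat(call_frames, ignore_index=True)
        if call_frames
        else vc.call_variants(cns.empty_pileup(model), model)
    )
    metas = [spec.meta for spec in cfg.libraries]
    all_calls = vc.mask_snps(all_calls, metas, cfg.snp_vaf_threshold)
    final = vc.filter_variants(all_calls, cfg.min_coverage)

    summaries = {
        spec.meta.library_id: fs.library_summary(
            final,
            pileups[spec.meta.library_id],
            model,
            layout,
            spec.meta.library_id,
            subregions=lib_subregions[spec.meta.library_id],
            scope=cfg.scope,
        )
        for spec in cfg.libraries
    }
    overall = fs.mutation_frequency(list(summaries.values())) if summaries else None
    ages = {m.library_id: m.age_group for m in metas}
    by_age = (
        fs.frequency_by_group(final, summaries, ages) if len(set(ages.values())) > 1 else {}
    )
    by_domain = (
        fs.frequency_by_domain(final, pileups, model, layout, lib_subregions)
        if layout.domains
        else {}
    )

    exonic_mask = fs.scope_mask(model, layout, None, "exonic")
    spectrum6 = spectrum96 = None
    if cfg.run_spectra and not final.empty:
        spectrum6 = spc.spectrum(final, model, 6, exonic_mask)
        spectrum96 = spc.spectrum(final, model, 96, exonic_mask)
    dnds_table = None
    if cfg.run_selection:
        dnds_table = sel.dnds_report(
            final, model, layout, ages, iterations=cfg.iterations, seed=cfg.stats_seed
        )

    # ---- reports -------------------------------------------------------
    vc.write_variant_table(all_calls, out_dir / "calls_all.tsv")
    vc.write_variant_table(final, out_dir / "variants_final.tsv")
    vc.write_vcf(final, model, out_dir / "variants_final.vcf")
    sum_df = pd.DataFrame(
        [dataclasses.asdict(s) for s in summaries.values()],
        columns=["library_id", "variant_count", "mean_coverage", "region_size"],
    )
    sum_df.to_csv(out_dir / "library_summaries.tsv", sep="\t", index=False)
    freq_rows = []
    if overall is not None:
        freq_rows.append({"stratum": "all", **dataclasses.asdict(overall)})
    freq_rows += [{"stratum": f"age:{k}", **dataclasses.asdict(v)} for k, v in by_age.items()]
    freq_rows += [{"stratum": f"domain:{k}", **dataclasses.asdict(v)} for k, v in by_domain.items()]
    pd.DataFrame(freq_rows).to_csv(out_dir / "mutation_frequencies.tsv", sep="\t", index=False)
    if spectrum6 is not None:
        spectrum6.write(out_dir / "spectrum6.tsv")
        spectrum96.write(out_dir / "spectrum96.tsv")
    if dnds_table is not None:
        dnds_table.to_csv(out_dir / "dnds.tsv", sep="\t", index=False)
    err_df = pd.DataFrame(
        [
            {
                "library_id": lid,
                "sscs_bases": e.sscs_bases,
                "sscs_alt": e.sscs_alt,
                "sscs_freq": e.sscs_freq,
                "dcs_bases": e.dcs_bases,
                "dcs_alt": e.dcs_alt,
                "dcs_freq": e.dcs_freq,
                "suppression_ratio": e.suppression_ratio,
            }
            for lid, e in error_stats.items()
        ]
    )
    err_df.to_csv(out_dir / "error_suppression.tsv", sep="\t", index=False)
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")

    return PipelineResult(
        out_dir=out_dir,
        model=model,
        layout=layout,
        truths=truths,
        pileups=pileups,
        all_calls=all_calls,
        final_calls=final,
        summaries=summaries,
        overall=overall,
        by_age=by_age,
        by_domain=by_domain,
        spectrum6=spectrum6,
        spectrum96=spectrum96,
        dnds_table=dnds_table,
        error_stats=error_stats,
    )


# --------------------------------------------------------------------------
# spike-in evaluation
# --------------------------------------------------------------------------


@dataclass
class SpikeinEval:
    detected: int
    total: int
    r2_log: float | None
    r2_linear: float | None
    table: pd.DataFrame


def spikein_evaluation(
    truths: dict[str, sim.GroundTruth], final_calls: pd.DataFrame
) -> SpikeinEval:
    """Per spiked variant: detected in the final table? measured vs expected VAF.

    R^2 is the squared Pearson correlation between log10 expected (realised
    molecular fraction) and log10 measured VAF over detected variants; it is
    undefined (None) below two detections.  Variants whose carrier draw was
    zero are legal truth rows and count as undetectable."""
    rows = []
    for lid, truth in truths.items():
        for t in truth.variants.itertuples():
            hit = final_calls[
                (final_calls["library_id"] == lid)
                & (final_calls["position"] == t.position)
                & (final_calls["alt"] == t.alt)
            ]
            detected = not hit.empty
            rows.append(
                {
                    "library_id": lid,
                    "position": t.position,
                    "ref": t.ref,
                    "alt": t.alt,
                    "nominal_fraction": t.fraction,
                    "expected_vaf": t.expected_vaf,
                    "detected": detected,
                    "measured_vaf": float(hit["vaf"].iloc[0]) if detected else np.nan,
                    "alt_count": int(hit["alt_count"].iloc[0]) if detected else 0,
                    "dcs_coverage": int(hit["dcs_coverage"].iloc[0]) if detected else 0,
                }
            )
    table = pd.DataFrame(rows)
    det = table[table["detected"] & (table["expected_vaf"] > 0)]
    r2_log = r2_lin = None
    if len(det) >= 2:
        x, y = det["expected_vaf"].to_numpy(), det["measured_vaf"].to_numpy()
        r2_log = float(sps.pearsonr(np.log10(x), np.log10(y))[0] ** 2)
        r2_lin = float(sps.pearsonr(x, y)[0] ** 2)
    return SpikeinEval(int(table["detected"].sum()), len(table), r2_log, r2_lin, table)


def vaf_recovery(eval_table: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Check each detected spiked variant against the exact binomial interval
    of its measured count at the realised coverage: does the interval cover
    the expected molecular fraction?"""
    a = (1 - level) / 2
    rows = []
    for t in eval_table[eval_table["detected"]].itertuples():
        k, n = t.alt_count, t.dcs_coverage
        lo = 0.0 if k == 0 else float(sps.beta.ppf(a, k, n - k + 1))
        hi = 1.0 if k == n else float(sps.beta.ppf(1 - a, k + 1, n - k))
        rows.append(
            {
                "library_id": t.library_id,
                "position": t.position,
                "alt": t.alt,
                "expected_vaf": t.expected_vaf,
                "measured_vaf": t.measured_vaf,
                "ci_low": lo,
                "ci_high": hi,
                "covered": lo <= t.expected_vaf <= hi,
            }
        )
    return pd.DataFrame(rows)


def spikein_run_config(
    out_dir: str | Path,
    seed: int,
    n_molecules: int = 22800,
    dilutions: tuple[float, ...] = (0.1, 0.01, 0.001, 0.0001),
) -> tuple[RunConfig, tuple[float, ...]]:
    """RunConfig for the four-library spike-in series (shared donor pool and
    target region, four variants per library)."""
    model, layout = sim.synthetic_gene()
    positions = [sim.genomic_of_cds(model, c) for c, _ in sim.DEFAULT_SPIKE_CDS]
    subs = tuple(sorted({layout.subregion_of(p) for p in positions}))
    libraries = []
    for i, d in enumerate(dilutions):
        variants = tuple(
            sim.cds_substitution(model, c, alt, d) for c, alt in sim.DEFAULT_SPIKE_CDS
        )
        cfg = sim.SimConfig(
            seed=seed + i,
            n_molecules=n_molecules,
            true_variants=variants,
            subregions=subs,
        )
        meta = vc.LibraryMeta(f"spike_{d:g}", "pool_YC", "younger", "Up")
        libraries.append(LibrarySpec(meta, cfg))
    return (
        RunConfig(out_dir=Path(out_dir), libraries=libraries, keep_fastq=False),
        dilutions,
    )
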