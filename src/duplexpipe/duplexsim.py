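"""Synthetic duplex-sequencing library generator.

Produces paired FASTQ files carrying double barcodes (duplex tags) plus a
ground-truth record, emulating the statistical structure a duplex consensus
pipeline assumes:

* each source molecule yields two read families, one per strand, with the
  duplex tag pair in opposite order on the two strands;
* true mutations are present on both strands of carrier molecules;
* strand-asymmetric DNA damage (oxo-G-type ``G>T`` and deamination ``C>T``)
  sits on exactly one strand of a molecule and therefore on every read of
  that strand's family;
* PCR errors arise at a duplication step of a branching amplification tree
  and propagate to a 2^-cycle fraction of the family's reads (jackpots);
* independent per-base sequencing errors are applied to each mate.

Also provides :func:`synthetic_gene`, a deterministic FGFR3-like reference
(synthetic stand-in for the real gene, which is not bundled) whose pinned
codons reproduce the well-known substitutions discussed in the analysis
(p.R248C, p.S249C, p.P250R, p.A334T, p.Y373C, p.G380R, p.N540K).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._seqcodes import CODE_TO_ASCII, encode, revcomp
from .refmodel import ReferenceModel, TargetLayout

# --------------------------------------------------------------------------
# synthetic reference gene
# --------------------------------------------------------------------------

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
]

#: codon number (1-based) -> pinned codon, chosen so that the corresponding
#: single-base changes reproduce known receptor-kinase substitutions
PINNED_CODONS = {
    1: "ATG",
    248: "CGC",  # c.742C>T -> p.R248C
    249: "TCC",  # c.746C>G -> p.S249C
    250: "CCG",  # c.749C>G -> p.P250R
    334: "GCT",  # c.1000G>A -> p.A334T
    373: "TAC",  # c.1118A>G -> p.Y373C
    380: "GGG",  # c.1138G>A -> p.G380R
    540: "AAC",  # c.1620C>A / c.1620C>G -> p.N540K
}

_N_CODONS = 806
_INTRON_LEN = 170
_CDS_BREAKS = [180, 360, 540, 702, 1020, 1200, 1380, 1560, 1740, 1920, 2100, 2280]
_SUBREGION_NAMES = [f"Up{i}" for i in range(1, 6)] + [f"Down{i}" for i in range(1, 6)]


def synthetic_gene(seed: int = 2021) -> tuple[ReferenceModel, TargetLayout]:
    """Deterministic synthetic FGFR3-like gene: 806 sense codons over 13 exons,
    12 introns of 170 bp, and a ten-subregion layout of 4405 targeted positions.

    Domain intervals (IgI-III, TM_inter-domain, TK) follow the coarse cartoon
    granularity of receptor-tyrosine-kinase domain maps; exact boundaries are
    assumptions of this synthetic model.
    """
    rng = np.random.default_rng(seed)
    codons = list(rng.choice(_SENSE_CODONS, size=_N_CODONS))
    for i, codon in PINNED_CODONS.items():
        codons[i - 1] = codon
    cds = "".join(codons)

    def intron() -> str:
        mid = "".join(rng.choice(list("ACGT"), size=_INTRON_LEN - 4))
        return "GT" + mid + "AG"

    pieces, exons, pos, prev = [], [], 0, 0
    for brk in [*_CDS_BREAKS, len(cds)]:
        pieces.append(cds[prev:brk])
        exons.append((pos, pos + (brk - prev)))
        pos += brk - prev
        if brk < len(cds):
            pieces.append(intron())
            pos += _INTRON_LEN
        prev = brk
    sequence = "".join(pieces)

    widths = [441, 440] * 5  # sums to 4405 targeted positions
    subregions, start = [], 0
    for name, w in zip(_SUBREGION_NAMES, widths):
        subregions.append((name, (start, start + w)))
        start += w
    layout = TargetLayout(
        subregions=subregions,
        domains=[("IgI-III", (1, 360)), ("TM_inter-domain", (361, 450)), ("TK", (451, 806))],
    )
    model = ReferenceModel(
        name="FGFR3_synthetic",
        sequence=sequence,
        exons=exons,
        cds_start_offset=0,
        splice_pad=2,
        minus_strand_gene=True,
    )
    layout.validate_against(model)
    return model, layout


def genomic_of_cds(model: ReferenceModel, c_position: int) -> int:
    """Genomic 0-based position of a 1-based CDS coordinate."""
    return int(model.cds_to_genomic[model.cds_start_offset + c_position - 1])


# --------------------------------------------------------------------------
# configuration and ground truth
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrueVariant:
    """A planted substitution at a molecular fraction."""

    position: int  # genomic, 0-based
    ref: str
    alt: str
    fraction: float


def cds_substitution(model: ReferenceModel, c_position: int, alt: str, fraction: float) -> TrueVariant:
    """Convenience constructor from a 1-based CDS coordinate."""
    pos = genomic_of_cds(model, c_position)
    return TrueVariant(pos, model.sequence[pos], alt, fraction)


#: default spike-in set: three known Coriell-line substitutions plus p.A334T,
#: all within one targeted subregion (Up4)
DEFAULT_SPIKE_CDS = ((742, "T"), (746, "G"), (749, "G"), (1000, "A"))


@dataclass(frozen=True)
class SimConfig:
    """All knobs of one simulated library.

    Rates are probabilities per applicable base; ``damage_rate_deam`` applies to
    each C of one strand (read as C>T on that strand, G>A on the complementary
    pileup), ``damage_rate_oxoG`` to each G of one strand (G>T / C>A).  Defaults
    emulate the study's libraries: ~11,000 duplex consensus reads per position
    and a single-strand consensus artifact frequency of ~5e-5 per base.
    """

    seed: int = 0
    n_molecules: int = 22800
    family_size_law: tuple = ("geometric", 6.0)
    tag_length: int = 12
    true_variants: tuple[TrueVariant, ...] = ()
    damage_rate_oxoG: float = 5e-5
    damage_rate_deam: float = 1.5e-4
    pcr_error_rate: float = 1e-6
    pcr_cycles: int = 8
    seq_error_rate: float = 1e-3
    read_length: int | None = None  # None: mates span the whole subregion
    subregions: tuple[str, ...] | None = None  # None: all in the layout

    def __post_init__(self) -> None:
        for name in ("damage_rate_oxoG", "damage_rate_deam", "pcr_error_rate", "seq_error_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        for v in self.true_variants:
            if not 0.0 <= v.fraction <= 1.0:
                raise ValueError(f"variant fraction {v.fraction} outside [0, 1]")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.tag_length < 1:
            raise ValueError("tag_length must be >= 1")


@dataclass
class GroundTruth:
    """What the generator actually planted, per library."""

    library_id: str
    n_molecules: dict[str, int]
    family_sizes: dict[str, np.ndarray]  # subregion -> (n_molecules, 2) read pairs per strand
    tags: dict[str, np.ndarray]  # subregion -> (n_molecules, 2) S<tag_length> arrays
    variants: pd.DataFrame  # subregion, position, ref, alt, fraction, carriers, expected_vaf
    lesions: pd.DataFrame  # subregion, position, strand, kind, molecule
    n_read_pairs: int = 0

    def write(self, path: str | Path) -> None:
        self.variants.to_csv(path, sep="\t", index=False)


@dataclass
class SimulatedLibrary:
    library_id: str
    r1_path: Path
    r2_path: Path
    truth: GroundTruth
    config: SimConfig


# --------------------------------------------------------------------------
# simulation internals
# --------------------------------------------------------------------------


def _draw_family_sizes(rng: np.random.Generator, law: tuple, shape) -> np.ndarray:
    kind = law[0]
    if kind == "geometric":
        mean = float(law[1])
        if mean < 1.0:
            raise ValueError("geometric family-size mean must be >= 1")
        return rng.geometric(1.0 / mean, size=shape).astype(np.int64)
    if kind == "fixed":
        return np.full(shape, int(law[1]), dtype=np.int64)
    if kind == "lognormal":
        mean, sigma = float(law[1]), float(law[2])
        mu = np.log(mean) - sigma**2 / 2
        return np.maximum(1, np.round(rng.lognormal(mu, sigma, size=shape))).astype(np.int64)
    raise ValueError(f"unknown family_size_law {law!r}")


def _apply_lesions(
    rng: np.random.Generator,
    template: np.ndarray,
    base_code: int,
    alt_code: int,
    rate: float,
) -> np.ndarray:
    """Mutate ``base_code`` positions of a (molecules x L) strand template at
    the given per-base rate.  Returns (molecule, position) pairs actually hit."""
    if rate <= 0.0:
        return np.empty((0, 2), dtype=np.int64)
    rows, cols = np.nonzero(template == base_code)
    if rows.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    k = rng.binomial(rows.size, rate)
    if k == 0:
        return np.empty((0, 2), dtype=np.int64)
    hit = rng.choice(rows.size, size=k, replace=False)
    template[rows[hit], cols[hit]] = alt_code
    return np.stack([rows[hit], cols[hit]], axis=1)


def _apply_pcr_jackpots(
    rng: np.random.Generator,
    frag: np.ndarray,
    sizes: np.ndarray,
    length: int,
    rate: float,
    cycles: int,
) -> None:
    """Branching-tree PCR errors applied by lineage sampling.

    A copy made at cycle ``c`` carries its new errors into a 2^-c fraction of
    the final pool; each of the family's sampled reads inherits such an error
    independently with that probability.  Equivalent in distribution to
    materialising the full duplication tree.
    """
    if rate <= 0.0 or cycles < 1:
        return
    n_dup = 2**cycles - 1
    lam = length * rate * n_dup
    counts = rng.poisson(lam, size=sizes.size)
    fams = np.flatnonzero(counts)
    if fams.size == 0:
        return
    starts = np.concatenate([[0], np.cumsum(sizes)])
    # a duplication at cycle c is one of 2^(c-1) events that cycle
    cycle_w = 2.0 ** np.arange(cycles, dtype=np.float64)
    cycle_p = cycle_w / cycle_w.sum()
    for f in fams:
        for _ in range(counts[f]):
            c = 1 + int(rng.choice(cycles, p=cycle_p))
            pos = rng.integers(length)
            k = sizes[f]
            carried = np.flatnonzero(rng.random(k) < 2.0**-c)
            if carried.size == 0:
                continue
            rows = starts[f] + carried
            alt = (frag[rows[0], pos] + rng.integers(1, 4)) % 4
            frag[rows, pos] = alt


def _inject_seq_errors(rng: np.random.Generator, mat: np.ndarray, rate: float) -> None:
    if rate <= 0.0 or mat.size == 0:
        return
    k = rng.binomial(mat.size, rate)
    if k == 0:
        return
    flat = rng.integers(0, mat.size, size=k)
    shift = rng.integers(1, 4, size=k).astype(np.uint8)
    mat.flat[flat] = (mat.flat[flat] + shift) % 4


def _digits(start: int, n: int, width: int = 8) -> np.ndarray:
    idx = np.arange(start, start + n, dtype=np.int64)
    powers = 10 ** np.arange(width - 1, -1, -1, dtype=np.int64)
    return (idx[:, None] // powers % 10 + ord("0")).astype(np.uint8)


def _write_fastq_block(
    fh,
    prefix: bytes,
    start_index: int,
    seq_ascii: np.ndarray,
) -> None:
    """Append constant-width FASTQ records: header ``@<prefix><index>``,
    sequence, ``+``, constant Q37 quality."""
    n, lr = seq_ascii.shape
    head = np.frombuffer(b"@" + prefix, dtype=np.uint8)
    rec_w = 1 + len(prefix) + 8 + 1 + lr + 1 + 2 + lr + 1
    rec = np.empty((n, rec_w), dtype=np.uint8)
    o = 0
    rec[:, o : o + head.size] = head
    o += head.size
    rec[:, o : o + 8] = _digits(start_index, n)
    o += 8
    rec[:, o] = ord("\n")
    o += 1
    rec[:, o : o + lr] = seq_ascii
    o += lr
    rec[:, o] = ord("\n")
    rec[:, o + 1] = ord("+")
    rec[:, o + 2] = ord("\n")
    o += 3
    rec[:, o : o + lr] = ord("F")  # constant Q37
    rec[:, o + lr] = ord("\n")
    fh.write(rec.tobytes())


def _random_tags(rng: np.random.Generator, n: int, tag_length: int) -> np.ndarray:
    """(n, 2) ASCII tag array, one tag pair per molecule."""
    codes = rng.integers(0, 4, size=(n, 2, tag_length), dtype=np.uint8)
    return CODE_TO_ASCII[codes]


# --------------------------------------------------------------------------
# public entry points
# --------------------------------------------------------------------------


def simulate_library(
    cfg: SimConfig,
    model: ReferenceModel,
    layout: TargetLayout,
    out_dir: str | Path,
    library_id: str = "lib",
) -> SimulatedLibrary:
    """Simulate one duplex library and write ``<library_id>_R1/_R2.fastq``.

    Deterministic for a fixed config (byte-identical FASTQ).  Returns the file
    paths plus the ground truth (realised carrier counts, lesion positions,
    family sizes and tag pairs).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    sub_names = [n for n, _ in layout.subregions]
    if cfg.subregions is not None:
        missing = set(cfg.subregions) - set(sub_names)
        if missing:
            raise KeyError(f"unknown subregions {sorted(missing)}")
        sub_names = [n for n in sub_names if n in cfg.subregions]

    r1_path = out_dir / f"{library_id}_R1.fastq"
    r2_path = out_dir / f"{library_id}_R2.fastq"
    var_rows: list[dict] = []
    lesion_rows: list[dict] = []
    fam_sizes: dict[str, np.ndarray] = {}
    tags_by_sub: dict[str, np.ndarray] = {}
    n_pairs_total = 0

    with open(r1_path, "wb") as fh1, open(r2_path, "wb") as fh2:
        for sub in sub_names:
            s, e = layout.subregion(sub)
            length = e - s
            rl = length if cfg.read_length is None else min(cfg.read_length, length)
            n = cfg.n_molecules
            ref = model.codes[s:e]
            top = np.tile(ref, (n, 1))

            planted = [v for v in cfg.true_variants if s <= v.position < e]
            seen_pos = set()
            for v in planted:
                if v.position in seen_pos:
                    raise ValueError(f"duplicate planted position {v.position}")
                seen_pos.add(v.position)
                col = v.position - s
                if model.sequence[v.position] != v.ref:
                    raise ValueError(
                        f"planted ref {v.ref!r} does not match reference "
                        f"{model.sequence[v.position]!r} at {v.position}"
                    )
                carriers = np.flatnonzero(rng.random(n) < v.fraction)
                top[carriers, col] = encode(v.alt)[0]
                var_rows.append(
                    {
                        "library_id": library_id,
                        "subregion": sub,
                        "position": v.position,
                        "ref": v.ref,
                        "alt": v.alt,
                        "fraction": v.fraction,
                        "carriers": carriers.size,
                        "n_molecules": n,
                        "expected_vaf": carriers.size / n,
                    }
                )
            bot = top.copy()

            # strand-asymmetric damage, expressed in reference orientation
            Ac, Cc, Gc, Tc = 0, 1, 2, 3
            for strand_name, template, spec in (
                ("top", top, ((Cc, Tc, cfg.damage_rate_deam, "deam"), (Gc, Tc, cfg.damage_rate_oxoG, "oxoG"))),
                ("bottom", bot, ((Gc, Ac, cfg.damage_rate_deam, "deam"), (Cc, Ac, cfg.damage_rate_oxoG, "oxoG"))),
            ):
                for base, alt, rate, kind in spec:
                    hits = _apply_lesions(rng, template, base, alt, rate)
                    for mol, col in hits:
                        lesion_rows.append(
                            {
                                "library_id": library_id,
                                "subregion": sub,
                                "position": int(s + col),
                                "strand": strand_name,
                                "kind": kind,
                                "molecule": int(mol),
                            }
                        )

            sizes = _draw_family_sizes(rng, cfg.family_size_law, (n, 2))
            fam_sizes[sub] = sizes
            tags = _random_tags(rng, n, cfg.tag_length)
            tags_by_sub[sub] = tags

            for strand in (0, 1):
                template = top if strand == 0 else bot
                ksz = sizes[:, strand]
                frag = np.repeat(template, ksz, axis=0)
                _apply_pcr_jackpots(rng, frag, ksz, length, cfg.pcr_error_rate, cfg.pcr_cycles)
                m1 = frag.copy()
                _inject_seq_errors(rng, m1, cfg.seq_error_rate)
                m2 = frag
                _inject_seq_errors(rng, m2, cfg.seq_error_rate)

                tag_a = np.repeat(tags[:, 0], ksz, axis=0)
                tag_b = np.repeat(tags[:, 1], ksz, axis=0)
                if strand == 0:
                    # top: R1 reads the fragment in reference orientation
                    r1 = np.concatenate([tag_a, CODE_TO_ASCII[m1[:, :rl]]], axis=1)
                    r2 = np.concatenate([tag_b, CODE_TO_ASCII[revcomp(m2)[:, :rl]]], axis=1)
                    ori = b"FR"
                else:
                    # bottom: R1 reads the complementary strand 5'->3'
                    r1 = np.concatenate([tag_b, CODE_TO_ASCII[revcomp(m1)[:, :rl]]], axis=1)
                    r2 = np.concatenate([tag_a, CODE_TO_ASCII[m2[:, :rl]]], axis=1)
                    ori = b"RF"
                prefix = f"{library_id}:{sub}:".encode() + ori + b":"
                _write_fastq_block(fh1, prefix, n_pairs_total, r1)
                _write_fastq_block(fh2, prefix, n_pairs_total, r2)
                n_pairs_total += r1.shape[0]

    truth = GroundTruth(
        library_id=library_id,
        n_molecules={sub: cfg.n_molecules for sub in sub_names},
        family_sizes=fam_sizes,
        tags=tags_by_sub,
        variants=pd.DataFrame(
            var_rows,
            columns=[
                "library_id",
                "subregion",
                "position",
                "ref",
                "alt",
                "fraction",
                "carriers",
                "n_molecules",
                "expected_vaf",
            ],
        ),
        lesions=pd.DataFrame(
            lesion_rows,
            columns=["library_id", "subregion", "position", "strand", "kind", "molecule"],
        ),
        n_read_pairs=n_pairs_total,
    )
    return SimulatedLibrary(library_id, r1_path, r2_path, truth, cfg)


def simulate_spikein_series(
    base_cfg: SimConfig,
    model: ReferenceModel,
    layout: TargetLayout,
    out_dir: str | Path,
    dilutions: tuple[float, ...] = (0.1, 0.01, 0.001, 0.0001),
    spike_cds: tuple[tuple[int, str], ...] = DEFAULT_SPIKE_CDS,
) -> list[SimulatedLibrary]:
    """One library per dilution, all spiking the same variants at that
    molecular fraction (mirrors a serial mixing experiment).

    All libraries share the same donor background; the spiked positions must be
    distinct.  Returns one :class:`SimulatedLibrary` per dilution.
    """
    positions = [genomic_of_cds(model, c) for c, _ in spike_cds]
    if len(set(positions)) != len(positions):
        raise ValueError("spiked positions must be distinct")
    libs = []
    for i, d in enumerate(dilutions):
        if not 0.0 < d < 1.0:
            raise ValueError(f"dilution {d} outside (0, 1)")
        variants = tuple(cds_substitution(model, c, alt, d) for c, alt in spike_cds)
        subs = {layout.subregion_of(p) for p in positions}
        cfg = replace(
            base_cfg,
            seed=base_cfg.seed + i,
            true_variants=variants,
            subregions=tuple(sorted(subs)),
        )
        libs.append(simulate_library(cfg, model, layout, out_dir, library_id=f"spike_{d:g}"))
    return libs
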