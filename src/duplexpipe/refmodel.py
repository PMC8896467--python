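"""Reference model for a targeted coding region.

Holds the gene sequence (in transcript/CDS orientation), its exon structure,
the targeted-subregion layout and protein-domain intervals, and provides site
classification (exonic / splice_region / intronic) and codon-level consequence
calls for single-base substitutions.

Coordinates are 0-based half-open internally; HGVS-like ``c.`` / ``p.`` strings
in reports are 1-based.  Analyses run in CDS orientation throughout; whether
the gene sits on the genomic minus strand is recorded as a flag only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

from ._seqcodes import encode

SITE_EXONIC = "exonic"
SITE_SPLICE = "splice_region"
SITE_INTRONIC = "intronic"

CATEGORY_SYNONYMOUS = "synonymous"
CATEGORY_MISSENSE = "missense"
CATEGORY_STOP_GAINED = "stop_gained"
CATEGORY_SPLICE = "splice_region"
CATEGORY_INTRONIC = "intronic"


@dataclass(frozen=True)
class Consequence:
    """Codon-level interpretation of a substitution.

    ``category`` is one of synonymous / missense / stop_gained / splice_region /
    intronic.  ``hgvs_c`` and ``hgvs_p`` are HGVS-like strings (``c.1138G>A``,
    ``p.G380R``); they are empty for non-exonic sites.  ``aa_index`` is the
    1-based residue number for exonic substitutions, else None.
    """

    category: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    aa_index: int | None = None
    ref_aa: str = ""
    alt_aa: str = ""

    @property
    def is_exonic(self) -> bool:
        return self.category in (CATEGORY_SYNONYMOUS, CATEGORY_MISSENSE, CATEGORY_STOP_GAINED)

    @property
    def is_nonsynonymous(self) -> bool:
        # stop-gained changes count as nonsynonymous for selection analyses
        return self.category in (CATEGORY_MISSENSE, CATEGORY_STOP_GAINED)


class LayoutError(ValueError):
    """Invalid reference/layout configuration."""


@dataclass
class ReferenceModel:
    """Gene sequence plus exon structure and coordinate maps."""

    name: str
    sequence: str
    exons: list[tuple[int, int]]
    cds_start_offset: int = 0
    splice_pad: int = 2
    minus_strand_gene: bool = False

    codes: np.ndarray = field(init=False, repr=False)
    site_class: np.ndarray = field(init=False, repr=False)  # 0 exonic, 1 splice, 2 intronic
    cds_index: np.ndarray = field(init=False, repr=False)  # genomic -> exon-concatenation index, -1 outside
    cds_to_genomic: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        bad = [i for i, b in enumerate(self.sequence) if b not in "ACGT"]
        if bad:
            raise LayoutError(f"non-ACGT character {self.sequence[bad[0]]!r} at position {bad[0]}")
        if self.cds_start_offset < 0 or self.splice_pad < 0:
            raise LayoutError("cds_start_offset and splice_pad must be >= 0")
        n = len(self.sequence)
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e <= n):
                raise LayoutError(f"exon interval ({s}, {e}) outside sequence of length {n}")
            if s <= prev_end:
                raise LayoutError("exon intervals must be sorted and non-overlapping")
            prev_end = e
        self.codes = encode(self.sequence)
        self.site_class = np.full(n, 2, dtype=np.int8)
        self.cds_index = np.full(n, -1, dtype=np.int64)
        pos = 0
        for s, e in self.exons:
            self.site_class[max(0, s - self.splice_pad) : s] = np.minimum(
                self.site_class[max(0, s - self.splice_pad) : s], 1
            )
            self.site_class[e : e + self.splice_pad] = np.minimum(self.site_class[e : e + self.splice_pad], 1)
            self.site_class[s:e] = 0
            self.cds_index[s:e] = np.arange(pos, pos + (e - s))
            pos += e - s
        self.cds_to_genomic = np.flatnonzero(self.cds_index >= 0)

    def __len__(self) -> int:
        return len(self.sequence)

    # -- coding sequence ---------------------------------------------------
    @property
    def coding_sequence(self) -> str:
        """Concatenated exon sequence from the codon-frame start, trimmed to full codons."""
        cat = "".join(self.sequence[s:e] for s, e in self.exons)
        cds = cat[self.cds_start_offset :]
        return cds[: len(cds) - len(cds) % 3]

    def classify_site(self, pos: int) -> str:
        """Partition a genomic position into exonic / splice_region / intronic."""
        if not 0 <= pos < len(self.sequence):
            raise IndexError(f"position {pos} outside sequence of length {len(self.sequence)}")
        return (SITE_EXONIC, SITE_SPLICE, SITE_INTRONIC)[self.site_class[pos]]

    def c_position(self, pos: int) -> int | None:
        """1-based CDS coordinate of an exonic genomic position (None outside the frame)."""
        idx = self.cds_index[pos]
        if idx < 0:
            return None
        c0 = idx - self.cds_start_offset
        return int(c0) + 1 if c0 >= 0 else None

    def consequence(self, pos: int, ref: str, alt: str) -> Consequence:
        """Classify the substitution ``ref>alt`` at genomic position ``pos``.

        Raises on a reference mismatch; returns an intronic/splice_region
        consequence (empty HGVS strings) for non-exonic sites and a codon-level
        call with ``c.``/``p.`` notation for exonic ones.
        """
        if self.sequence[pos] != ref:
            raise ValueError(
                f"reference mismatch at {pos}: expected {self.sequence[pos]!r}, got {ref!r}"
            )
        if ref == alt or alt not in "ACGT":
            raise ValueError(f"invalid substitution {ref}>{alt}")
        cls = self.classify_site(pos)
        if cls == SITE_INTRONIC:
            return Consequence(CATEGORY_INTRONIC)
        if cls == SITE_SPLICE:
            return Consequence(CATEGORY_SPLICE)
        cpos = self.c_position(pos)
        if cpos is None:
            # exonic but upstream of the codon frame: no protein consequence
            return Consequence(CATEGORY_SPLICE)
        c0 = cpos - 1
        codon_i, within = divmod(c0, 3)
        cds = self.coding_sequence
        if 3 * codon_i + 3 > len(cds):
            raise ValueError(f"position {pos} falls in an incomplete terminal codon")
        codon = cds[3 * codon_i : 3 * codon_i + 3]
        if codon[within] != ref:
            raise AssertionError("codon map inconsistent with sequence")  # pragma: no cover
        mutant = codon[:within] + alt + codon[within + 1 :]
        ref_aa = str(Seq(codon).translate())
        alt_aa = str(Seq(mutant).translate())
        hgvs_c = f"c.{cpos}{ref}>{alt}"
        hgvs_p = f"p.{ref_aa}{codon_i + 1}{alt_aa}"
        if alt_aa == "*":
            category = CATEGORY_STOP_GAINED
        elif alt_aa == ref_aa:
            category = CATEGORY_SYNONYMOUS
        else:
            category = CATEGORY_MISSENSE
        return Consequence(category, hgvs_c, hgvs_p, codon_i + 1, ref_aa, alt_aa)


@dataclass
class TargetLayout:
    """Targeted subregions (sequencing units) and protein-domain intervals.

    Subregions are named half-open genomic intervals (e.g. ten ~500 bp
    sequencing units).  Domains are named 1-based inclusive amino-acid intervals.
    ``region_size`` is the number of targeted (sequenced) positions.
    """

    subregions: list[tuple[str, tuple[int, int]]]
    domains: list[tuple[str, tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.subregions]
        if len(set(names)) != len(names):
            raise LayoutError("subregion names must be unique")
        for n, (s, e) in self.subregions:
            if s >= e:
                raise LayoutError(f"empty subregion interval for {n!r}")
        ivals = sorted(iv for _, iv in self.domains)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise LayoutError("domain intervals must be non-overlapping")

    @property
    def region_size(self) -> int:
        return sum(e - s for _, (s, e) in self.subregions)

    def subregion(self, name: str) -> tuple[int, int]:
        for n, iv in self.subregions:
            if n == name:
                return iv
        raise KeyError(name)

    def subregion_of(self, pos: int) -> str | None:
        for n, (s, e) in self.subregions:
            if s <= pos < e:
                return n
        return None

    def target_mask(self, n: int) -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        for _, (s, e) in self.subregions:
            mask[s:e] = True
        return mask

    def domain_of(self, aa_index: int | None) -> str | None:
        """Domain containing a 1-based residue index, or None."""
        if aa_index is None:
            return None
        for name, (s, e) in self.domains:
            if s <= aa_index <= e:
                return name
        return None

    def validate_against(self, model: ReferenceModel) -> None:
        n = len(model)
        for name, (s, e) in self.subregions:
            if not (0 <= s < e <= n):
                raise LayoutError(f"subregion {name!r} interval ({s}, {e}) outside sequence of length {n}")
        n_aa = len(model.coding_sequence) // 3
        for name, (s, e) in self.domains:
            if not (1 <= s <= e <= n_aa):
                raise LayoutError(f"domain {name!r} interval ({s}, {e}) outside protein of {n_aa} residues")


def load_reference(fasta_path: str | Path, layout_config: str | Path) -> tuple[ReferenceModel, TargetLayout]:
    """Load a single-record FASTA plus a YAML layout config.

    The config supplies ``exons`` (list of [start, end]), optional
    ``cds_start_offset``, ``splice_pad``, ``minus_strand_gene``, ``subregions``
    (mapping name -> [start, end]) and ``domains`` (mapping name ->
    [aa_start, aa_end], 1-based inclusive).  All intervals are validated
    against the sequence on load.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise LayoutError(f"expected exactly one FASTA record, found {len(records)}")
    with open(layout_config) as fh:
        cfg = yaml.safe_load(fh)
    model = ReferenceModel(
        name=cfg.get("name", records[0].id),
        sequence=str(records[0].seq).upper(),
        exons=[tuple(iv) for iv in cfg.get("exons", [])],
        cds_start_offset=int(cfg.get("cds_start_offset", 0)),
        splice_pad=int(cfg.get("splice_pad", 2)),
        minus_strand_gene=bool(cfg.get("minus_strand_gene", False)),
    )
    layout = TargetLayout(
        subregions=[(str(n), tuple(iv)) for n, iv in cfg.get("subregions", {}).items()],
        domains=[(str(n), tuple(iv)) for n, iv in cfg.get("domains", {}).items()],
    )
    layout.validate_against(model)
    return model, layout


def write_layout(model: ReferenceModel, layout: TargetLayout, fasta_path: str | Path, config_path: str | Path) -> None:
    """Serialise a model/layout pair to FASTA + YAML (inverse of load_reference)."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{model.name}\n")
        for i in range(0, len(model.sequence), 70):
            fh.write(model.sequence[i : i + 70] + "\n")
    cfg = {
        "name": model.name,
        "cds_start_offset": model.cds_start_offset,
        "splice_pad": model.splice_pad,
        "minus_strand_gene": model.minus_strand_gene,
        "exons": [[int(s), int(e)] for s, e in model.exons],
        "subregions": {n: [int(s), int(e)] for n, (s, e) in layout.subregions},
        "domains": {n: [int(s), int(e)] for n, (s, e) in layout.domains},
    }
    with open(config_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
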