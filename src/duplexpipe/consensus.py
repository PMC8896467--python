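"""Single-strand (SSCS) and duplex (DCS) consensus building.

Reads carrying duplex tags are grouped into families keyed by the canonical
(sorted) tag pair; the two orders of the pair distinguish the two strands of
the source molecule.  Per strand, a single-strand consensus keeps a base only
where it is supported by strictly more than a ``majority`` fraction of non-N
observations; the duplex consensus then keeps only positions where the two
strand consensuses agree on a non-N base.  A single-strand artifact (DNA
lesion, early-cycle PCR jackpot) therefore becomes N in the duplex consensus.

Two surfaces are provided: a scalar, object-per-family API used for small
inputs and as the reference in tests (:func:`group_families`,
:func:`build_sscs`, :func:`build_dcs`, :func:`pileup`), and a vectorised batch
path (:func:`consensus_library`) that processes whole FASTQ pairs.  Mates of a
read pair are first merged into one fragment observation (disagreements
become N), so the family size unit is the read pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._seqcodes import ASCII_TO_CODE, N, decode, encode, revcomp
from .refmodel import ReferenceModel, TargetLayout


@dataclass(frozen=True)
class ConsensusParams:
    """Thresholds of the consensus caller (config-exposed, logged by the pipeline)."""

    tag_length: int = 12
    min_family_size: int = 3  # read pairs per strand
    majority: float = 0.7  # strict: support must exceed this fraction


# --------------------------------------------------------------------------
# scalar API
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TaggedReadPair:
    """One read pair, tags already split off, fragment in reference orientation."""

    tag1: str
    tag2: str
    fragment: str
    subregion: str = ""


@dataclass
class DuplexFamily:
    family_key: tuple[str, str]
    strand_a_reads: list[str] = field(default_factory=list)  # tag order == family_key
    strand_b_reads: list[str] = field(default_factory=list)  # tag order reversed
    subregion: str = ""


@dataclass(frozen=True)
class SSCS:
    sequence: str
    family_size: int
    support: tuple[float, ...]
    family_key: tuple[str, str] | None = None
    strand: str | None = None


@dataclass(frozen=True)
class DCS:
    sequence: str
    family_key: tuple[str, str] | None = None
    subregion: str = ""


def group_families(read_pairs: Sequence[TaggedReadPair]) -> tuple[list[DuplexFamily], int]:
    """Partition read pairs into duplex families by canonical tag pair.

    Pairs whose tags contain N (or whose two tags are identical, leaving the
    strand ambiguous) are discarded; the second return value counts them.
    """
    families: dict[tuple[str, str, str], DuplexFamily] = {}
    discarded = 0
    for rp in read_pairs:
        if "N" in rp.tag1 or "N" in rp.tag2 or rp.tag1 == rp.tag2:
            discarded += 1
            continue
        key = (min(rp.tag1, rp.tag2), max(rp.tag1, rp.tag2))
        fam = families.setdefault((*key, rp.subregion), DuplexFamily(key, subregion=rp.subregion))
        if (rp.tag1, rp.tag2) == key:
            fam.strand_a_reads.append(rp.fragment)
        else:
            fam.strand_b_reads.append(rp.fragment)
    return list(families.values()), discarded


def build_sscs(
    reads: Sequence[str],
    min_family_size: int = 3,
    majority: float = 0.7,
    family_key: tuple[str, str] | None = None,
    strand: str | None = None,
) -> SSCS | None:
    """Per-position majority consensus over one strand family.

    Returns None (rejection) for families below ``min_family_size``.  A base is
    kept only if its count strictly exceeds ``majority`` x (non-N observations)
    at that position; ties at the threshold yield N.
    """
    if len(reads) < min_family_size:
        return None
    lengths = {len(r) for r in reads}
    if len(lengths) != 1:
        raise ValueError(f"reads differ in length: {sorted(lengths)}")
    mat = np.stack([encode(r) for r in reads])
    counts = np.stack([(mat == c).sum(axis=0) for c in range(4)])
    depth = counts.sum(axis=0)
    top = counts.argmax(axis=0)
    topc = counts.max(axis=0)
    keep = (depth > 0) & (topc > majority * depth)
    cons = np.where(keep, top, N).astype(np.uint8)
    support = np.where(keep & (depth > 0), topc / np.maximum(depth, 1), 0.0)
    return SSCS(decode(cons), len(reads), tuple(support.tolist()), family_key, strand)


def build_dcs(sscs_fwd: SSCS, sscs_rev: SSCS) -> DCS:
    """Join two complementary strand consensuses: agreement kept, else N."""
    if sscs_fwd.family_key != sscs_rev.family_key:
        raise ValueError(
            f"family keys differ: {sscs_fwd.family_key!r} vs {sscs_rev.family_key!r}"
        )
    a, b = encode(sscs_fwd.sequence), encode(sscs_rev.sequence)
    if a.size != b.size:
        raise ValueError("strand consensuses differ in length")
    out = np.where((a == b) & (a != N), a, N).astype(np.uint8)
    return DCS(decode(out), sscs_fwd.family_key)


@dataclass
class Pileup:
    """Per-position duplex coverage and allele counts over the gene.

    ``coverage[p]`` counts non-N DCS bases; ``counts[c, p]`` the DCS calls of
    base code c.  The allele counts sum to the coverage at every position.
    """

    coverage: np.ndarray  # (gene_length,)
    counts: np.ndarray  # (4, gene_length)

    @property
    def gene_length(self) -> int:
        return self.coverage.size

    def alt_counts(self, ref_codes: np.ndarray) -> np.ndarray:
        """Non-reference call count per position."""
        ref_calls = self.counts[ref_codes, np.arange(self.gene_length)]
        return self.coverage - ref_calls


def empty_pileup(model: ReferenceModel) -> Pileup:
    n = len(model)
    return Pileup(np.zeros(n, dtype=np.int64), np.zeros((4, n), dtype=np.int64))


def pileup(dcs_set: Sequence[DCS], model: ReferenceModel, layout: TargetLayout) -> Pileup:
    """Accumulate duplex consensuses (scalar API) into a per-position pileup."""
    out = empty_pileup(model)
    for d in dcs_set:
        try:
            s, e = layout.subregion(d.subregion)
        except KeyError:
            raise ValueError(f"DCS subregion {d.subregion!r} not in layout") from None
        codes = encode(d.sequence)
        if codes.size != e - s:
            raise ValueError("DCS length does not match its subregion")
        ok = codes != N
        pos = np.arange(s, e)[ok]
        out.coverage[pos] += 1
        out.counts[codes[ok], pos] += 1
    return out


# --------------------------------------------------------------------------
# batch path
# --------------------------------------------------------------------------


@dataclass
class SubregionConsensus:
    """Vectorised consensus state for one targeted subregion.

    ``dcs`` holds one row per duplex family with both strand consensuses
    accepted; ``strand_cons``/``strand_support``/``strand_depth`` are indexed
    [strand, family, position] and back the tier evidence of the variant
    caller.  ``sscs_cons``/``sscs_sizes`` cover *all* accepted single-strand
    consensuses, including unpaired ones, for single-strand-level statistics.
    """

    name: str
    start: int
    length: int
    family_keys: np.ndarray  # (n_fam,) bytes keys
    fam_sizes: np.ndarray  # (n_fam, 2) read pairs per strand
    dcs: np.ndarray  # (n_fam, L) uint8
    strand_cons: np.ndarray  # (2, n_fam, L) uint8
    strand_support: np.ndarray  # (2, n_fam, L) uint16 count of consensus base
    strand_depth: np.ndarray  # (2, n_fam, L) uint16 non-N observations
    sscs_cons: np.ndarray  # (n_sscs, L) uint8
    sscs_sizes: np.ndarray  # (n_sscs,)
    n_read_pairs: int = 0
    n_discarded_pairs: int = 0


@dataclass
class LibraryConsensus:
    library_id: str
    params: ConsensusParams
    subregions: dict[str, SubregionConsensus]

    @property
    def n_discarded_pairs(self) -> int:
        return sum(s.n_discarded_pairs for s in self.subregions.values())


def _read_fastq_lines(path: str | Path) -> tuple[list[bytes], list[bytes]]:
    lines = Path(path).read_bytes().split(b"\n")
    while lines and not lines[-1]:
        lines.pop()
    if len(lines) % 4:
        raise ValueError(f"{path}: truncated FASTQ")
    return lines[0::4], lines[1::4]


def _merge_mates(
    seq1: np.ndarray, seq2: np.ndarray, ori: np.ndarray, length: int
) -> np.ndarray:
    """Combine oriented mates into fragment observations over [0, length).

    ``ori`` is 0 for FR pairs (mate1 reference-oriented) and 1 for RF.  An
    F-oriented mate covers the subregion start, an R-oriented mate its end;
    where both mates cover a position and disagree the observation is N.
    """
    n, rl = seq1.shape
    obs1 = np.full((n, length), N, dtype=np.uint8)
    obs2 = np.full((n, length), N, dtype=np.uint8)
    fr = ori == 0
    rf = ~fr
    # mate1
    obs1[fr, :rl] = seq1[fr]
    obs1[rf, length - rl :] = revcomp(seq1[rf])
    # mate2
    obs2[fr, length - rl :] = revcomp(seq2[fr])
    obs2[rf, :rl] = seq2[rf]
    out = np.where(obs1 == obs2, obs1, np.where(obs1 == N, obs2, np.where(obs2 == N, obs1, N)))
    return out.astype(np.uint8)


def _group_consensus(
    obs: np.ndarray, inv: np.ndarray, n_groups: int, majority: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-group majority consensus over sorted fragment observations.

    Returns (consensus codes, support count, non-N depth, group sizes)."""
    order = np.argsort(inv, kind="stable")
    obs_sorted = obs[order]
    sizes = np.bincount(inv, minlength=n_groups)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    L = obs.shape[1]
    counts = np.empty((4, n_groups, L), dtype=np.uint16)
    for c in range(4):
        counts[c] = np.add.reduceat((obs_sorted == c).astype(np.uint16), starts, axis=0)
    depth = counts.sum(axis=0, dtype=np.uint16)
    top = counts.argmax(axis=0).astype(np.uint8)
    topc = counts.max(axis=0)
    keep = (depth > 0) & (topc.astype(np.float64) > majority * depth.astype(np.float64))
    cons = np.where(keep, top, N).astype(np.uint8)
    support = np.where(keep, topc, 0).astype(np.uint16)
    return cons, support, depth, sizes


def _consensus_subregion(
    sub: str,
    start: int,
    length: int,
    t1: np.ndarray,
    t2: np.ndarray,
    seq1: np.ndarray,
    seq2: np.ndarray,
    ori: np.ndarray,
    params: ConsensusParams,
) -> SubregionConsensus:
    n_pairs_in = t1.shape[0]
    # tags with N (or equal pair: strand ambiguous) are discarded
    has_n = (t1 == ord("N")).any(axis=1) | (t2 == ord("N")).any(axis=1)
    same = (t1 == t2).all(axis=1)
    keep = ~(has_n | same)
    t1, t2, seq1, seq2, ori = t1[keep], t2[keep], seq1[keep], seq2[keep], ori[keep]
    n_discarded = int(n_pairs_in - keep.sum())

    obs = _merge_mates(seq1, seq2, ori, length)

    # canonical family key: sorted tag pair; strand: order of observation
    tl = params.tag_length
    t1v = np.ascontiguousarray(t1).view(f"S{tl}").ravel()
    t2v = np.ascontiguousarray(t2).view(f"S{tl}").ravel()
    swap = t1v > t2v
    lo = np.where(swap[:, None], t2, t1)
    hi = np.where(swap[:, None], t1, t2)
    strand = swap.astype(np.uint8)  # 0: tags already sorted, 1: reversed
    gkey = np.concatenate([lo, hi, strand[:, None] + ord("0")], axis=1)
    gview = np.ascontiguousarray(gkey).view(f"S{gkey.shape[1]}").ravel()
    uniq, inv = np.unique(gview, return_inverse=True)
    cons, support, depth, sizes = _group_consensus(obs, inv, uniq.size, params.majority)

    accepted = sizes >= params.min_family_size
    fam_of_group = np.array([k[:-1] for k in uniq], dtype=f"S{2 * tl}")
    strand_of_group = np.array([k[-1:] == b"1" for k in uniq])

    # all accepted SSCS (for single-strand-level statistics)
    sscs_cons = cons[accepted]
    sscs_sizes = sizes[accepted]

    # pair strand groups into duplex families
    acc_idx = np.flatnonzero(accepted)
    fams, fam_inv = np.unique(fam_of_group[acc_idx], return_inverse=True)
    slot = np.full((fams.size, 2), -1, dtype=np.int64)
    slot[fam_inv, strand_of_group[acc_idx].astype(np.int64)] = acc_idx
    both = (slot >= 0).all(axis=1)
    g0, g1 = slot[both, 0], slot[both, 1]
    c0, c1 = cons[g0], cons[g1]
    dcs = np.where((c0 == c1) & (c0 != N), c0, N).astype(np.uint8)

    return SubregionConsensus(
        name=sub,
        start=start,
        length=length,
        family_keys=fams[both],
        fam_sizes=np.stack([sizes[g0], sizes[g1]], axis=1),
        dcs=dcs,
        strand_cons=np.stack([c0, c1]),
        strand_support=np.stack([support[g0], support[g1]]),
        strand_depth=np.stack([depth[g0], depth[g1]]),
        sscs_cons=sscs_cons,
        sscs_sizes=sscs_sizes,
        n_read_pairs=n_pairs_in,
        n_discarded_pairs=n_discarded,
    )


def consensus_library(
    r1_path: str | Path,
    r2_path: str | Path,
    model: ReferenceModel,
    layout: TargetLayout,
    params: ConsensusParams = ConsensusParams(),
    library_id: str = "lib",
) -> LibraryConsensus:
    """Run SSCS and DCS consensus over a paired FASTQ library.

    Read names are expected to carry the anchoring produced by a mapper (here
    the simulator): ``lib:subregion:ORI:index`` with ORI in {FR, RF}.
    """
    names1, seqs1 = _read_fastq_lines(r1_path)
    _, seqs2 = _read_fastq_lines(r2_path)
    if len(seqs1) != len(seqs2):
        raise ValueError("R1/R2 read counts differ")

    by_sub: dict[str, list[int]] = {}
    oris: list[int] = []
    for i, name in enumerate(names1):
        parts = name.split(b":")
        if len(parts) < 4:
            raise ValueError(f"unparseable read name {name!r}")
        by_sub.setdefault(parts[1].decode(), []).append(i)
        oris.append(0 if parts[2] == b"FR" else 1)
    ori_arr = np.array(oris, dtype=np.uint8)

    subs: dict[str, SubregionConsensus] = {}
    for sub, idx in by_sub.items():
        s, e = layout.subregion(sub)  # KeyError for unknown anchors
        idx_a = np.array(idx)
        m1 = np.frombuffer(b"".join([seqs1[i] for i in idx]), dtype=np.uint8).reshape(len(idx), -1)
        m2 = np.frombuffer(b"".join([seqs2[i] for i in idx]), dtype=np.uint8).reshape(len(idx), -1)
        t1, t2 = m1[:, : params.tag_length], m2[:, : params.tag_length]
        seq1 = ASCII_TO_CODE[m1[:, params.tag_length :]]
        seq2 = ASCII_TO_CODE[m2[:, params.tag_length :]]
        subs[sub] = _consensus_subregion(
            sub, s, e - s, t1, t2, seq1, seq2, ori_arr[idx_a], params
        )
    return LibraryConsensus(library_id, params, subs)


def dcs_pileup(lib: LibraryConsensus, model: ReferenceModel) -> Pileup:
    """Duplex pileup over the gene: coverage counts non-N DCS bases."""
    out = empty_pileup(model)
    for sub in lib.subregions.values():
        pos = np.arange(sub.start, sub.start + sub.length)
        for c in range(4):
            out.counts[c, pos] += (sub.dcs == c).sum(axis=0)
    out.coverage = out.counts.sum(axis=0)
    return out


def sscs_pileup(lib: LibraryConsensus, model: ReferenceModel) -> Pileup:
    """Single-strand-consensus pileup (all accepted SSCS, both strands)."""
    out = empty_pileup(model)
    for sub in lib.subregions.values():
        pos = np.arange(sub.start, sub.start + sub.length)
        for c in range(4):
            out.counts[c, pos] += (sub.sscs_cons == c).sum(axis=0)
    out.coverage = out.counts.sum(axis=0)
    return out


def substitution_matrix(pile: Pileup, model: ReferenceModel) -> np.ndarray:
    """4x4 matrix of (ref base code, called base code) counts, diagonal zero."""
    mat = np.zeros((4, 4), dtype=np.int64)
    pos = np.arange(len(model))
    for r in range(4):
        at_r = model.codes == r
        for a in range(4):
            if a != r:
                mat[r, a] = pile.counts[a, pos[at_r]].sum()
    return mat
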