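"""Mutational spectra: 6-class and 96-trinucleotide-context matrices,
strand-assigned spectra, opportunity-normalised frequencies, and cosine
similarity with a bootstrap reference distribution.

Substitutions are folded to the six pyrimidine-centred classes (C>A, C>G,
C>T, T>A, T>C, T>G) by reverse-complementing purine-reference changes; the
96-channel signature adds the 5' and 3' neighbouring bases.  Opportunities
record how many reference bases (or trinucleotide contexts) in the region
could have produced each class, which normalises class frequencies:

    freq_type = count_type / (n_ref_allele/region_size * sum_i mean_cov_i * region_size_i)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cosine as _cosine_dist

from ._seqcodes import COMP, encode
from .freqstats import LibrarySummary
from .refmodel import ReferenceModel

CLASSES6 = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_PYRIMIDINES = {1, 3}  # C, T codes


def _fold(ref_code: int, alt_code: int) -> tuple[int, int, bool]:
    """Fold to pyrimidine-centred (ref, alt); last element: was folded."""
    if ref_code in _PYRIMIDINES:
        return ref_code, alt_code, False
    return int(COMP[ref_code]), int(COMP[alt_code]), True


def class6_index(ref: str, alt: str) -> int:
    """Index of a substitution in the fixed 6-class order."""
    r, a, _ = _fold(encode(ref)[0], encode(alt)[0])
    label = f"{'ACGT'[r]}>{'ACGT'[a]}"
    return CLASSES6.index(label)


def context96_labels() -> list[str]:
    """Fixed 96-channel order: classes in CLASSES6 order, contexts A<C<G<T."""
    out = []
    for cls in CLASSES6:
        for p in "ACGT":
            for q in "ACGT":
                out.append(f"{p}[{cls}]{q}")
    return out


_LABELS96 = context96_labels()


def context96_index(ref: str, alt: str, five: str, three: str) -> int:
    """96-channel index; the context is reverse-complemented when folding."""
    r0, a0 = encode(ref)[0], encode(alt)[0]
    r, a, folded = _fold(r0, a0)
    if folded:
        p, q = "ACGT"[COMP[encode(three)[0]]], "ACGT"[COMP[encode(five)[0]]]
    else:
        p, q = five, three
    label = f"{p}[{'ACGT'[r]}>{'ACGT'[a]}]{q}"
    return _LABELS96.index(label)


@dataclass
class SpectrumMatrix:
    """Counts plus opportunities in a fixed category space (6 or 96)."""

    labels: tuple[str, ...]
    counts: np.ndarray  # int64
    opportunities: np.ndarray  # int64: reference bases/contexts in the region
    region_size: int

    @property
    def context(self) -> int:
        return len(self.labels)

    @property
    def relative(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": self.labels, "count": self.counts, "opportunity": self.opportunities}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _opportunities6(model: ReferenceModel, mask: np.ndarray) -> np.ndarray:
    codes = model.codes[mask]
    n_cg = int(((codes == 1) | (codes == 2)).sum())
    n_ta = int(((codes == 3) | (codes == 0)).sum())
    # three classes share each pyrimidine-centred reference base
    return np.array([n_cg, n_cg, n_cg, n_ta, n_ta, n_ta], dtype=np.int64)


def _opportunities96(model: ReferenceModel, mask: np.ndarray) -> np.ndarray:
    opp = np.zeros(96, dtype=np.int64)
    inner = np.flatnonzero(mask)
    inner = inner[(inner > 0) & (inner < len(model) - 1)]
    for pos in inner:
        r = int(model.codes[pos])
        five = model.sequence[pos - 1]
        three = model.sequence[pos + 1]
        # the three classes of this reference base share the context count
        for alt_code in range(4):
            if alt_code == r:
                continue
            opp[context96_index("ACGT"[r], "ACGT"[alt_code], five, three)] += 1
    return opp


def spectrum(
    variants: pd.DataFrame,
    model: ReferenceModel,
    context: int = 6,
    mask: np.ndarray | None = None,
) -> SpectrumMatrix:
    """Build a spectrum from a variant table (position/ref/alt columns).

    ``mask`` selects the opportunity region (default: the whole sequence);
    each table row counts once.  In 96-context mode a variant at the sequence
    edge (no flanking base) is an error."""
    if context not in (6, 96):
        raise ValueError("context must be 6 or 96")
    if mask is None:
        mask = np.ones(len(model), dtype=bool)
    if context == 6:
        counts = np.zeros(6, dtype=np.int64)
        for row in variants.itertuples():
            counts[class6_index(row.ref, row.alt)] += 1
        return SpectrumMatrix(CLASSES6, counts, _opportunities6(model, mask), int(mask.sum()))
    counts = np.zeros(96, dtype=np.int64)
    for row in variants.itertuples():
        pos = int(row.position)
        if pos <= 0 or pos >= len(model) - 1:
            raise ValueError(f"position {pos} lacks trinucleotide context")
        counts[
            context96_index(row.ref, row.alt, model.sequence[pos - 1], model.sequence[pos + 1])
        ] += 1
    return SpectrumMatrix(tuple(_LABELS96), counts, _opportunities96(model, mask), int(mask.sum()))


def marginalize96(spec96: SpectrumMatrix) -> SpectrumMatrix:
    """Collapse a 96-channel spectrum onto the 6 classes exactly."""
    counts = spec96.counts.reshape(6, 16).sum(axis=1)
    opp = spec96.opportunities.reshape(6, 16).sum(axis=1)
    return SpectrumMatrix(CLASSES6, counts, opp, spec96.region_size)


def cpg_transition_count(spec96: SpectrumMatrix) -> int:
    """Marginal count of C>T transitions in CpG context (N[C>T]G channels)."""
    idx = [i for i, lab in enumerate(spec96.labels) if "[C>T]G" in lab]
    return int(spec96.counts[idx].sum())


def strand_spectrum(variants: pd.DataFrame, model: ReferenceModel) -> pd.DataFrame:
    """Class counts split by the strand carrying the folded pyrimidine.

    The analysis runs in transcript orientation, so a pyrimidine reference
    base sits on the coding (untranscribed) strand; purine-reference changes
    fold onto the transcribed strand."""
    counts = np.zeros((6, 2), dtype=np.int64)
    for row in variants.itertuples():
        ref_code = encode(row.ref)[0]
        col = 1 if ref_code in _PYRIMIDINES else 0
        counts[class6_index(row.ref, row.alt), col] += 1
    return pd.DataFrame(counts, index=list(CLASSES6), columns=["transcribed", "untranscribed"])


def normalized_frequency_spectrum(
    matrix: SpectrumMatrix, summaries: list[LibrarySummary]
) -> np.ndarray:
    """Per-class mutation frequency normalised by class opportunity."""
    exposure = sum(s.exposure for s in summaries)
    if exposure <= 0:
        raise ValueError("zero exposure")
    out = np.zeros(matrix.context, dtype=float)
    for k in range(matrix.context):
        if matrix.opportunities[k] == 0:
            if matrix.counts[k] > 0:
                raise ValueError(
                    f"class {matrix.labels[k]} has {matrix.counts[k]} counts but zero opportunity"
                )
            continue
        out[k] = matrix.counts[k] / (matrix.opportunities[k] / matrix.region_size * exposure)
    return out


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Standard cosine similarity of two nonnegative spectra."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("spectra live in different category spaces")
    if not a.any() or not b.any():
        raise ValueError("cosine undefined for a zero spectrum")
    return float(1.0 - _cosine_dist(a, b))


@dataclass
class CosineBootstrap:
    """Observed cosine plus the bootstrap reference distribution."""

    observed: float | None
    draws: np.ndarray
    n: int

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.draws, q))


def bootstrap_cosine_reference(
    reference: np.ndarray,
    n: int,
    iterations: int = 1000,
    seed: int = 0,
    resample_both: bool = False,
) -> CosineBootstrap:
    """Expected cosine-similarity distribution for a reference spectrum.

    Each iteration resamples ``n`` mutations from the reference's category
    distribution and takes the cosine against the original reference (or, with
    ``resample_both``, against an independent resample of the same size).
    Deterministic for a fixed seed."""
    reference = np.asarray(reference, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    total = reference.sum()
    if total <= 0:
        raise ValueError("reference spectrum has no mass")
    p = reference / total
    rng = np.random.default_rng(seed)
    draws = np.empty(iterations, dtype=float)
    for i in range(iterations):
        sample = rng.multinomial(n, p)
        other = rng.multinomial(n, p) if resample_both else reference
        draws[i] = cosine_similarity(sample, other)
    return CosineBootstrap(None, draws, n)


def cosine_with_bootstrap(
    query: np.ndarray,
    reference: np.ndarray,
    iterations: int = 1000,
    seed: int = 0,
    resample_both: bool = False,
) -> CosineBootstrap:
    """Observed cosine of query vs reference plus the bootstrap null at the
    query's mutation count."""
    query = np.asarray(query, dtype=float)
    n = int(round(query.sum()))
    boot = bootstrap_cosine_reference(reference, max(n, 1), iterations, seed, resample_both)
    return CosineBootstrap(cosine_similarity(query, reference), boot.draws, boot.n)
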