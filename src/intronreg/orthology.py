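"""Orthologous exon mapping and intron length-conservation analysis.

Coding exons of two orthologous genes are compared by translated local
alignment (every pair of exons, best over the 3x3 reading-frame
combinations, BLOSUM62 with affine gaps) and paired by reciprocal best hit.
Genes whose exons form the identity mapping over equal exon counts have
*identical exon-intron structure*, the prerequisite for comparing intron
lengths ordinal by ordinal between species.

Length conservation is measured as the ratio of the longer over the shorter
orthologous intron (ratio 1 = perfectly conserved).  Introns no longer than
a cutoff (default 500 bp) in both species are excluded, since conservation
of short introns may only reflect a general tendency toward compact
introns.  First-intron ratios are compared to other-intron ratios with a
two-sided Mann-Whitney U test, and to a random-pair null built by permuting
the species-B genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 50.0
LENGTH_CONSERVATION_CUTOFF = 500  # bp; at least one species must exceed it


@dataclass
class AlignmentParams:
    """Translated-alignment configuration (BLOSUM62, affine gaps)."""

    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_score: float = DEFAULT_MIN_SCORE


@dataclass
class ExonCorrespondence:
    """Reciprocal-best exon pairing between two orthologous genes."""

    pairs: list[tuple[int, int, float]]  # (exon index in A, in B, score), 0-based
    n_exons_a: int
    n_exons_b: int

    @property
    def is_one_to_one(self) -> bool:
        """True iff kept pairs are a strictly monotone bijection of all exons."""
        if len(self.pairs) != self.n_exons_a or self.n_exons_a != self.n_exons_b:
            return False
        ordered = sorted(self.pairs)
        return all(i == k and j == k for k, (i, j, _) in enumerate(ordered))

    @property
    def is_identical_structure(self) -> bool:
        # A strictly monotone bijection over equal exon counts is the
        # identity mapping, so the two notions coincide here.
        return self.is_one_to_one


@dataclass
class LengthRatioRecord:
    gene_a: str
    gene_b: str
    intron_index: int  # 1-based transcriptional ordinal
    length_a: int
    length_b: int

    @property
    def ratio(self) -> float:
        return intron_length_ratio(self.length_a, self.length_b)

    def passes_filter(self, cutoff: int = LENGTH_CONSERVATION_CUTOFF) -> bool:
        return max(self.length_a, self.length_b) > cutoff

    @property
    def is_first(self) -> bool:
        return self.intron_index == 1


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _frames(nt: str) -> list[str]:
    """The three forward-frame conceptual translations of a coding exon."""
    out = []
    for f in range(3):
        sub = nt[f:]
        sub = sub[: len(sub) - len(sub) % 3]
        if len(sub) >= 3:
            out.append(str(Seq(sub).translate()))
    return out


def translated_score(
    exon_a: str, exon_b: str, aligner: Align.PairwiseAligner
) -> float:
    """Best local protein alignment score over the 3x3 frame combinations."""
    frames_a = _frames(exon_a)
    frames_b = _frames(exon_b)
    if not frames_a or not frames_b:
        logger.warning("exon shorter than one codon scored 0")
        return 0.0
    best = 0.0
    for pa in frames_a:
        for pb in frames_b:
            if not pa or not pb:
                continue
            best = max(best, aligner.score(pa, pb))
    return best


def align_exons_translated(
    exons_a: Sequence[str],
    exons_b: Sequence[str],
    params: AlignmentParams | None = None,
) -> ExonCorrespondence:
    """Score every exon of A against every exon of B and keep reciprocal
    best hits with score >= ``params.min_score``.

    Score ties are broken in favor of the smaller ordinal offset ``|i - j|``
    (the conservative choice for collinear gene structures); a tie that
    survives that rule leaves the exon unpaired.
    """
    params = params or AlignmentParams()
    aligner = _make_aligner(params)
    na, nb = len(exons_a), len(exons_b)
    scores = np.zeros((na, nb))
    for i, ea in enumerate(exons_a):
        for j, eb in enumerate(exons_b):
            scores[i, j] = translated_score(ea, eb, aligner)

    def best_unique(row: np.ndarray, anchor: int) -> int | None:
        top = row.max()
        if top < params.min_score:
            return None
        cand = np.flatnonzero(row == top)
        if len(cand) == 1:
            return int(cand[0])
        offs = np.abs(cand - anchor)
        nearest = cand[offs == offs.min()]
        return int(nearest[0]) if len(nearest) == 1 else None

    pairs = []
    for i in range(na):
        j = best_unique(scores[i], i)
        if j is None:
            continue
        if best_unique(scores[:, j], j) == i:
            pairs.append((i, j, float(scores[i, j])))
    return ExonCorrespondence(pairs=pairs, n_exons_a=na, n_exons_b=nb)


def intron_length_ratio(len_a: float, len_b: float) -> float:
    """Larger over smaller of two orthologous intron lengths (>= 1)."""
    if len_a <= 0 or len_b <= 0:
        raise ValueError("intron lengths must be positive")
    return max(len_a, len_b) / min(len_a, len_b)


def length_ratio_records(
    gene_a: str,
    gene_b: str,
    intron_lengths_a: Sequence[int],
    intron_lengths_b: Sequence[int],
) -> list[LengthRatioRecord]:
    """Per-ordinal records for an identical-structure gene pair."""
    if len(intron_lengths_a) != len(intron_lengths_b):
        raise ValueError(
            f"{gene_a}/{gene_b}: intron counts differ; structure not identical"
        )
    return [
        LengthRatioRecord(gene_a, gene_b, k + 1, int(la), int(lb))
        for k, (la, lb) in enumerate(zip(intron_lengths_a, intron_lengths_b))
    ]


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float | None, float | None]:
    if len(x) < 2 or len(y) < 2:
        return None, None
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 50 and len(y) <= 50 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ConservationReport:
    n_first: int
    n_other: int
    median_first: float | None
    median_other: float | None
    u_statistic: float | None
    p_value: float | None
    ratios_first: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))
    ratios_other: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))

    def to_dict(self) -> dict:
        return {
            "n_first": self.n_first,
            "n_other": self.n_other,
            "median_first": self.median_first,
            "median_other": self.median_other,
            "u_statistic": self.u_statistic,
            "p_value": self.p_value,
        }


def conservation_comparison(
    records: Sequence[LengthRatioRecord],
    cutoff: int = LENGTH_CONSERVATION_CUTOFF,
) -> ConservationReport:
    """First- vs non-first-intron length-ratio comparison.

    Records whose intron is <= ``cutoff`` bp in both species are dropped;
    the two surviving groups are compared with a two-sided Mann-Whitney U
    test (exact for small tie-free samples, tie-corrected normal
    approximation otherwise).  With fewer than two records in a group the
    p-value is reported as None.
    """
    kept = [r for r in records if r.passes_filter(cutoff)]
    first = np.array([r.ratio for r in kept if r.is_first])
    other = np.array([r.ratio for r in kept if not r.is_first])
    u, p = _mannwhitney(first, other)
    return ConservationReport(
        n_first=len(first),
        n_other=len(other),
        median_first=float(np.median(first)) if len(first) else None,
        median_other=float(np.median(other)) if len(other) else None,
        u_statistic=u,
        p_value=p,
        ratios_first=first,
        ratios_other=other,
    )


def random_pair_ratios(
    first_lengths_a: Sequence[int],
    first_lengths_b: Sequence[int],
    rng: np.random.Generator,
    cutoff: int = LENGTH_CONSERVATION_CUTOFF,
) -> np.ndarray:
    """Null first-intron ratios from non-orthologous pairs.

    Species-B first introns are permuted (derangement-style: any fixed point
    is rotated away) and the same per-pair length filter is applied.
    """
    a = np.asarray(first_lengths_a)
    b = np.asarray(first_lengths_b)
    if len(a) != len(b):
        raise ValueError("need equally many first introns in both species")
    perm = rng.permutation(len(b))
    fixed = np.flatnonzero(perm == np.arange(len(b)))
    if len(fixed) > 1:
        perm[fixed] = perm[np.roll(fixed, 1)]
    elif len(fixed) == 1 and len(b) > 1:
        other = (fixed[0] + 1) % len(b)
        perm[[fixed[0], other]] = perm[[other, fixed[0]]]
    b = b[perm]
    keep = np.maximum(a, b) > cutoff
    return np.maximum(a[keep], b[keep]) / np.minimum(a[keep], b[keep])
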