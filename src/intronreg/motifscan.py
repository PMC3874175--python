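"""Energy-matrix motif scanning and conserved predicted TF interactions.

A position probability matrix (PWM) is converted to a per-position,
per-base binding energy matrix: after pseudocount regularization,
``eps_i(b) = ln(max_b' f_i(b') / f_i(b))`` (units kT), so the consensus
base has energy 0 at every position.  A window of sequence s scores
``E = sum_i eps_i(s_i)`` and is mapped to a fractional occupancy through
the Fermi-Dirac form ``occ = 1 / (1 + exp(E - mu))``; windows with
occupancy at or above a threshold (default 0.09, i.e. E <= ln(1/0.09 - 1)
~= 2.3136 kT at mu = 0) are called as predicted binding sites.

A TF is *predicted to interact* with a fragment when at least one window
passes; the interaction is *conserved* when the TF is predicted in both
species' orthologous fragments (identical-structure gene pairs only).
Orthologous fragment pairs with no predicted site for any TF in either
species carry no information and are excluded from per-region averages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {ord(b): i for i, b in enumerate(BASES)}
DEFAULT_THRESHOLD = 0.09
DEFAULT_PSEUDOCOUNT = 1e-3


@dataclass
class PWM:
    """Position probability matrix over A/C/G/T."""

    tf_id: str
    matrix: np.ndarray  # shape (width, 4), rows sum to 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.tf_id}: PWM must have 4 columns")
        if self.width < 4:
            raise ValueError(f"{self.tf_id}: PWM width must be >= 4")
        if np.any(self.matrix < 0) or np.any(self.matrix.sum(axis=1) <= 0):
            raise ValueError(f"{self.tf_id}: invalid probability rows")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass
class EnergyMatrix:
    """PWM-derived binding energies with occupancy-threshold site calling."""

    tf_id: str
    epsilon: np.ndarray  # (width, 4), kT, row minimum exactly 0
    mu: float = 0.0
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if not 0 < self.threshold < 1:
            raise ValueError("occupancy threshold must lie in (0, 1)")
        if not np.allclose(self.epsilon.min(axis=1), 0.0):
            raise ValueError("each energy row must have minimum 0 (consensus base)")

    @property
    def width(self) -> int:
        return self.epsilon.shape[0]

    @property
    def energy_cutoff(self) -> float:
        """The energy at which occupancy equals the threshold."""
        return self.mu + math.log(1.0 / self.threshold - 1.0)

    def occupancy(self, energy: float | np.ndarray) -> float | np.ndarray:
        return 1.0 / (1.0 + np.exp(np.asarray(energy) - self.mu))


@dataclass
class PredictedSite:
    tf_id: str
    offset: int  # 0-based within the scanned fragment
    strand: str
    energy: float
    occupancy: float


def pwm_to_energy(
    pwm: PWM,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    mu: float = 0.0,
    threshold: float = DEFAULT_THRESHOLD,
) -> EnergyMatrix:
    """Energies from log-ratios to the per-position consensus base."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    f = pwm.matrix + pseudocount
    f = f / f.sum(axis=1, keepdims=True)
    eps = np.log(f.max(axis=1, keepdims=True) / f)
    eps[np.arange(pwm.width), f.argmax(axis=1)] = 0.0  # exact zero at consensus
    return EnergyMatrix(tf_id=pwm.tf_id, epsilon=eps, mu=mu, threshold=threshold)


def _encode(sequence: str) -> np.ndarray:
    """A=0 C=1 G=2 T=3, anything else (N etc.) = 4."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int64)
    for byte, idx in _CODE.items():
        codes[arr == byte] = idx
    return codes


def _window_energies(codes: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Total energy of every window; windows containing N score +inf."""
    w = eps.shape[0]
    ext = np.hstack([eps, np.full((w, 1), np.inf)])  # column 4 = N
    wins = np.lib.stride_tricks.sliding_window_view(codes, w)
    return ext[np.arange(w)[None, :], wins].sum(axis=1)


def scan_fragment(sequence: str, em: EnergyMatrix) -> list[PredictedSite]:
    """All predicted sites on both strands of a fragment, sorted by offset.

    The reverse strand is scanned by reverse-complementing the energy
    matrix, so reported offsets always index the forward (fragment)
    sequence.  A double call at the same offset with equal energy (a
    palindromic matrix) collapses to the + strand site.  Windows containing
    N are skipped.
    """
    w = em.width
    if len(sequence) < w:
        return []
    codes = _encode(sequence)
    fwd = _window_energies(codes, em.epsilon)
    rev = _window_energies(codes, em.epsilon[::-1, ::-1])
    cutoff = em.energy_cutoff
    sites: list[PredictedSite] = []
    for off in range(len(fwd)):
        ef, er = fwd[off], rev[off]
        fwd_hit = ef <= cutoff
        rev_hit = er <= cutoff
        if fwd_hit:
            sites.append(
                PredictedSite(em.tf_id, off, "+", float(ef), float(em.occupancy(ef)))
            )
        if rev_hit and not (fwd_hit and ef == er):
            sites.append(
                PredictedSite(em.tf_id, off, "-", float(er), float(em.occupancy(er)))
            )
    for s in sites:
        assert (s.occupancy >= em.threshold) == (s.energy <= cutoff) or math.isclose(
            s.energy, cutoff
        )
    return sites


def predicted_tfs(sequence: str, ems: Iterable[EnergyMatrix]) -> set[str]:
    """TFs with at least one predicted site in the fragment (set semantics:
    several matrices of the same TF count once)."""
    return {em.tf_id for em in ems if scan_fragment(sequence, em)}


NO_DATA = None  # marker: neither orthologous fragment has any predicted site


def conserved_predicted_tfs(
    frag_a: str, frag_b: str, ems: Sequence[EnergyMatrix]
) -> set[str] | None:
    """TFs predicted in both orthologous fragments.

    Returns :data:`NO_DATA` (None) when no TF has a site in either
    fragment; such pairs are excluded from per-region averages.
    """
    tfs_a = predicted_tfs(frag_a, ems)
    tfs_b = predicted_tfs(frag_b, ems)
    if not tfs_a and not tfs_b:
        return NO_DATA
    return tfs_a & tfs_b


@dataclass
class RegionConservationSummary:
    per_class: dict[str, dict]  # class -> {mean, sem, n}
    first_vs_other_p: float | None

    def to_dict(self) -> dict:
        return {"per_class": self.per_class, "first_vs_other_p": self.first_vs_other_p}


def mean_conserved_by_region(
    entries: Iterable[tuple[str, set[str] | None]],
) -> RegionConservationSummary:
    """Mean +- SEM conserved-interaction counts per region class.

    ``entries`` are (region class, conserved TF set or NO_DATA) pairs, one
    per orthologous fragment pair.  NO_DATA entries are excluded.  SEM is
    reported as 0.0 when n = 1.  Classes ``first_intron`` and
    ``other_intron`` are additionally compared by Mann-Whitney U.
    """
    counts: dict[str, list[int]] = {}
    for cls, conserved in entries:
        if conserved is NO_DATA:
            continue
        counts.setdefault(cls, []).append(len(conserved))
    per_class = {}
    for cls, values in counts.items():
        arr = np.asarray(values, dtype=float)
        sem = float(stats.sem(arr)) if len(arr) > 1 else 0.0
        per_class[cls] = {"mean": float(arr.mean()), "sem": sem, "n": len(arr)}
    p = None
    if len(counts.get("first_intron", [])) >= 2 and len(counts.get("other_intron", [])) >= 2:
        res = stats.mannwhitneyu(
            counts["first_intron"], counts["other_intron"], alternative="two-sided"
        )
        p = float(res.pvalue)
    return RegionConservationSummary(per_class=per_class, first_vs_other_p=p)


def read_pwms_meme(path: str) -> list[PWM]:
    """Read PWMs from a MEME-minimal motif file."""
    from Bio import motifs

    with open(path) as handle:
        records = motifs.parse(handle, "minimal")
    out = []
    for m in records:
        mat = np.array([[m.pwm[b][i] for b in BASES] for i in range(m.length)])
        out.append(PWM(tf_id=m.name, matrix=mat))
    return out


def read_pwms_tsv(path: str) -> list[PWM]:
    """Read PWMs from a TSV with header ``tf A C G T``, one row per position;
    consecutive rows of the same tf form one matrix."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for tf, grp in df.groupby("tf", sort=False):
        out.append(PWM(tf_id=str(tf), matrix=grp[list(BASES)].to_numpy(float)))
    return out


def sites_to_bed(
    sites: Iterable[PredictedSite], chromosome: str, fragment_start: int = 0
) -> str:
    """BED6 with occupancy x1000 (clamped to [0, 1000]) in the score column."""
    lines = []
    for s in sites:
        score = int(min(1000, max(0, round(s.occupancy * 1000))))
        start = fragment_start + s.offset
        lines.append(
            f"{chromosome}\t{start}\t{start + 1}\t{s.tf_id}\t{score}\t{s.strand}"
        )
    return "\n".join(lines) + "\n" if lines else ""
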