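"""ChIP peak midpoint assignment to gene fragments and binding statistics.

A ChIP peak is reduced to its midpoint (floor of the interval average); the
midpoint is assigned to every fragment whose half-open interval contains
it, across all genes — fragments are analyzed individually, so a midpoint
inside two overlapping genes counts for both.  Per fragment the *distinct*
TF set is recorded: the statistic of interest is how many TFs touch a
region, not how many peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from intronreg.genome import GeneFragment, region_class

logger = logging.getLogger(__name__)

FragmentKey = tuple[str, str, int]  # (gene_id, kind, index)


@dataclass(frozen=True)
class ChIPPeak:
    tf_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.tf_id} has empty interval")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def read_peaks_bed(path: str, dialect: str = "bed") -> list[ChIPPeak]:
    """Read peaks from BED, column 4 = TF id.

    ``dialect='bed'`` is standard 0-based half-open; ``dialect='one-based'``
    accepts 1-based closed coordinates (some archive exports) and converts.
    """
    if dialect not in ("bed", "one-based"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, tf = line.split("\t")[:4]
            s, e = int(start), int(end)
            if dialect == "one-based":
                s -= 1
            peaks.append(ChIPPeak(tf_id=tf, chromosome=chrom, start=s, end=e))
    return peaks


def assign_peaks(
    peaks: Iterable[ChIPPeak], fragments: Sequence[GeneFragment]
) -> dict[FragmentKey, set[str]]:
    """Map every fragment to the distinct TFs whose peak midpoints fall in it.

    Every fragment receives an entry (possibly empty), so downstream means
    include unbound fragments.  Peaks on chromosomes absent from the
    fragment set are skipped with a logged count.
    """
    trees: dict[str, IntervalTree] = {}
    assignments: dict[FragmentKey, set[str]] = {}
    for frag in fragments:
        key = (frag.gene_id, frag.kind, frag.index)
        assignments[key] = set()
        start, end = frag.interval
        if end > start:  # zero-length fragments cannot contain a midpoint
            trees.setdefault(frag.chromosome, IntervalTree()).addi(start, end, key)
    skipped = 0
    for peak in peaks:
        tree = trees.get(peak.chromosome)
        if tree is None:
            skipped += 1
            continue
        for hit in tree.at(peak.midpoint):
            assignments[hit.data].add(peak.tf_id)
    if skipped:
        logger.warning("%d peaks on chromosomes without fragments skipped", skipped)
    return assignments


@dataclass
class BindingSummary:
    per_class: dict[str, dict]  # class -> {mean, sem, n}
    first_over_other_ratio: float | None

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "first_over_other_ratio": self.first_over_other_ratio,
        }


def region_binding_summary(
    assignments: Mapping[FragmentKey, set[str]],
    fragments: Sequence[GeneFragment],
) -> BindingSummary:
    """Mean +- SEM distinct-TF counts per region class, and the ratio of the
    first-intron mean over the other-intron mean."""
    by_class: dict[str, list[int]] = {}
    for frag in fragments:
        key = (frag.gene_id, frag.kind, frag.index)
        by_class.setdefault(region_class(frag), []).append(
            len(assignments.get(key, set()))
        )
    per_class = {}
    for cls, values in by_class.items():
        arr = np.asarray(values, dtype=float)
        sem = float(stats.sem(arr)) if len(arr) > 1 else 0.0
        per_class[cls] = {"mean": float(arr.mean()), "sem": sem, "n": len(arr)}
    ratio = None
    first = per_class.get("first_intron")
    other = per_class.get("other_intron")
    if first and other and other["mean"] > 0:
        ratio = first["mean"] / other["mean"]
    return BindingSummary(per_class=per_class, first_over_other_ratio=ratio)


def length_binding_correlation(
    lengths: Sequence[float], counts: Sequence[float]
) -> dict:
    """Pearson r on (length, count) and (log10 length, count), plus
    Spearman rho, each with a two-sided p.  Zero-variance input yields
    None entries."""
    if len(lengths) < 3 or len(lengths) != len(counts):
        raise ValueError("need >= 3 paired observations")
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(counts, dtype=float)
    out: dict = {"n": len(x)}
    if x.std() == 0 or y.std() == 0:
        out.update(
            pearson_r=None, pearson_p=None,
            pearson_log_r=None, pearson_log_p=None,
            spearman_rho=None, spearman_p=None,
        )
        return out
    r, p = stats.pearsonr(x, y)
    rl, pl = stats.pearsonr(np.log10(x), y)
    rho, ps = stats.spearmanr(x, y)
    out.update(
        pearson_r=float(r), pearson_p=float(p),
        pearson_log_r=float(rl), pearson_log_p=float(pl),
        spearman_rho=float(rho), spearman_p=float(ps),
    )
    return out


def promoter_intron_overlap(
    promoter_tfs: set[str], intron_tfs: set[str]
) -> float | None:
    """Overlap/intron (O/I) fraction: shared interactions over intron
    interactions; undefined (None) when the intron set is empty."""
    if not intron_tfs:
        return None
    return len(promoter_tfs & intron_tfs) / len(intron_tfs)


def assignments_to_tsv(assignments: Mapping[FragmentKey, set[str]]) -> str:
    lines = ["gene\tkind\tindex\ttfs"]
    for (gene, kind, index), tfs in sorted(assignments.items()):
        lines.append(f"{gene}\t{kind}\t{index}\t{','.join(sorted(tfs))}")
    return "\n".join(lines) + "\n"
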