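"""Gene-centered protein-DNA interaction (PDI) network statistics.

The network is a bipartite edge set (TF, gene, region kind) with region
kinds ``promoter`` and ``first_intron``, typically from yeast one-hybrid
screens or ChIP evidence.  This module computes per-gene TF sets and their
Jaccard similarity (promoter-only, intron-only, or pooling both regions),
tests whether similar-binding gene pairs are enriched for co-expression,
projects screen statistics to a genome through intron-length bins, and
performs hypergeometric gene-family enrichment with Benjamini-Hochberg
correction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

REGION_KINDS = ("promoter", "first_intron")
DEFAULT_J_CUT = 0.3
DEFAULT_COEXP_CUTS = (0.2, 0.5)
DEFAULT_PROJECTION_BINS = (65, 129, 257, 513)  # <65, 65-128, 129-256, 257-512, >512


@dataclass
class PDINetwork:
    """Bipartite TF-to-(gene, region) interaction set."""

    edges: set[tuple[str, str, str]]  # (tf_id, gene_id, region_kind)
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        bad = {e[2] for e in self.edges} - set(REGION_KINDS)
        if bad:
            raise ValueError(f"unknown region kinds: {sorted(bad)}")

    @classmethod
    def from_tsv(cls, path: str, provenance: str = "file") -> "PDINetwork":
        df = pd.read_csv(path, sep="\t", names=["tf", "gene", "region"], header=None,
                         comment="#")
        if list(df.iloc[0]) == ["tf", "gene", "region"]:
            df = df.iloc[1:]
        edges = {tuple(row) for row in df.itertuples(index=False)}
        return cls(edges=edges, provenance=provenance)

    def to_tsv(self) -> str:
        lines = ["tf\tgene\tregion"]
        for tf, gene, region in sorted(self.edges):
            lines.append(f"{tf}\t{gene}\t{region}")
        return "\n".join(lines) + "\n"

    def _index(self) -> dict[tuple[str, str], set[str]]:
        # built lazily; the edge set is treated as immutable once queried
        cached = getattr(self, "_by_gene", None)
        if cached is None:
            cached = {}
            for tf, g, region in self.edges:
                cached.setdefault((g, region), set()).add(tf)
            self._by_gene = cached
        return cached

    def tf_set(self, gene: str, mode: str = "combined") -> set[str]:
        """TFs bound to a gene in one region kind, or pooled (``combined``)."""
        if mode == "combined":
            kinds = REGION_KINDS
        elif mode in REGION_KINDS:
            kinds = (mode,)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        idx = self._index()
        out: set[str] = set()
        for kind in kinds:
            out |= idx.get((gene, kind), set())
        return out

    def in_degree(self, gene: str, mode: str = "combined") -> int:
        return len(self.tf_set(gene, mode))

    def genes(self) -> set[str]:
        return {g for _, g, _ in self.edges}


def jaccard_similarity(set_a: set, set_b: set) -> float | None:
    """|A & B| / |A | B|; undefined (None) when both sets are empty."""
    union = len(set_a | set_b)
    if union == 0:
        return None
    inter = len(set_a & set_b)
    assert union == len(set_a) + len(set_b) - inter
    return inter / union


def similarity_table(
    network: PDINetwork,
    genes: Sequence[str],
    coexpression: Mapping[frozenset, float] | None = None,
) -> pd.DataFrame:
    """One row per unordered gene pair with promoter-only, intron-only and
    combined (pooled TF sets) Jaccard indices plus the pair's co-expression
    score (NaN when missing)."""
    promoter = {g: network.tf_set(g, "promoter") for g in genes}
    intron = {g: network.tf_set(g, "first_intron") for g in genes}
    combined = {g: promoter[g] | intron[g] for g in genes}
    rows = []
    for ga, gb in itertools.combinations(genes, 2):
        coexp = math.nan
        if coexpression is not None:
            coexp = coexpression.get(frozenset((ga, gb)), math.nan)
        rows.append(
            {
                "gene_a": ga,
                "gene_b": gb,
                "j_promoter": jaccard_similarity(promoter[ga], promoter[gb]),
                "j_first_intron": jaccard_similarity(intron[ga], intron[gb]),
                "j_combined": jaccard_similarity(combined[ga], combined[gb]),
                "coexpression": coexp,
            }
        )
    return pd.DataFrame(rows)


def read_coexpression_tsv(path: str) -> dict[frozenset, float]:
    df = pd.read_csv(path, sep="\t", names=["gene_a", "gene_b", "score"],
                     header=None, comment="#")
    if list(df.iloc[0, :2]) == ["gene_a", "gene_b"]:
        df = df.iloc[1:]
    return {
        frozenset((r.gene_a, r.gene_b)): float(r.score)
        for r in df.itertuples(index=False)
    }


def _hypergeom_table_prob(table: np.ndarray) -> float:
    """Probability of an r x c table under the margin-conditioned
    (multivariate hypergeometric) null."""
    n = table.sum()
    logp = (
        sum(math.lgamma(m + 1) for m in table.sum(axis=1))
        + sum(math.lgamma(m + 1) for m in table.sum(axis=0))
        - math.lgamma(n + 1)
        - sum(math.lgamma(int(v) + 1) for v in table.ravel())
    )
    return math.exp(logp)


def freeman_halton_2x3(table: Sequence[Sequence[int]]) -> float:
    """Exact conditional p for a 2x3 table: the total probability of all
    margin-preserving tables no more probable than the observed one.

    Written out by direct enumeration because the common stats stacks only
    ship the 2x2 exact test.
    """
    obs = np.asarray(table, dtype=int)
    if obs.shape != (2, 3):
        raise ValueError("expected a 2x3 table")
    r0 = obs[0].sum()
    cols = obs.sum(axis=0)
    p_obs = _hypergeom_table_prob(obs)
    p = 0.0
    for a in range(min(r0, cols[0]) + 1):
        for b in range(min(r0 - a, cols[1]) + 1):
            c = r0 - a - b
            if c > cols[2]:
                continue
            cand = np.array([[a, b, c], [cols[0] - a, cols[1] - b, cols[2] - c]])
            p_t = _hypergeom_table_prob(cand)
            if p_t <= p_obs * (1 + 1e-9):
                p += p_t
    return min(1.0, p)


@dataclass
class EnrichmentTable:
    table: np.ndarray  # 2 (low/high J) x 3 (low/med/high coexpression)
    fisher_p: float | None  # 2x2 collapse: medium+high vs low co-expression
    freeman_halton_p: float | None
    n_undefined_j: int = 0

    def to_dict(self) -> dict:
        return {
            "table": self.table.tolist(),
            "fisher_p": self.fisher_p,
            "freeman_halton_p": self.freeman_halton_p,
            "n_undefined_j": self.n_undefined_j,
        }


def coexpression_enrichment(
    records: pd.DataFrame,
    mode: str = "combined",
    j_cut: float = DEFAULT_J_CUT,
    coexp_cuts: tuple[float, float] = DEFAULT_COEXP_CUTS,
) -> EnrichmentTable:
    """Partition gene pairs into low/high PDI similarity (J < cut vs >=)
    and low/medium/high co-expression, then test association.

    The primary p-value is a two-sided Fisher exact test on the 2x2
    collapse (medium+high vs low co-expression); the full 2x3
    Freeman-Halton exact p is reported alongside.  Pairs with undefined J
    (both TF sets empty) or missing co-expression are excluded (count
    logged).  An empty table margin leaves the p-values undefined (None).
    """
    col = {"promoter": "j_promoter", "first_intron": "j_first_intron",
           "combined": "j_combined"}[mode]
    j = records[col].to_numpy(dtype=float)
    coexp = records["coexpression"].to_numpy(dtype=float)
    valid = ~np.isnan(j) & ~np.isnan(coexp)
    n_undef = int((~valid).sum())
    if n_undef:
        logger.info("%d pairs with undefined J or missing co-expression excluded",
                    n_undef)
    j, coexp = j[valid], coexp[valid]
    lo, hi = coexp_cuts
    jbin = (j >= j_cut).astype(int)  # 0 = low, 1 = high
    cbin = np.digitize(coexp, [lo, hi])  # 0 low, 1 medium, 2 high
    table = np.zeros((2, 3), dtype=int)
    for jb, cb in zip(jbin, cbin):
        table[jb, cb] += 1
    collapse = np.array(
        [[table[0, 0], table[0, 1] + table[0, 2]],
         [table[1, 0], table[1, 1] + table[1, 2]]]
    )
    fisher_p = fh_p = None
    if table.sum(axis=1).min() > 0 and collapse.sum(axis=0).min() > 0:
        fisher_p = float(stats.fisher_exact(collapse, alternative="two-sided")[1])
    if table.sum(axis=1).min() > 0 and table.sum(axis=0).min() > 0:
        fh_p = freeman_halton_2x3(table)
    return EnrichmentTable(
        table=table, fisher_p=fisher_p, freeman_halton_p=fh_p,
        n_undefined_j=n_undef,
    )


@dataclass
class ProjectionReport:
    fraction_bound: float
    mean_interactions: float
    per_bin: list[dict]
    partial: bool  # some genome-weighted bin had no screened introns

    def to_dict(self) -> dict:
        return {
            "fraction_bound": self.fraction_bound,
            "mean_interactions": self.mean_interactions,
            "per_bin": self.per_bin,
            "partial": self.partial,
        }


def genome_projection(
    screen_lengths: Sequence[float],
    screen_counts: Sequence[int],
    genome_lengths: Sequence[float],
    bin_edges: Sequence[int] = DEFAULT_PROJECTION_BINS,
) -> ProjectionReport:
    """Project screen statistics to a genome through first-intron length bins.

    Per bin, the screened introns give the fraction with >= 1 TF and the
    mean interaction count; the genome-wide bin occupancies weight these
    into genome-level expectations.  Bins carrying genome weight but no
    screened intron are dropped, the remaining weights renormalized, and
    the projection flagged partial.
    """
    edges = list(bin_edges)
    sl = np.asarray(screen_lengths, dtype=float)
    sc = np.asarray(screen_counts, dtype=float)
    gl = np.asarray(genome_lengths, dtype=float)
    if len(sl) != len(sc):
        raise ValueError("screen lengths and counts must align")
    sbin = np.digitize(sl, edges)
    gbin = np.digitize(gl, edges)
    n_bins = len(edges) + 1
    per_bin = []
    weights, fracs, means = [], [], []
    partial = False
    for b in range(n_bins):
        weight = float((gbin == b).mean()) if len(gl) else 0.0
        in_bin = sc[sbin == b]
        if len(in_bin) == 0:
            if weight > 0:
                partial = True
                logger.warning("projection bin %d has genome weight %.3f but no "
                               "screened introns", b, weight)
            per_bin.append({"bin": b, "weight": weight, "n_screen": 0,
                            "fraction_bound": None, "mean_interactions": None})
            continue
        frac = float((in_bin >= 1).mean())
        mean = float(in_bin.mean())
        per_bin.append({"bin": b, "weight": weight, "n_screen": int(len(in_bin)),
                        "fraction_bound": frac, "mean_interactions": mean})
        weights.append(weight)
        fracs.append(frac)
        means.append(mean)
    w = np.asarray(weights)
    if w.sum() == 0:
        raise ValueError("no projection bin has both genome weight and screen data")
    w = w / w.sum()
    return ProjectionReport(
        fraction_bound=float(np.dot(w, fracs)),
        mean_interactions=float(np.dot(w, means)),
        per_bin=per_bin,
        partial=partial,
    )


@dataclass
class EnrichmentRecord:
    family_id: str
    n_family: int
    n_selection: int
    overlap: int
    p_value: float
    q_value: float


def family_enrichment(
    selection: Iterable[str],
    families: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentRecord]:
    """One-sided hypergeometric over-representation of each gene family in
    the selection (e.g. genes with first introns > 250 bp), BH-corrected
    across families and sorted by q then p."""
    universe = set(universe)
    selection = set(selection) & universe
    records = []
    pvals = []
    for fam_id, members in families.items():
        fam = set(members) & universe
        overlap = len(fam & selection)
        # P(X >= overlap), X ~ Hypergeom(N=|universe|, K=|family|, n=|selection|)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(fam),
                                     len(selection)))
        pvals.append(min(1.0, p))
        records.append((fam_id, len(fam), len(selection), overlap))
    if not records:
        return []
    qvals = multipletests(pvals, method="fdr_bh")[1]
    out = [
        EnrichmentRecord(fam_id, nf, ns, ov, p, float(q))
        for (fam_id, nf, ns, ov), p, q in zip(records, pvals, qvals)
    ]
    out.sort(key=lambda r: (r.q_value, r.p_value))
    return out


@dataclass
class ScreenSummary:
    """Bookkeeping of a gene-centered screen: bait attrition and hit rate."""

    n_baits: int
    n_removed: int  # auto-active / low-confidence baits
    n_zero_interaction: int
    n_positive: int
    n_tested: int

    @property
    def n_screened(self) -> int:
        return self.n_baits - self.n_removed

    @property
    def n_bound(self) -> int:
        return self.n_screened - self.n_zero_interaction

    @property
    def positive_rate(self) -> float:
        return self.n_positive / self.n_tested

    def to_dict(self) -> dict:
        return {
            "n_screened": self.n_screened,
            "n_bound": self.n_bound,
            "positive_rate": self.positive_rate,
        }


def screen_bookkeeping(
    n_baits: int, n_removed: int, n_zero_interaction: int,
    n_positive: int, n_tested: int,
) -> ScreenSummary:
    return ScreenSummary(n_baits, n_removed, n_zero_interaction,
                         n_positive, n_tested)
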