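"""Integration of methylation, binding and expression results.

Combines the gene sets produced upstream into target classes and summary
statistics: hypergeometric overlap tests, direct targets (hypomethylated
and enzyme-bound) and functional targets (hypomethylated and
down-regulated), carbon/light responsiveness partitions, binned
expression-vs-methylation trends, and sliding-window chromosomal
clustering of a gene set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeAnnotation


@dataclass
class GeneSet:
    name: str
    members: set
    background: set

    def __post_init__(self) -> None:
        self.members = set(self.members)
        self.background = set(self.background)
        stray = self.members - self.background
        if stray:
            raise ValueError(
                f"{self.name}: {len(stray)} members outside the background "
                "universe"
            )

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class OverlapResult:
    k: int
    n1: int
    n2: int
    N: int
    expected: float
    fold: float
    p_upper: float


@dataclass
class BinSummary:
    """Equal-count binning of genes by one measure, summarised by another."""

    bin_labels: list
    bin_counts: list
    bin_stats: list            # per-bin median or mean of the second measure
    trend_rho: float           # Spearman of bin statistic vs bin rank
    statistic: str = "median"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": self.bin_labels, "n_genes": self.bin_counts,
             self.statistic: self.bin_stats}
        )


@dataclass
class ChromCluster:
    chrom: str
    first_gene: str
    last_gene: str
    start: int
    end: int
    member_count: int
    members: list
    p_value: float


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, matching conventional report rounding."""
    scale = 10 ** ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# set overlap
# ---------------------------------------------------------------------------

def hypergeometric_overlap(set_a, set_b, background) -> OverlapResult:
    """Upper-tail hypergeometric test of the overlap of two gene sets.

    With N background genes of which n1 are in A, drawing n2 (set B) gives
    the overlap X ~ Hypergeom(N, n1, n2); p = P(X >= k) exactly.
    """
    if isinstance(set_a, GeneSet):
        set_a = set_a.members
    if isinstance(set_b, GeneSet):
        set_b = set_b.members
    background = set(background)
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= background or not set_b <= background:
        raise ValueError("sets must be subsets of the background universe")
    N, n1, n2 = len(background), len(set_a), len(set_b)
    k = len(set_a & set_b)
    expected = n1 * n2 / N if N else 0.0
    fold = k / expected if expected else float("nan")
    p_upper = float(stats.hypergeom.sf(k - 1, N, n1, n2))
    return OverlapResult(k=k, n1=n1, n2=n2, N=N, expected=expected,
                         fold=fold, p_upper=p_upper)


def derive_target_sets(hypo: GeneSet, bound: GeneSet, down: GeneSet):
    """Direct targets = hypo ∩ bound; functional targets = hypo ∩ down.

    Each intersection comes with its hypergeometric overlap statistics.
    """
    if hypo.background != bound.background or hypo.background != down.background:
        raise ValueError("gene sets must share one background universe")
    bg = hypo.background
    direct = GeneSet("direct_targets", hypo.members & bound.members, bg)
    functional = GeneSet("functional_targets", hypo.members & down.members, bg)
    overlaps = {
        "direct": hypergeometric_overlap(hypo.members, bound.members, bg),
        "functional": hypergeometric_overlap(hypo.members, down.members, bg),
    }
    return {"direct_targets": direct, "functional_targets": functional,
            "overlaps": overlaps}


def responsiveness_partition(targets, c_set, l_set):
    """Partition targets by carbon/light responsiveness.

    Returns the four disjoint counts (C only, L only, both, neither) plus
    the percent responsive to either signal, rounded half-up to an integer.
    """
    if isinstance(targets, GeneSet):
        targets = targets.members
    if isinstance(c_set, GeneSet):
        c_set = c_set.members
    if isinstance(l_set, GeneSet):
        l_set = l_set.members
    targets = set(targets)
    c_only = (targets & c_set) - l_set
    l_only = (targets & l_set) - c_set
    both = targets & c_set & l_set
    neither = targets - c_set - l_set
    n_resp = len(c_only) + len(l_only) + len(both)
    percent = (round_half_up(100.0 * n_resp / len(targets))
               if targets else 0.0)
    return {
        "C_only": len(c_only), "L_only": len(l_only),
        "both": len(both), "neither": len(neither),
        "n_responsive": n_resp, "percent_responsive": percent,
    }


# ---------------------------------------------------------------------------
# binned trends
# ---------------------------------------------------------------------------

def _equal_count_bins(order: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Split an index order into n_bins equal-count bins, remainder to the
    lowest bins."""
    n = len(order)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} genes, got {n}")
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if i < rem else 0) for i in range(n_bins)]
    bins, pos = [], 0
    for s in sizes:
        bins.append(order[pos: pos + s])
        pos += s
    return bins


def _trend_rho(stats_per_bin) -> float:
    if len(set(stats_per_bin)) == 1:  # flat: no trend by construction
        return 0.0
    rho = stats.spearmanr(np.arange(len(stats_per_bin)), stats_per_bin).statistic
    return float(rho)


def expression_methylation_bins(
    expression: pd.Series, methylation: pd.Series, n_bins: int = 10
) -> BinSummary:
    """Median methylation per expression decile.

    Genes are ranked by expression (ascending) and split into ``n_bins``
    equal-count bins; the per-bin median methylation and the Spearman trend
    of bin medians against bin rank quantify the expression-methylation
    coupling.
    """
    common = expression.index.intersection(methylation.index)
    expr = expression.loc[common]
    meth = methylation.loc[common]
    order = expr.sort_values(kind="mergesort").index.to_numpy()
    bins = _equal_count_bins(order, n_bins)
    medians = [float(meth.loc[b].median()) for b in bins]
    return BinSummary(
        bin_labels=[f"expr_bin{i + 1}" for i in range(n_bins)],
        bin_counts=[len(b) for b in bins],
        bin_stats=medians,
        trend_rho=_trend_rho(medians),
        statistic="median_methylation",
    )


def hypomethylation_magnitude_bins(
    delta_methylation: pd.Series, delta_expression: pd.Series, n_bins: int = 10
) -> BinSummary:
    """Mean expression change per hypomethylation-magnitude bin.

    Deltas are mutant - WT (log2 for expression, RPM difference for
    methylation); genes are binned by increasing methylation loss
    (descending delta), so the last bin holds the most hypomethylated
    genes.
    """
    common = delta_methylation.index.intersection(delta_expression.index)
    dm = delta_methylation.loc[common]
    de = delta_expression.loc[common]
    order = dm.sort_values(ascending=False, kind="mergesort").index.to_numpy()
    bins = _equal_count_bins(order, n_bins)
    means = [float(de.loc[b].mean()) for b in bins]
    return BinSummary(
        bin_labels=[f"hypo_bin{i + 1}" for i in range(n_bins)],
        bin_counts=[len(b) for b in bins],
        bin_stats=means,
        trend_rho=_trend_rho(means),
        statistic="mean_delta_expression",
    )


# ---------------------------------------------------------------------------
# chromosomal clustering
# ---------------------------------------------------------------------------

def chromosomal_clusters(
    gene_set,
    annotation: GenomeAnnotation,
    window_genes: int = 20,
    alpha: float = 0.05,
) -> list[ChromCluster]:
    """Sliding-window clusters of a gene set along each chromosome.

    A window of ``window_genes`` consecutive genes (step 1) is scored by the
    hypergeometric upper tail of its set-member count given the genome-wide
    set frequency; overlapping windows with p < ``alpha`` merge into
    clusters reporting their member genes and best window p.  Chromosomes
    with fewer than ``window_genes`` genes are skipped.
    """
    if isinstance(gene_set, GeneSet):
        gene_set = gene_set.members
    gene_set = set(gene_set)
    clusters: list[ChromCluster] = []
    if not gene_set:
        return clusters
    N = len(annotation)
    K = len(gene_set & set(annotation.gene_ids))
    for chrom in sorted(annotation.chrom_lengths):
        genes = annotation.genes_on(chrom)
        if len(genes) < window_genes:
            continue
        member = np.array([g.gene_id in gene_set for g in genes], dtype=int)
        counts = np.convolve(member, np.ones(window_genes, dtype=int),
                             "valid")
        pvals = stats.hypergeom.sf(counts - 1, N, K, window_genes)
        sig = np.flatnonzero(pvals < alpha)
        if sig.size == 0:
            continue
        # merge windows that overlap (starts within window_genes of each other)
        run_start = prev = int(sig[0])
        runs = []
        for idx in sig[1:]:
            idx = int(idx)
            if idx - prev >= window_genes:
                runs.append((run_start, prev))
                run_start = idx
            prev = idx
        runs.append((run_start, prev))
        for ws, we in runs:
            span = genes[ws: we + window_genes]
            members = [g.gene_id for g in span if g.gene_id in gene_set]
            clusters.append(
                ChromCluster(
                    chrom=chrom,
                    first_gene=span[0].gene_id,
                    last_gene=span[-1].gene_id,
                    start=span[0].start,
                    end=span[-1].end,
                    member_count=len(members),
                    members=members,
                    p_value=float(pvals[ws: we + 1].min()),
                )
            )
    return clusters


def clusters_to_frame(clusters: list[ChromCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in clusters],
            "start": [c.start for c in clusters],
            "end": [c.end for c in clusters],
            "first_gene": [c.first_gene for c in clusters],
            "last_gene": [c.last_gene for c in clusters],
            "member_count": [c.member_count for c in clusters],
            "p_value": [c.p_value for c in clusters],
            "members": [",".join(c.members) for c in clusters],
        }
    )
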