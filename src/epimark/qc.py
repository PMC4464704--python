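"""Replicate-concordance QC and ChIP-qPCR enrichment arithmetic.

Three replicate criteria are applied before any result is reported:
(1) the biological replicates share at least 80% of the top 40% of islands
ranked by FDR; (2) the Spearman correlation of per-base coverage, averaged
over three random 300 kb regions, exceeds 0.9; (3) more than 80% of all
retained islands are shared.  Sharing means >= 1 bp of overlap and is
required in both directions.  Results are then reported only when true in
both replicates (the consensus rule).

qPCR: percent input = 2^(input Ct - ChIP Ct) x input dilution factor,
optionally normalised to reference genes (geometric mean); fold enrichment
over the no-antibody control = 2^(noAb Ct - ChIP Ct), required > 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import CoverageTrack


@dataclass
class SharingResult:
    frac_1_in_2: float
    frac_2_in_1: float
    passed: bool


@dataclass
class SpearmanResult:
    regions: list          # (chrom, start, end)
    rhos: list
    mean_rho: float
    passed: bool


@dataclass
class QcReport:
    top_peak_sharing: SharingResult
    coverage_spearman: SpearmanResult
    island_sharing: SharingResult

    @property
    def passed(self) -> bool:
        return (self.top_peak_sharing.passed and self.coverage_spearman.passed
                and self.island_sharing.passed)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": ["top_peak_sharing", "coverage_spearman",
                              "island_sharing"],
                "value_1": [self.top_peak_sharing.frac_1_in_2,
                            self.coverage_spearman.mean_rho,
                            self.island_sharing.frac_1_in_2],
                "value_2": [self.top_peak_sharing.frac_2_in_1,
                            float("nan"),
                            self.island_sharing.frac_2_in_1],
                "passed": [self.top_peak_sharing.passed,
                           self.coverage_spearman.passed,
                           self.island_sharing.passed],
            }
        )


@dataclass
class PcrMeasurement:
    """One ChIP-qPCR assay: cycle thresholds and the input dilution."""

    ct_chip: float
    ct_input: float
    ct_noab: float | None = None
    input_dilution_factor: float = 1.0
    reference_percent_inputs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ct_chip <= 0 or self.ct_input <= 0:
            raise ValueError("Ct values must be positive")
        if self.input_dilution_factor <= 0:
            raise ValueError("input dilution factor must be positive")


# ---------------------------------------------------------------------------
# island sharing
# ---------------------------------------------------------------------------

def _shared_fraction(query: pd.DataFrame, target: pd.DataFrame) -> float:
    """Fraction of query islands overlapping (>=1 bp) any target island."""
    if len(query) == 0:
        raise ValueError("empty island list")
    trees: dict[str, IntervalTree] = {}
    for row in target.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    n_hit = 0
    for row in query.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is not None and tree.overlap(row.start, row.end):
            n_hit += 1
    return n_hit / len(query)


def _rank_by_fdr(islands: pd.DataFrame) -> pd.DataFrame:
    return islands.sort_values(
        ["fdr", "p_value", "chrom", "start"], kind="mergesort"
    )


def top_peak_sharing(
    islands_1: pd.DataFrame,
    islands_2: pd.DataFrame,
    top_frac: float = 0.4,
    min_sharing: float = 0.8,
) -> SharingResult:
    """Sharing of the top ``top_frac`` of islands ranked by ascending FDR.

    Ties break by ascending p then coordinate; the top set size is
    ceil(top_frac * n).  Pass needs both directions >= ``min_sharing``.
    """
    if len(islands_1) == 0 or len(islands_2) == 0:
        raise ValueError("empty island list")
    top1 = _rank_by_fdr(islands_1).head(math.ceil(top_frac * len(islands_1)))
    top2 = _rank_by_fdr(islands_2).head(math.ceil(top_frac * len(islands_2)))
    f12 = _shared_fraction(top1, top2)
    f21 = _shared_fraction(top2, top1)
    return SharingResult(f12, f21, passed=(f12 >= min_sharing and f21 >= min_sharing))


def island_sharing(
    islands_1: pd.DataFrame, islands_2: pd.DataFrame, min_sharing: float = 0.8
) -> SharingResult:
    """Sharing over all retained islands; pass needs both directions > 0.8."""
    f12 = _shared_fraction(islands_1, islands_2)
    f21 = _shared_fraction(islands_2, islands_1)
    return SharingResult(f12, f21, passed=(f12 > min_sharing and f21 > min_sharing))


# ---------------------------------------------------------------------------
# coverage correlation
# ---------------------------------------------------------------------------

def _draw_regions(chrom_lengths, n_regions, region_bp, rng):
    """Uniform non-overlapping regions, chromosome chosen by capacity."""
    chroms = [c for c, L in sorted(chrom_lengths.items()) if L >= region_bp]
    if not chroms:
        raise ValueError(f"no chromosome holds a {region_bp} bp region")
    regions = []
    attempts = 0
    while len(regions) < n_regions:
        attempts += 1
        if attempts > 1000 * n_regions:
            raise ValueError("genome too small for non-overlapping regions")
        weights = np.array([chrom_lengths[c] - region_bp + 1 for c in chroms],
                           dtype=float)
        chrom = chroms[rng.choice(len(chroms), p=weights / weights.sum())]
        start = int(rng.integers(0, chrom_lengths[chrom] - region_bp + 1))
        if any(c == chrom and start < e and s < start + region_bp
               for c, s, e in regions):
            continue
        regions.append((chrom, start, start + region_bp))
    return regions


def coverage_spearman(
    cov_1: CoverageTrack,
    cov_2: CoverageTrack,
    n_regions: int = 3,
    region_bp: int = 300_000,
    seed: int = 0,
    min_rho: float = 0.9,
    per_region: bool = False,
) -> SpearmanResult:
    """Spearman rho of per-base coverage over random genomic regions.

    Draws ``n_regions`` non-overlapping regions with the seed and computes
    rho per region.  By default the pass criterion is mean rho > ``min_rho``;
    ``per_region=True`` requires every region to pass individually.
    """
    rng = np.random.default_rng(seed)
    chrom_lengths = {c: len(a) for c, a in cov_1.arrays.items()}
    regions = _draw_regions(chrom_lengths, n_regions, region_bp, rng)
    rhos = []
    for chrom, start, end in regions:
        v1 = cov_1.region(chrom, start, end)
        v2 = cov_2.region(chrom, start, end)
        rho = stats.spearmanr(v1, v2).statistic
        rhos.append(float(rho))
    mean_rho = float(np.mean(rhos))
    passed = (all(r > min_rho for r in rhos) if per_region
              else mean_rho > min_rho)
    return SpearmanResult(regions=regions, rhos=rhos, mean_rho=mean_rho,
                          passed=passed)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def replicate_consensus(result_set_1, result_set_2) -> set:
    """Results reported only when true in both replicates.

    Inputs are sets of (gene_id, status) pairs — or a GeneMarkTable-style
    DataFrame, converted on the fly.  Commutative and idempotent.
    """
    def _as_pairs(x):
        if isinstance(x, pd.DataFrame):
            return set(zip(x.index, x["status"]))
        return set(x)

    return _as_pairs(result_set_1) & _as_pairs(result_set_2)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def pcr_percent_input(m: PcrMeasurement) -> float:
    """Percent input: 2^(input Ct - ChIP Ct) x dilution, reference-normalised.

    With reference genes given, the raw value is divided by the geometric
    mean of the reference percent inputs.
    """
    raw = 2.0 ** (m.ct_input - m.ct_chip) * m.input_dilution_factor
    if m.reference_percent_inputs:
        refs = np.asarray(m.reference_percent_inputs, dtype=float)
        if (refs <= 0).any():
            raise ValueError("reference percent inputs must be positive")
        raw /= float(np.exp(np.mean(np.log(refs))))
    return raw


def pcr_fold_enrichment(m: PcrMeasurement, min_fold: float = 3.0):
    """Fold enrichment over the no-antibody control; pass iff strictly > 3."""
    if m.ct_noab is None:
        raise ValueError("no-antibody Ct is required for fold enrichment")
    fold = 2.0 ** (m.ct_noab - m.ct_chip)
    return fold, fold > min_fold


def read_pcr_table(path) -> list[tuple[str, PcrMeasurement]]:
    """Read a qPCR TSV: columns gene, ct_chip, ct_input, ct_noab, dilution."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            (
                row.gene,
                PcrMeasurement(
                    ct_chip=row.ct_chip,
                    ct_input=row.ct_input,
                    ct_noab=getattr(row, "ct_noab", None),
                    input_dilution_factor=getattr(row, "dilution", 1.0),
                ),
            )
        )
    return out
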