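"""Positional metagene profiles over scaled gene bodies with fixed flanks.

Each gene contributes a 60-bin vector: 10 upstream flank bins (500 bp at
50 bp/bin), 40 gene-body bins (near-equal split of the body), 10 downstream
flank bins.  Vectors are oriented 5'->3' regardless of strand.  Aggregation
over a marked-gene set is the per-bin median; a cross-sample normalization
corrects for genome-coverage differences between genotypes, and the
3'-fraction statistic quantifies positional shifts of the mark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CoverageTrack, Gene, GenomeAnnotation


@dataclass
class BinScheme:
    body_bins: int = 40
    flank_bp: int = 500
    flank_bins: int = 10

    def __post_init__(self) -> None:
        if min(self.body_bins, self.flank_bp, self.flank_bins) <= 0:
            raise ValueError("all bin-scheme fields must be positive")
        if self.flank_bp % self.flank_bins != 0:
            raise ValueError("flank_bp must be divisible by flank_bins")

    @property
    def n_bins(self) -> int:
        return self.body_bins + 2 * self.flank_bins

    @property
    def flank_bin_bp(self) -> int:
        return self.flank_bp // self.flank_bins


@dataclass
class MetageneProfile:
    """Aggregated 60-bin positional signal (upstream | body | downstream)."""

    values: np.ndarray
    n_genes: int
    scheme: BinScheme
    normalization_factor: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.scheme.n_bins,):
            raise ValueError(
                f"profile must have {self.scheme.n_bins} bins, "
                f"got {self.values.shape}"
            )

    @property
    def body(self) -> np.ndarray:
        fb = self.scheme.flank_bins
        return self.values[fb: fb + self.scheme.body_bins]


def _split_body_means(body: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean per bin of a near-equal split; the first (L mod n) bins get the
    extra base, counting from the 5' end (the array is already 5'->3')."""
    L = len(body)
    base, rem = divmod(L, n_bins)
    widths = np.full(n_bins, base, dtype=int)
    widths[:rem] += 1
    edges = np.concatenate([[0], np.cumsum(widths)])
    sums = np.add.reduceat(body, edges[:-1])
    return sums / widths


def gene_bin_profile(
    gene: Gene, coverage: CoverageTrack, scheme: BinScheme | None = None
) -> np.ndarray:
    """60-bin mean-coverage vector for one gene, oriented 5'->3'.

    The body is split into ``body_bins`` near-equal intervals (remainder
    bases distributed one per bin from the 5' end); flanks are binned at
    ``flank_bin_bp``.  Genes shorter than ``body_bins`` bases cannot be
    split and raise ValueError (callers skip and count them).  Flank bases
    beyond the chromosome end contribute zero coverage.
    """
    scheme = scheme or BinScheme()
    if gene.length < scheme.body_bins:
        raise ValueError(
            f"{gene.gene_id}: body shorter than {scheme.body_bins} bp"
        )
    if gene.chrom not in coverage.arrays:
        raise KeyError(f"{gene.gene_id}: no coverage for {gene.chrom}")
    full = coverage.region(
        gene.chrom, gene.start - scheme.flank_bp, gene.end + scheme.flank_bp
    )
    if gene.strand == "-":
        full = full[::-1]
    left = full[: scheme.flank_bp]
    body = full[scheme.flank_bp: scheme.flank_bp + gene.length]
    right = full[scheme.flank_bp + gene.length:]
    fb = scheme.flank_bin_bp
    left_bins = left.reshape(scheme.flank_bins, fb).mean(axis=1)
    right_bins = right.reshape(scheme.flank_bins, fb).mean(axis=1)
    body_bins = _split_body_means(body, scheme.body_bins)
    return np.concatenate([left_bins, body_bins, right_bins])


def profile_gene_set(
    annotation: GenomeAnnotation,
    coverage: CoverageTrack,
    gene_ids=None,
    scheme: BinScheme | None = None,
):
    """Per-gene profiles for a set of genes.

    Returns (DataFrame genes x 60, skipped gene ids).  Genes too short for
    the body split are skipped and reported.
    """
    scheme = scheme or BinScheme()
    wanted = set(gene_ids) if gene_ids is not None else None
    rows, index, skipped = [], [], []
    for g in annotation:
        if wanted is not None and g.gene_id not in wanted:
            continue
        if g.length < scheme.body_bins:
            skipped.append(g.gene_id)
            continue
        rows.append(gene_bin_profile(g, coverage, scheme))
        index.append(g.gene_id)
    df = pd.DataFrame(rows, index=pd.Index(index, name="gene_id"))
    return df, skipped


def aggregate_profiles(
    profiles: pd.DataFrame, gene_set=None, scheme: BinScheme | None = None
) -> MetageneProfile:
    """Per-bin median over a gene set."""
    scheme = scheme or BinScheme()
    if gene_set is not None:
        missing = set(gene_set) - set(profiles.index)
        if missing:
            raise KeyError(f"genes not profiled: {sorted(missing)[:5]} ...")
        profiles = profiles.loc[sorted(gene_set)]
    if len(profiles) == 0:
        raise ValueError("cannot aggregate an empty gene set")
    return MetageneProfile(
        values=profiles.median(axis=0).to_numpy(),
        n_genes=len(profiles),
        scheme=scheme,
    )


def mean_body_coverage(
    coverage: CoverageTrack, annotation: GenomeAnnotation, gene_ids
) -> float:
    """Mean per-base coverage over the bodies of the given genes."""
    total = 0.0
    n_bases = 0
    wanted = set(gene_ids)
    for g in annotation:
        if g.gene_id in wanted:
            total += float(coverage.region(g.chrom, g.start, g.end).sum())
            n_bases += g.length
    if n_bases == 0 or total == 0.0:
        raise ValueError("zero mean coverage over the gene set")
    return total / n_bases


def normalize_profiles_between_samples(
    profile_a: MetageneProfile,
    profile_b: MetageneProfile,
    coverage_a: CoverageTrack,
    coverage_b: CoverageTrack,
    annotation: GenomeAnnotation,
    marked_a,
    marked_b,
    mode: str = "marked_bodies",
):
    """Scale two profiles onto a common footing before comparison.

    A genotype that loses the mark on many genes has a lower genome-wide
    ChIP coverage; dividing each profile by its sample's mean coverage over
    its own marked-gene bodies (default) removes that difference, so each
    sample's gene-body signal averages ~1.  ``mode='genome'`` divides by the
    genome-wide mean coverage instead.
    """
    if mode == "marked_bodies":
        fa = mean_body_coverage(coverage_a, annotation, marked_a)
        fb = mean_body_coverage(coverage_b, annotation, marked_b)
    elif mode == "genome":
        fa = coverage_a.total_mass / sum(len(v) for v in coverage_a.arrays.values())
        fb = coverage_b.total_mass / sum(len(v) for v in coverage_b.arrays.values())
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if fa == 0 or fb == 0:
        raise ValueError("zero mean coverage")
    out_a = MetageneProfile(profile_a.values / fa, profile_a.n_genes,
                            profile_a.scheme, normalization_factor=1.0 / fa)
    out_b = MetageneProfile(profile_b.values / fb, profile_b.n_genes,
                            profile_b.scheme, normalization_factor=1.0 / fb)
    return out_a, out_b


def three_prime_fraction(profile: MetageneProfile) -> float:
    """Fraction of body signal in the 3' half of the body bins.

    0.5 for a flat profile; smaller values mean a 5'-shifted mark.
    """
    body = profile.body
    half = len(body) // 2
    total = body.sum()
    if total == 0:
        raise ValueError("all-zero gene body")
    return float(body[half:].sum() / total)


def write_profiles(profiles: pd.DataFrame, aggregate: MetageneProfile, path):
    """TSV with per-gene 60-bin profiles plus the aggregate row."""
    out = profiles.copy()
    out.columns = [f"bin{i:02d}" for i in range(out.shape[1])]
    agg = pd.DataFrame(
        [aggregate.values], index=pd.Index(["<aggregate>"], name="gene_id"),
        columns=out.columns,
    )
    pd.concat([agg, out]).to_csv(path, sep="\t")
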