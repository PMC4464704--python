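"""Per-gene three-way factorial ANOVA on the expression matrix.

The design is a balanced full factorial: genotype (G: WT vs mutant) x
carbon (C: -/+) x light (L: -/+), with an equal number of replicates per
cell.  After removing genes below the low-expression cutoff (linear-scale
40), each gene is decomposed into the seven factorial terms G, C, L, GxC,
GxL, CxL, GxCxL; with a balanced 2^3 design the +-1 contrasts are
orthogonal, so the sums of squares are unambiguous and the whole matrix can
be fitted in one vectorised pass.  P-values per term are BH-adjusted across
genes, and the response gene sets are cut at FDR < 0.05 (G, C, L; the G set
split by the sign of the mutant-vs-WT contrast) and FDR < 0.15 (GxL).

The fit is on log2(x + 1) of the linear-scale values by default — the
standard variance-stabilising choice for MAS5-style intensities; a
raw-scale mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TERMS = ["G", "C", "L", "GxC", "GxL", "CxL", "GxCxL"]


@dataclass
class ExpressionMatrix:
    """Linear-scale genes x samples values plus the sample design sheet."""

    values: pd.DataFrame
    design: pd.DataFrame  # columns sample, genotype, carbon, light, rep

    def __post_init__(self) -> None:
        missing = set(self.design["sample"]) - set(self.values.columns)
        if missing:
            raise ValueError(f"design samples absent from matrix: {missing}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    def write(self, matrix_path, design_path) -> None:
        self.values.to_csv(matrix_path, sep="\t")
        self.design.to_csv(design_path, sep="\t", index=False)

    @classmethod
    def read(cls, matrix_path, design_path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t")
        for col in ("carbon", "light"):
            design[col] = design[col].astype(bool)
        return cls(values=values, design=design)


@dataclass
class ResponseSets:
    """The derived response/target gene sets with the thresholds used."""

    down_in_mut: set
    up_in_mut: set
    c_responsive: set
    l_responsive: set
    gxl: set
    g_fdr: float = 0.05
    cl_fdr: float = 0.05
    gxl_fdr: float = 0.15

    def counts(self) -> dict:
        return {
            "down_in_mut": len(self.down_in_mut),
            "up_in_mut": len(self.up_in_mut),
            "c_responsive": len(self.c_responsive),
            "l_responsive": len(self.l_responsive),
            "gxl": len(self.gxl),
        }


def filter_low_expression(matrix: pd.DataFrame, cutoff: float = 40.0):
    """Drop genes whose expression is below ``cutoff`` in every sample.

    The comparison is inclusive: a gene reaching the cutoff in any one
    sample is retained.  Returns (filtered matrix, removed gene ids).
    """
    keep = (matrix >= cutoff).any(axis=1)
    removed = list(matrix.index[~keep])
    return matrix[keep], removed


def _validate_balanced(design: pd.DataFrame) -> int:
    cells = design.groupby(["genotype", "carbon", "light"], observed=True).size()
    if len(cells) != 8:
        raise ValueError(
            f"design must cover all 8 genotype x carbon x light cells, "
            f"found {len(cells)}"
        )
    if cells.nunique() != 1:
        raise ValueError(
            "unbalanced design: replicate counts per cell differ "
            f"({dict(cells)}); the factorial decomposition requires balance"
        )
    r = int(cells.iloc[0])
    if r < 2:
        raise ValueError("need at least 2 replicates per cell")
    return r


def fit_three_way_anova(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    log2_transform: bool = True,
) -> pd.DataFrame:
    """Fixed-effects 2x2x2 ANOVA for every gene at once.

    Returns a table indexed by gene with, per term t in
    G, C, L, GxC, GxL, CxL, GxCxL: ``F_t``, ``p_t`` and BH-adjusted
    ``fdr_t`` (adjusted across genes within each term), plus ``delta_G`` /
    ``delta_C`` / ``delta_L``: the main-effect contrasts (mutant - WT,
    +carbon - -carbon, +light - -light) on the analysis scale.
    """
    r = _validate_balanced(design)
    samples = list(design["sample"])
    Y = matrix[samples].to_numpy(dtype=float)
    if log2_transform:
        Y = np.log2(Y + 1.0)
    n_genes, n_samples = Y.shape

    g_code = np.where(design["genotype"].to_numpy() == "WT", -1.0, 1.0)
    c_code = np.where(design["carbon"].to_numpy(), 1.0, -1.0)
    l_code = np.where(design["light"].to_numpy(), 1.0, -1.0)
    contrasts = {
        "G": g_code, "C": c_code, "L": l_code,
        "GxC": g_code * c_code, "GxL": g_code * l_code,
        "CxL": c_code * l_code, "GxCxL": g_code * c_code * l_code,
    }

    # within-cell residual sum of squares
    cell_key = ((g_code > 0).astype(int) * 4 + (c_code > 0).astype(int) * 2
                + (l_code > 0).astype(int))
    indicator = np.zeros((n_samples, 8))
    indicator[np.arange(n_samples), cell_key] = 1.0
    cell_means = (Y @ indicator) / r
    ss_error = (Y ** 2).sum(axis=1) - r * (cell_means ** 2).sum(axis=1)
    df_error = 8 * (r - 1)
    ms_error = ss_error / df_error

    out = pd.DataFrame(index=matrix.index)
    for term, code in contrasts.items():
        effect = Y @ code / n_samples          # half the +-contrast difference
        ss_term = n_samples * effect ** 2      # orthogonal contrast, df = 1
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ss_term / ms_error
        F = np.where(ms_error > 0, F, np.inf)
        p = stats.f.sf(F, 1, df_error)
        out[f"F_{term}"] = F
        out[f"p_{term}"] = p
        out[f"fdr_{term}"] = adjust_fdr(p)
    out["delta_G"] = 2.0 * (Y @ contrasts["G"]) / n_samples
    out["delta_C"] = 2.0 * (Y @ contrasts["C"]) / n_samples
    out["delta_L"] = 2.0 * (Y @ contrasts["L"]) / n_samples
    return out


def adjust_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment of one p-value column."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def classify_response_sets(
    table: pd.DataFrame,
    g_fdr: float = 0.05,
    cl_fdr: float = 0.05,
    gxl_fdr: float = 0.15,
) -> ResponseSets:
    """Cut the ANOVA table into the study's response gene sets.

    Genotype-significant genes split into down/up in the mutant by the sign
    of ``delta_G``; carbon- and light-responsive sets use the C and L main
    effects; the GxL set uses the interaction at its looser threshold.
    """
    g_sig = table["fdr_G"] < g_fdr
    down = set(table.index[g_sig & (table["delta_G"] < 0)])
    up = set(table.index[g_sig & (table["delta_G"] > 0)])
    return ResponseSets(
        down_in_mut=down,
        up_in_mut=up,
        c_responsive=set(table.index[table["fdr_C"] < cl_fdr]),
        l_responsive=set(table.index[table["fdr_L"] < cl_fdr]),
        gxl=set(table.index[table["fdr_GxL"] < gxl_fdr]),
        g_fdr=g_fdr, cl_fdr=cl_fdr, gxl_fdr=gxl_fdr,
    )
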