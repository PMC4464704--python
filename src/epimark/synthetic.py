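"""Synthetic genomes, ChIP fragment libraries and factorial expression matrices.

The generator emulates a histone-methyltransferase deletion study at desk
scale: two genotypes (WT and a deletion mutant), a 2x2 transient
carbon x light treatment, duplicate ChIP libraries plus an input per
genotype/condition, an antibody-binding library for the enzyme itself,
gene-body-enriched marks with a 5'-weighted profile, a designated
hypomethylated gene subset that loses its 3' signal in the mutant, and
expression down-regulation coupled to hypomethylation.  Every gene carries
ground-truth labels so downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import (
    FragmentSet,
    Gene,
    GenomeAnnotation,
    write_bed,
    write_gff3,
)

GENOTYPES = ("WT", "mut")
LIBRARY_KINDS = ("chip_mark", "input", "chip_binding")

# 5'-weighted gene-body profile: relative density 1.5 at the TSS tapering
# linearly to 0.75 at the TTS.  Any monotone 5'-biased shape would do; this
# one gives a 2:1 TSS:TTS ratio with mean 1.125.
PROFILE_TSS_WEIGHT = 1.5
PROFILE_TTS_WEIGHT = 0.75


@dataclass
class SyntheticConfig:
    """Study-design parameters for the synthetic generator.

    Fractions are of the relevant parent set (``frac_hypo`` is a fraction of
    *marked* genes, ``frac_bound`` of *hypo* genes).  ``effect_log2`` maps the
    factorial terms to log2 effect sizes; the G (genotype) effect is the one
    applied to truth down-regulated genes, up-regulated genes receive its
    negation.  ``three_prime_attenuation`` scales the enrichment excess above
    background over the 3' portion of hypo-gene bodies in the mutant
    (0 = the mark is completely lost there, leaving background).
    """

    n_genes: int = 500
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 1_150_000, "chr2": 1_150_000}
    )
    gene_length_range: tuple = (1_000, 3_000)
    intergenic_gap_range: tuple = (1_000, 3_000)
    frac_marked: float = 0.6
    frac_hypo: float = 0.4
    frac_bound: float = 0.5
    frac_up: float = 0.1          # non-marked genes up-regulated in the mutant
    frac_c_responsive: float = 0.22
    frac_l_responsive: float = 0.35
    frac_gxl: float = 0.05
    enrichment_fold: float = 10.0
    three_prime_attenuation: float = 0.0
    three_prime_start: float = 0.4  # body fraction where the 3' region begins
    fragment_length: int = 200
    library_size: int = 500_000
    expr_baseline_log2_mean: float = 8.0
    expr_baseline_log2_sd: float = 2.0
    effect_log2: dict = field(
        default_factory=lambda: {"G": -2.0, "C": 1.0, "L": 1.0, "GxL": 1.0}
    )
    noise_log2_sd: float = 0.25
    n_reps: int = 3               # expression replicates per design cell
    n_chip_reps: int = 2          # ChIP replicates per genotype/condition
    chip_conditions: tuple = ((False, False), (True, True))  # (carbon, light)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_marked", "frac_hypo", "frac_bound", "frac_up",
                     "frac_c_responsive", "frac_l_responsive", "frac_gxl"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not all(np.isfinite(list(self.effect_log2.values()))):
            raise ValueError("effect sizes must be finite")
        if not 0.0 <= self.three_prime_attenuation:
            raise ValueError("three_prime_attenuation must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("gene_length_range", "intergenic_gap_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "chip_conditions" in raw:
            raw["chip_conditions"] = tuple(
                tuple(bool(x) for x in cell) for cell in raw["chip_conditions"]
            )
        return cls(**raw)


class GroundTruth:
    """Per-gene synthetic labels used to score pipeline recovery."""

    COLUMNS = ["marked", "hypo", "bound", "de_direction",
               "c_responsive", "l_responsive", "gxl"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"truth table missing columns {missing}")
        if ((frame["hypo"]) & (~frame["marked"])).any():
            raise ValueError("hypo genes must be marked")
        self.frame = frame

    def genes_where(self, column: str) -> set[str]:
        return set(self.frame.index[self.frame[column].astype(bool)])

    @property
    def down_genes(self) -> set[str]:
        return set(self.frame.index[self.frame["de_direction"] == "down"])

    @property
    def up_genes(self) -> set[str]:
        return set(self.frame.index[self.frame["de_direction"] == "up"])


class CapacityError(ValueError):
    """Raised when the configured genes cannot be placed on the chromosomes."""


# ---------------------------------------------------------------------------
# annotation + truth
# ---------------------------------------------------------------------------

def build_annotation(config: SyntheticConfig):
    """Place non-overlapping genes and draw ground-truth labels.

    Genes are laid down left to right on each chromosome with lengths and
    intergenic gaps drawn uniformly from the configured ranges; strands are
    assigned ~50/50.  Deterministic for a fixed ``config.seed``.

    Returns
    -------
    (GenomeAnnotation, GroundTruth)
    """
    rng = np.random.default_rng(config.seed)
    lo_len, hi_len = config.gene_length_range
    lo_gap, hi_gap = config.intergenic_gap_range
    genes: list[Gene] = []
    chrom_names = sorted(config.chrom_lengths)
    ci = 0
    cursor = int(rng.integers(lo_gap, hi_gap + 1)) if config.n_genes else 0
    for i in range(config.n_genes):
        length = int(rng.integers(lo_len, hi_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        while ci < len(chrom_names) and (
            cursor + length > config.chrom_lengths[chrom_names[ci]]
        ):
            ci += 1
            cursor = int(rng.integers(lo_gap, hi_gap + 1))
        if ci >= len(chrom_names):
            raise CapacityError(
                f"could not place gene {i + 1}/{config.n_genes}: "
                "chromosomes too short for the configured lengths and gaps"
            )
        chrom = chrom_names[ci]
        genes.append(Gene(f"g{i + 1:05d}", chrom, cursor, cursor + length, strand))
        cursor += length + int(rng.integers(lo_gap, hi_gap + 1))

    annotation = GenomeAnnotation(genes=genes, chrom_lengths=dict(config.chrom_lengths))

    ids = [g.gene_id for g in genes]
    n = len(ids)
    marked = rng.random(n) < config.frac_marked
    hypo = marked & (rng.random(n) < config.frac_hypo)
    bound = hypo & (rng.random(n) < config.frac_bound)
    de = np.where(hypo, "down", "none").astype(object)
    up_candidates = (~marked) & (rng.random(n) < config.frac_up)
    de[up_candidates] = "up"
    truth = GroundTruth(
        pd.DataFrame(
            {
                "marked": marked,
                "hypo": hypo,
                "bound": bound,
                "de_direction": de,
                "c_responsive": rng.random(n) < config.frac_c_responsive,
                "l_responsive": rng.random(n) < config.frac_l_responsive,
                "gxl": rng.random(n) < config.frac_gxl,
            },
            index=pd.Index(ids, name="gene_id"),
        )
    )
    return annotation, truth


# ---------------------------------------------------------------------------
# fragment libraries
# ---------------------------------------------------------------------------

def _body_profile(length: int, strand: str) -> np.ndarray:
    """Per-base 5'-weighted body shape, mean-normalised to 1."""
    w = np.linspace(PROFILE_TSS_WEIGHT, PROFILE_TTS_WEIGHT, length)
    if strand == "-":
        w = w[::-1]
    return w / w.mean()


def fragment_start_density(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    genotype: str,
    library_kind: str,
    config: SyntheticConfig,
) -> dict[str, np.ndarray]:
    """Unnormalised per-base fragment-start weights for one library.

    Background weight is 1 per base everywhere.  ``chip_mark`` adds
    ``(enrichment_fold - 1) * shape`` over marked gene bodies, so the
    body-average density is exactly ``enrichment_fold`` x background; in the
    mutant the excess over the 3' portion of hypo genes is scaled by
    ``three_prime_attenuation``.  ``chip_binding`` adds a flat
    ``(enrichment_fold - 1)`` excess over bound-gene bodies.  ``input`` is
    uniform.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    if library_kind not in LIBRARY_KINDS:
        raise ValueError(f"unknown library_kind {library_kind!r}")
    density = {
        c: np.ones(L, dtype=np.float64) for c, L in annotation.chrom_lengths.items()
    }
    if library_kind == "input":
        return density
    excess = config.enrichment_fold - 1.0
    tf = truth.frame
    for g in annotation:
        row = tf.loc[g.gene_id]
        if library_kind == "chip_binding":
            if row["bound"]:
                density[g.chrom][g.start:g.end] += excess
            continue
        if not row["marked"]:
            continue
        shape = _body_profile(g.length, g.strand) * excess
        if genotype == "mut" and row["hypo"]:
            # attenuate the mark over the 3' portion (5'->3' sense)
            cut = int(round(config.three_prime_start * g.length))
            if g.strand == "+":
                shape[cut:] *= config.three_prime_attenuation
            else:
                shape[: g.length - cut] *= config.three_prime_attenuation
        density[g.chrom][g.start:g.end] += shape
    return density


def simulate_chip_fragments(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    genotype: str,
    library_kind: str,
    config: SyntheticConfig,
    seed: int,
) -> FragmentSet:
    """Sample one fragment library from the library's start density.

    The fragment count is Poisson(library_size); starts are drawn from the
    per-base density, fragments run ``fragment_length`` bp rightward (clipped
    at the chromosome end) and are strandless ('+' recorded).  Deterministic
    per seed.
    """
    rng = np.random.default_rng(seed)
    density = fragment_start_density(annotation, truth, genotype, library_kind, config)
    chroms = sorted(density)
    masses = np.array([density[c].sum() for c in chroms])
    n_total = int(rng.poisson(config.library_size))
    per_chrom = rng.multinomial(n_total, masses / masses.sum())
    records = []
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        w = density[chrom]
        if np.ptp(w) == 0:  # uniform: avoid the O(L) weighted path
            starts = rng.integers(0, len(w), size=n)
        else:
            starts = rng.choice(len(w), size=n, replace=True, p=w / w.sum())
        starts = np.sort(starts)
        ends = np.minimum(starts + config.fragment_length, len(w))
        records.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "strand": "+"}
            )
        )
    if records:
        frame = pd.concat(records, ignore_index=True)
    else:
        frame = pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    return FragmentSet(frame)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def expression_design(config: SyntheticConfig) -> pd.DataFrame:
    """Sample sheet for the full 2x2x2 x n_reps factorial."""
    rows = []
    for genotype in GENOTYPES:
        for carbon in (False, True):
            for light in (False, True):
                for rep in range(1, config.n_reps + 1):
                    rows.append(
                        {
                            "sample": f"{genotype}_C{int(carbon)}_L{int(light)}_r{rep}",
                            "genotype": genotype,
                            "carbon": carbon,
                            "light": light,
                            "rep": rep,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_expression(
    truth: GroundTruth, config: SyntheticConfig, seed: int
):
    """Linear-scale expression matrix for the 2x2x2 factorial design.

    log2 signal = gene baseline + assigned effects + Gaussian noise; the
    matrix is emitted on the linear scale (2**log2) so the low-expression
    cutoff downstream is exercised.  Effects: G applied in the mutant to
    truth DE genes (down get ``effect_log2['G']``, up its negation), C/L to
    responsive genes under +carbon/+light, GxL to flagged genes in the
    (mutant, +light) cells only.

    Returns
    -------
    (matrix, design) : genes x samples DataFrame (linear scale) and the
    sample sheet.
    """
    if config.n_reps < 2:
        raise ValueError("n_reps must be >= 2 for a testable factorial")
    rng = np.random.default_rng(seed)
    design = expression_design(config)
    tf = truth.frame
    ids = tf.index.to_numpy()
    n = len(ids)
    baseline = rng.normal(
        config.expr_baseline_log2_mean, config.expr_baseline_log2_sd, size=n
    )
    e = config.effect_log2
    g_eff = np.where(
        tf["de_direction"] == "down", e["G"],
        np.where(tf["de_direction"] == "up", -e["G"], 0.0),
    )
    c_eff = np.where(tf["c_responsive"], e["C"], 0.0)
    l_eff = np.where(tf["l_responsive"], e["L"], 0.0)
    gxl_eff = np.where(tf["gxl"], e["GxL"], 0.0)

    cols = {}
    for row in design.itertuples(index=False):
        log2v = baseline.copy()
        if row.genotype == "mut":
            log2v += g_eff
        if row.carbon:
            log2v += c_eff
        if row.light:
            log2v += l_eff
        if row.genotype == "mut" and row.light:
            log2v += gxl_eff
        if config.noise_log2_sd > 0:
            log2v = log2v + rng.normal(0.0, config.noise_log2_sd, size=n)
        cols[row.sample] = np.exp2(log2v)
    matrix = pd.DataFrame(cols, index=pd.Index(ids, name="gene_id"))
    return matrix, design


# ---------------------------------------------------------------------------
# full study + fixtures on disk
# ---------------------------------------------------------------------------

def chip_library_design(config: SyntheticConfig) -> list[dict]:
    """Enumerate the ChIP libraries of the study design.

    Per genotype and treatment condition: ``n_chip_reps`` mark-ChIP
    replicates and one input.  The enzyme-binding library (plus its input)
    is profiled once, in the untreated condition, on the WT background of
    the tagged line.
    """
    libs = []
    for genotype in GENOTYPES:
        for carbon, light in config.chip_conditions:
            for rep in range(1, config.n_chip_reps + 1):
                libs.append(dict(genotype=genotype, carbon=carbon, light=light,
                                 library_kind="chip_mark", rep=rep))
            libs.append(dict(genotype=genotype, carbon=carbon, light=light,
                             library_kind="input", rep=1))
    for rep in range(1, config.n_chip_reps + 1):
        libs.append(dict(genotype="WT", carbon=False, light=False,
                         library_kind="chip_binding", rep=rep))
    libs.append(dict(genotype="WT", carbon=False, light=False,
                     library_kind="binding_input", rep=1))
    return libs


def _lib_name(lib: dict) -> str:
    return (
        f"{lib['genotype']}_C{int(lib['carbon'])}_L{int(lib['light'])}"
        f"_{lib['library_kind']}_rep{lib['rep']}"
    )


def simulate_study(config: SyntheticConfig):
    """Generate the whole study in memory.

    Returns a dict with the annotation, truth, a ``{name: FragmentSet}``
    map covering the ChIP design, the expression matrix and sample sheet.
    Library seeds are derived deterministically from ``config.seed``.
    """
    annotation, truth = build_annotation(config)
    seed_seq = np.random.SeedSequence(config.seed)
    lib_specs = chip_library_design(config)
    child_seeds = seed_seq.spawn(len(lib_specs) + 1)
    fragment_sets = {}
    for lib, ss in zip(lib_specs, child_seeds[:-1]):
        kind = "input" if lib["library_kind"] == "binding_input" else lib["library_kind"]
        seed = int(ss.generate_state(1)[0] % (2**31))
        fragment_sets[_lib_name(lib)] = simulate_chip_fragments(
            annotation, truth, lib["genotype"], kind, config, seed
        )
    expr_seed = int(child_seeds[-1].generate_state(1)[0] % (2**31))
    matrix, design = simulate_expression(truth, config, expr_seed)
    return {
        "annotation": annotation,
        "truth": truth,
        "fragment_sets": fragment_sets,
        "expression": matrix,
        "design": design,
    }


def write_fixtures(annotation, truth, fragment_sets, expression, design, outdir):
    """Write the study to plain-text fixtures and return a file manifest.

    GFF3 annotation, one BED per library, TSV expression matrix with a
    sample-design sidecar, TSV truth table.  Everything round-trips through
    the package readers.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    manifest = {}

    def _path(name):
        return os.path.join(outdir, name)

    try:
        write_gff3(annotation, _path("annotation.gff3"))
        manifest["annotation"] = _path("annotation.gff3")
        for name, frags in fragment_sets.items():
            write_bed(frags, _path(f"{name}.bed"))
            manifest[name] = _path(f"{name}.bed")
        expression.to_csv(_path("expression.tsv"), sep="\t")
        manifest["expression"] = _path("expression.tsv")
        design.to_csv(_path("samples.tsv"), sep="\t", index=False)
        manifest["samples"] = _path("samples.tsv")
        truth.frame.to_csv(_path("truth.tsv"), sep="\t")
        manifest["truth"] = _path("truth.tsv")
    except OSError as err:
        raise OSError(f"failed writing fixtures under {outdir}: {err}") from err
    return manifest


def read_truth(path) -> GroundTruth:
    frame = pd.read_csv(path, sep="\t", index_col="gene_id")
    for col in ("marked", "hypo", "bound", "c_responsive", "l_responsive", "gxl"):
        frame[col] = frame[col].astype(bool)
    return GroundTruth(frame)
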