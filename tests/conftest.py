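import numpy as np
import pandas as pd
import pytest

import epimark as em


def small_config(**overrides):
    """Desk-scale study small enough for unit tests."""
    base = dict(
        n_genes=60,
        chrom_lengths={"chrA": 150_000, "chrB": 150_000},
        gene_length_range=(800, 1_600),
        intergenic_gap_range=(600, 1_400),
        library_size=60_000,
        seed=7,
    )
    base.update(overrides)
    return em.SyntheticConfig(**base)


@pytest.fixture(scope="session")
def cfg():
    return small_config()


@pytest.fixture(scope="session")
def study(cfg):
    annotation, truth = em.build_annotation(cfg)
    return annotation, truth


@pytest.fixture(scope="session")
def libraries(cfg, study):
    """Deduplicated WT/mut mark-ChIP + input libraries for the small study."""
    annotation, truth = study
    dd = em.deduplicate_fragments
    return {
        "chip_wt": dd(em.simulate_chip_fragments(annotation, truth, "WT",
                                                 "chip_mark", cfg, 11)),
        "chip_mut": dd(em.simulate_chip_fragments(annotation, truth, "mut",
                                                  "chip_mark", cfg, 12)),
        "input_wt": dd(em.simulate_chip_fragments(annotation, truth, "WT",
                                                  "input", cfg, 13)),
        "input_mut": dd(em.simulate_chip_fragments(annotation, truth, "mut",
                                                   "input", cfg, 14)),
    }


@pytest.fixture(scope="session")
def wt_islands(cfg, study, libraries):
    annotation, _ = study
    return em.call_islands(libraries["chip_wt"], libraries["input_wt"],
                           annotation.chrom_lengths)


def random_fragments(rng, chrom_lengths, n, frag_len=200, with_dups=False):
    chroms = sorted(chrom_lengths)
    which = rng.integers(0, len(chroms), size=n)
    rows = []
    for i, ci in enumerate(which):
        chrom = chroms[ci]
        L = chrom_lengths[chrom]
        start = int(rng.integers(0, L - frag_len))
        rows.append((chrom, start, start + frag_len,
                     "+" if rng.random() < 0.5 else "-"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    if with_dups:
        extra = df.sample(n=n // 3, replace=True, random_state=0)
        df = pd.concat([df, extra], ignore_index=True)
    return em.FragmentSet(df)
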