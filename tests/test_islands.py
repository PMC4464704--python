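"""Island-calling contracts: deduplication, coverage, island and
differential-island calling, and gene annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import epimark as em
from epimark.core import FragmentSet, frames_equal
from epimark.islands import IslandParams, bh_adjust, read_islands, write_islands

from conftest import random_fragments


def _frag(rows):
    return FragmentSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    )


class TestDeduplicate:
    def test_no_duplicates_identity(self):
        fs = _frag([("chr1", 0, 200, "+"), ("chr1", 300, 500, "-")])
        out = em.deduplicate_fragments(fs, 1)
        assert frames_equal(out.frame, fs.frame)

    def test_triplicate_collapsed(self):
        fs = _frag([("chr1", 100, 300, "+")] * 3 + [("chr1", 500, 700, "-")])
        out = em.deduplicate_fragments(fs, 1)
        assert out.library_size == 2

    def test_threshold_two_keeps_two(self):
        fs = _frag([("chr1", 100, 300, "+")] * 5)
        assert em.deduplicate_fragments(fs, 2).library_size == 2

    def test_matches_hash_count_oracle(self):
        rng = np.random.default_rng(0)
        fs = random_fragments(rng, {"c1": 10_000, "c2": 8_000}, 400,
                              frag_len=50, with_dups=True)
        for thr in (1, 2, 3):
            out = em.deduplicate_fragments(fs, thr)
            from collections import Counter
            keys = Counter(map(tuple, fs.frame.to_numpy().tolist()))
            expected = sum(min(thr, m) for m in keys.values())
            assert out.library_size == expected

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        fs = random_fragments(rng, {"c1": 5_000}, 300, frag_len=50,
                              with_dups=True)
        once = em.deduplicate_fragments(fs, 1)
        twice = em.deduplicate_fragments(once, 1)
        assert frames_equal(once.frame, twice.frame)

    def test_order_independent(self):
        rng = np.random.default_rng(2)
        fs = random_fragments(rng, {"c1": 5_000}, 200, with_dups=True)
        shuffled = FragmentSet(
            fs.frame.sample(frac=1, random_state=5).reset_index(drop=True)
        )
        a = em.deduplicate_fragments(fs, 1)
        b = em.deduplicate_fragments(shuffled, 1)
        assert frames_equal(a.frame, b.frame)


class TestCoverage:
    def test_single_fragment(self):
        fs = _frag([("chr1", 0, 100, "+")])
        cov = em.compute_coverage(fs, {"chr1": 500})
        arr = cov.chrom("chr1")
        assert (arr[:100] == 1).all() and (arr[100:] == 0).all()
        assert cov.total_mass == 100

    def test_rpm_scaling_exact(self):
        fs = _frag([("chr1", 0, 100, "+")] * 4)
        raw = em.compute_coverage(em.deduplicate_fragments(fs, 4),
                                  {"chr1": 500})
        rpm = em.compute_coverage(em.deduplicate_fragments(fs, 4),
                                  {"chr1": 500}, rpm=True)
        assert rpm.total_mass == pytest.approx(raw.total_mass * 1e6 / 4)
        assert rpm.rpm_factor == 1e6 / 4

    def test_mass_conservation_random(self):
        rng = np.random.default_rng(3)
        fs = random_fragments(rng, {"c1": 20_000, "c2": 10_000}, 500,
                              frag_len=80)
        cov = em.compute_coverage(fs, {"c1": 20_000, "c2": 10_000})
        assert cov.total_mass == pytest.approx(
            float((fs.frame["end"] - fs.frame["start"]).sum())
        )

    def test_out_of_bounds_rejected(self):
        fs = _frag([("chr1", 450, 650, "+")])
        with pytest.raises(ValueError):
            em.compute_coverage(fs, {"chr1": 500})


def _uniform_library(rng, G, n, frag_len=200):
    starts = np.sort(rng.integers(0, G - frag_len, size=rng.poisson(n)))
    return _frag([("chr1", int(s), int(s) + frag_len, "+") for s in starts])


class TestCallIslands:
    def test_boundaries_window_aligned(self, cfg, study, libraries):
        annotation, _ = study
        isl = em.call_islands(libraries["chip_wt"], libraries["input_wt"],
                              annotation.chrom_lengths)
        assert len(isl) > 0
        assert (isl["start"] % 200 == 0).all()
        assert (isl["end"] % 200 == 0).all()
        assert (isl["end"] - isl["start"] >= 200).all()

    def test_null_yields_almost_nothing(self):
        """ChIP identical in law to input: retained islands ~ FDR-rare."""
        G = 1_000_000
        n_retained = 0
        n_candidates = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            chip = _uniform_library(rng, G, 50_000)
            inp = _uniform_library(rng, G, 50_000)
            cand = em.call_islands(chip, inp, {"chr1": G}, return_all=True)
            n_candidates += len(cand)
            n_retained += int(cand["retained"].sum())
        assert n_retained <= max(2, 0.02 * n_candidates)

    def test_implant_recovered(self):
        G = 1_000_000
        rng = np.random.default_rng(9)
        implant = (400_000, 402_000)
        w = np.ones(G)
        w[implant[0]: implant[1]] = 10.0
        starts = np.sort(rng.choice(G - 200, size=20_000, p=w[:-200] / w[:-200].sum()))
        chip = _frag([("chr1", int(s), int(s) + 200, "+") for s in starts])
        inp = _uniform_library(np.random.default_rng(10), G, 20_000)
        isl = em.call_islands(chip, inp, {"chr1": G})
        assert len(isl) == 1
        s, e = int(isl.iloc[0]["start"]), int(isl.iloc[0]["end"])
        inter = max(0, min(e, implant[1]) - max(s, implant[0]))
        assert inter / (implant[1] - implant[0]) >= 0.8
        assert inter / (e - s) >= 0.8

    def test_permutation_invariant(self, study, libraries):
        annotation, _ = study
        chip = libraries["chip_wt"]
        shuffled = FragmentSet(
            chip.frame.sample(frac=1, random_state=3).reset_index(drop=True)
        )
        a = em.call_islands(chip, libraries["input_wt"],
                            annotation.chrom_lengths)
        b = em.call_islands(shuffled, libraries["input_wt"],
                            annotation.chrom_lengths)
        assert a.equals(b)

    def test_empty_chip_rejected(self):
        empty = FragmentSet(
            pd.DataFrame(columns=["chrom", "start", "end", "strand"])
        )
        with pytest.raises(ValueError):
            em.call_islands(empty, None, {"chr1": 1000})

    def test_gap_must_be_window_multiple(self):
        with pytest.raises(ValueError):
            IslandParams(window_bp=200, gap_bp=300)


class TestDifferential:
    def test_identical_libraries_no_calls(self, study, libraries):
        annotation, _ = study
        diff = em.call_differential_islands(
            libraries["chip_wt"], libraries["chip_wt"],
            annotation.chrom_lengths,
            input_a=libraries["input_wt"], input_b=libraries["input_wt"],
        )
        assert int(diff["significant"].sum()) == 0

    def test_fold_change_arithmetic(self, study, libraries):
        annotation, _ = study
        diff = em.call_differential_islands(
            libraries["chip_wt"], libraries["chip_mut"],
            annotation.chrom_lengths,
            input_a=libraries["input_wt"], input_b=libraries["input_mut"],
        )
        a, b = diff["rpm_a"], diff["rpm_b"]
        assert np.allclose(diff["fold_change"],
                           np.maximum(a, b) / np.minimum(a, b))
        assert (diff["fold_change"] >= 1).all()
        assert (diff.loc[diff["direction"] == "a_up", "rpm_a"]
                >= diff.loc[diff["direction"] == "a_up", "rpm_b"]).all()
        # pseudocounted RPM: a region with 4x the per-million rate gives ~4
        strong = diff[diff["count_a"] > 200]
        manual = ((strong["count_a"] + 0.5) / libraries["chip_wt"].library_size) \
            / ((strong["count_b"] + 0.5) / libraries["chip_mut"].library_size)
        ratio = np.where(manual >= 1, manual, 1 / manual)
        assert np.allclose(strong["fold_change"], ratio)

    def test_antisymmetric(self, study, libraries):
        annotation, _ = study
        ab = em.call_differential_islands(
            libraries["chip_wt"], libraries["chip_mut"],
            annotation.chrom_lengths,
            input_a=libraries["input_wt"], input_b=libraries["input_mut"],
        )
        ba = em.call_differential_islands(
            libraries["chip_mut"], libraries["chip_wt"],
            annotation.chrom_lengths,
            input_a=libraries["input_mut"], input_b=libraries["input_wt"],
        )
        assert np.allclose(ab["p_value"], ba["p_value"])
        assert (ab["count_a"].to_numpy() == ba["count_b"].to_numpy()).all()
        flipped = ba["direction"].map({"a_up": "b_up", "b_up": "a_up"})
        # ties (equal pseudocounted rpm with equal lib sizes) cannot occur here
        assert (ab["direction"].to_numpy() == flipped.to_numpy()).all()

    def test_recovers_hypomethylated_genes(self, cfg, study, libraries):
        annotation, truth = study
        diff = em.call_differential_islands(
            libraries["chip_wt"], libraries["chip_mut"],
            annotation.chrom_lengths,
            input_a=libraries["input_wt"], input_b=libraries["input_mut"],
        )
        table = em.annotate_islands_to_genes(diff, annotation)
        called = set(table.index[table["status"] == "hypomethylated"])
        true = truth.genes_where("hypo")
        tp = len(called & true)
        assert tp / len(true) >= 0.9
        assert tp / max(len(called), 1) >= 0.9


class TestAnnotate:
    def test_island_inside_gene(self, study):
        annotation, _ = study
        g = annotation.genes[0]
        isl = pd.DataFrame(
            {"chrom": [g.chrom], "start": [g.start + 10], "end": [g.start + 60]}
        )
        table = em.annotate_islands_to_genes(isl, annotation)
        assert set(table.index[table["status"] == "marked"]) == {g.gene_id}

    def test_island_spanning_two_genes(self, study):
        annotation, _ = study
        g1, g2 = annotation.genes_on("chrA")[:2]
        isl = pd.DataFrame(
            {"chrom": ["chrA"], "start": [g1.end - 1], "end": [g2.start + 1]}
        )
        table = em.annotate_islands_to_genes(isl, annotation)
        assert set(table.index[table["status"] == "marked"]) == \
            {g1.gene_id, g2.gene_id}

    def test_min_overlap_excludes_grazing_island(self, study):
        annotation, _ = study
        g = annotation.genes[0]
        isl = pd.DataFrame(
            {"chrom": [g.chrom], "start": [g.end - 5], "end": [g.end + 200]}
        )
        table = em.annotate_islands_to_genes(isl, annotation, min_overlap_bp=10)
        assert (table["status"] == "unmarked").all()

    def test_ambiguous_gene_flagged(self, study):
        annotation, _ = study
        g = annotation.genes[0]
        mid = (g.start + g.end) // 2
        diff = pd.DataFrame(
            {
                "chrom": [g.chrom, g.chrom],
                "start": [g.start, mid],
                "end": [mid, g.end],
                "direction": ["a_up", "b_up"],
                "significant": [True, True],
            }
        )
        table = em.annotate_islands_to_genes(diff, annotation)
        assert table.loc[g.gene_id, "status"] == "ambiguous"

    def test_matches_quadratic_oracle(self, study):
        annotation, _ = study
        rng = np.random.default_rng(12)
        chroms = sorted(annotation.chrom_lengths)
        isl = pd.DataFrame(
            {
                "chrom": [chroms[i % 2] for i in range(60)],
                "start": rng.integers(0, 140_000, size=60),
            }
        )
        isl["end"] = isl["start"] + rng.integers(100, 3_000, size=60)
        table = em.annotate_islands_to_genes(isl, annotation)
        called = set(table.index[table["status"] == "marked"])
        brute = {
            g.gene_id
            for g in annotation
            for row in isl.itertuples(index=False)
            if row.chrom == g.chrom
            and min(row.end, g.end) - max(row.start, g.start) >= 1
        }
        assert called == brute


class TestBh:
    def test_hand_example(self):
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])),
                           [0.04, 0.04, 0.04, 0.04])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_bh_dominates_p_and_order_invariant(self, ps):
        p = np.array(ps)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1 + 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(bh_adjust(p[perm]), q[perm])


def test_island_io_round_trip(tmp_path, wt_islands):
    path = tmp_path / "islands.bed"
    write_islands(wt_islands, path)
    back = read_islands(path)
    for col in ("chrom", "start", "end", "chip_count"):
        assert (back[col].to_numpy() == wt_islands[col].to_numpy()).all()
    assert np.allclose(back["fdr"], wt_islands["fdr"])
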