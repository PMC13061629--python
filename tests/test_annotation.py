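"""Genome annotation: Pol II density, conservation windows, repeats."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pirslice import annotation as ann


def _track(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand"])


class TestPolIIDensity:
    def test_worked_arithmetic(self):
        """10-kb gene, 9,500 body reads after the 500-bp pause exclusion,
        depth 1e6 -> 9,500 ppm over 9.5 kb = 1,000 ppm/kb."""
        track = _track([("chr1", 500, 10_000, 1.0)])
        genes = _genes([("g1", "chr1", 0, 10_000, "+")])
        d = ann.polii_density(track, genes, depth=1e6)
        assert d["g1"] == pytest.approx(1000.0)

    def test_depth_doubling_halves_density(self):
        track = _track([("chr1", 500, 10_000, 1.0)])
        genes = _genes([("g1", "chr1", 0, 10_000, "+")])
        d1 = ann.polii_density(track, genes, depth=1e6)
        d2 = ann.polii_density(track, genes, depth=2e6)
        assert d2["g1"] == pytest.approx(d1["g1"] / 2)

    def test_pause_bump_excluded(self):
        """A huge spike inside the first 500 bp must not change density."""
        base = [("chr1", 500, 10_000, 1.0)]
        spike = [("chr1", 0, 100, 1000.0)]
        genes = _genes([("g1", "chr1", 0, 10_000, "+")])
        d_base = ann.polii_density(_track(base), genes, depth=1e6)
        d_spiked = ann.polii_density(_track(base + spike), genes, depth=1e6)
        assert d_spiked["g1"] == pytest.approx(d_base["g1"])

    def test_minus_strand_excludes_downstream_end(self):
        """On the minus strand the TSS is at the interval end, so the
        exclusion removes the last 500 bp instead of the first."""
        spike_at_end = _track([("chr1", 0, 9_500, 1.0),
                               ("chr1", 9_900, 10_000, 1000.0)])
        genes_minus = _genes([("g1", "chr1", 0, 10_000, "-")])
        genes_plus = _genes([("g1", "chr1", 0, 10_000, "+")])
        d_minus = ann.polii_density(spike_at_end, genes_minus, depth=1e6)
        d_plus = ann.polii_density(spike_at_end, genes_plus, depth=1e6)
        assert d_minus["g1"] == pytest.approx(1000.0)  # spike outside body
        assert d_plus["g1"] > d_minus["g1"]

    def test_interval_splitting_invariance(self):
        whole = _track([("chr1", 500, 10_000, 2.0)])
        split = _track([("chr1", 500, 4_000, 2.0),
                        ("chr1", 4_000, 10_000, 2.0)])
        genes = _genes([("g1", "chr1", 0, 10_000, "+")])
        assert (ann.polii_density(whole, genes, depth=1e6)["g1"]
                == pytest.approx(
                    ann.polii_density(split, genes, depth=1e6)["g1"]))

    def test_short_gene_is_nan(self):
        track = _track([("chr1", 0, 1000, 1.0)])
        genes = _genes([("tiny", "chr1", 100, 500, "+")])
        assert np.isnan(ann.polii_density(track, genes, depth=1e6)["tiny"])

    def test_depth_from_track_when_unspecified(self):
        track = _track([("chr1", 0, 1000, 1.0)])  # total signal = 1000
        genes = _genes([("g1", "chr1", 0, 1000, "+")])
        d = ann.polii_density(track, genes)
        # body = 500 bp, signal 500/1000 of library -> 5e5 ppm over 0.5 kb
        assert d["g1"] == pytest.approx(5e5 / 0.5)

    def test_nonpositive_depth_error(self):
        with pytest.raises(ValueError):
            ann.polii_density(_track([]), _genes([]), depth=0.0)


def _origins(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "pirna_id",
                                       "strand"])


def _cons_track(chrom, start, values):
    return pd.DataFrame({"chrom": chrom,
                         "start": np.arange(start, start + len(values)),
                         "end": np.arange(start, start + len(values)) + 1,
                         "value": values})


class TestGWindow:
    def test_plus_strand_window(self):
        origins = _origins([("chr1", 100, 130, "p1", "+")])  # 30-nt piRNA
        w = ann.g_window(origins)
        assert w["start"].iloc[0] == 101  # g2 = start + 1
        assert w["end"].iloc[0] == 130    # g30 = position 129

    def test_minus_strand_window(self):
        origins = _origins([("chr1", 100, 130, "p1", "-")])
        w = ann.g_window(origins)
        # g1 at end-1 = 129, so g2 = 128 and the window end excludes g1
        assert w["end"].iloc[0] == 129
        assert w["start"].iloc[0] == 100  # g30 = position 100

    def test_short_pirna_clipped(self):
        origins = _origins([("chr1", 100, 126, "p1", "+")])  # 26 nt
        w = ann.g_window(origins)
        assert w["end"].iloc[0] == 126  # cannot extend past the origin


class TestConservationProfile:
    def test_constant_track_gives_constant(self):
        origins = ann.g_window(_origins([("chr1", 100, 130, "p1", "+"),
                                         ("chr1", 200, 230, "p2", "+")]))
        track = _cons_track("chr1", 0, np.full(400, 0.37))
        prof = ann.conservation_profile(origins, track)
        assert np.allclose(prof["per_pirna"], 0.37)
        assert prof["cohort"]["median"] == pytest.approx(0.37)
        assert np.allclose(prof["position_median"], 0.37)
        assert prof["skipped"] == 0

    def test_minus_strand_g2_maps_to_end_minus_1(self):
        """Plant a unique score at the interval's end-1 coordinate and a
        different one everywhere else: g2 of a minus-strand window must
        read the end-1 value."""
        values = np.zeros(300)
        values[128] = 0.9  # end-1 of the g2..g30 window below
        track = _cons_track("chr1", 0, values)
        window = _origins([("chr1", 100, 129, "p1", "-")])  # pre-cut window
        prof = ann.conservation_profile(window, track)
        assert prof["position_median"][2] == pytest.approx(0.9)
        assert prof["position_median"][3] == pytest.approx(0.0)

    def test_strand_reversal_reverses_positions(self):
        values = np.linspace(0, 1, 29)
        track = _cons_track("chr1", 100, values)
        plus = _origins([("chr1", 100, 129, "p1", "+")])
        minus = _origins([("chr1", 100, 129, "p1", "-")])
        p = ann.conservation_profile(plus, track)["position_median"]
        m = ann.conservation_profile(minus, track)["position_median"]
        assert np.allclose(p.to_numpy(), m.to_numpy()[::-1])

    def test_two_class_cohort_separation(self, rng):
        """Origins on a conserved block score above random segments."""
        n_pos = 50_000
        values = rng.uniform(0, 0.2, n_pos)
        values[10_000:11_000] = rng.uniform(0.7, 1.0, 1000)  # conserved block
        track = _cons_track("chr1", 0, values)
        conserved = ann.g_window(_origins(
            [("chr1", 10_000 + 30 * i, 10_030 + 30 * i, f"c{i}", "+")
             for i in range(20)]))
        random_seg = ann.sample_segments({"chr1": n_pos}, 200, 29, rng)
        hi = ann.conservation_profile(conserved, track)
        lo = ann.conservation_profile(random_seg, track)
        assert hi["cohort"]["median"] > lo["cohort"]["median"] + 0.4
        q25, q75 = hi["cohort"]["iqr"]
        assert q25 <= hi["cohort"]["median"] <= q75

    def test_off_track_interval_skipped(self):
        track = _cons_track("chr1", 0, np.ones(10))
        origins = _origins([("chr2", 0, 29, "p1", "+")])
        prof = ann.conservation_profile(origins, track)
        assert prof["skipped"] == 1 and prof["per_pirna"].empty


class TestRepeats:
    def test_trivial_fractions(self):
        origins = _origins([("chr1", 0, 30, "p1", "+"),
                            ("chr1", 100, 130, "p2", "+")])
        all_rep = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                "end": [1000]})
        none_rep = pd.DataFrame({"chrom": ["chr1"], "start": [500],
                                 "end": [600]})
        assert ann.repeat_fraction(origins, all_rep) == 1.0
        assert ann.repeat_fraction(origins, none_rep) == 0.0

    def test_majority_rule(self):
        origins = _origins([("chr1", 0, 30, "p1", "+")])
        rep_small = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                  "end": [10]})
        rep_big = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                "end": [16]})
        assert ann.repeat_fraction(origins, rep_small, rule="any") == 1.0
        assert ann.repeat_fraction(origins, rep_small, rule="majority") == 0.0
        assert ann.repeat_fraction(origins, rep_big, rule="majority") == 1.0

    def test_matches_brute_force_pairwise(self, rng):
        chroms = ["chr1", "chr2"]
        origins = pd.DataFrame({
            "chrom": rng.choice(chroms, 300),
            "start": rng.integers(0, 10_000, 300)})
        origins["end"] = origins["start"] + rng.integers(20, 35, 300)
        origins["pirna_id"] = [f"p{i}" for i in range(300)]
        origins["strand"] = "+"
        reps = pd.DataFrame({
            "chrom": rng.choice(chroms, 100),
            "start": rng.integers(0, 10_000, 100)})
        reps["end"] = reps["start"] + rng.integers(1, 500, 100)
        flags = ann.repeat_overlap(origins, reps)
        for (_, o), got in zip(origins.iterrows(), flags):
            expect = any((r["chrom"] == o["chrom"])
                         and (r["start"] < o["end"])
                         and (o["start"] < r["end"])
                         for _, r in reps.iterrows())
            assert got == expect

    def test_empty_origins_error(self):
        with pytest.raises(ValueError):
            ann.repeat_fraction(_origins([]), pd.DataFrame(
                columns=["chrom", "start", "end"]))

    def test_bad_rule(self):
        with pytest.raises(ValueError):
            ann.repeat_fraction(_origins([("chr1", 0, 30, "p", "+")]),
                                pd.DataFrame(columns=["chrom", "start",
                                                      "end"]),
                                rule="most")


class TestSampling:
    def test_sample_segments_bounds(self, rng):
        sizes = {"chr1": 1000, "chr2": 50}
        segs = ann.sample_segments(sizes, 500, 29, rng)
        assert len(segs) == 500
        assert ((segs["end"] - segs["start"]) == 29).all()
        for _, s in segs.iterrows():
            assert 0 <= s["start"] and s["end"] <= sizes[s["chrom"]]

    def test_sample_segments_impossible_length(self, rng):
        with pytest.raises(ValueError):
            ann.sample_segments({"chr1": 10}, 5, 29, rng)

    def test_matched_random_preserves_lengths(self, rng):
        origins = _origins([("chr1", 100, 130, "p1", "+"),
                            ("chr1", 500, 526, "p2", "-")])
        rand = ann.matched_random_intervals(origins, {"chr1": 10_000}, rng)
        assert ((rand["end"] - rand["start"]).to_numpy()
                == (origins["end"] - origins["start"]).to_numpy()).all()
        assert (rand["chrom"] == origins["chrom"]).all()
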