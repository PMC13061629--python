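"""Pairing engine: oracle equivalence, tier rules, properties."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirslice import pairing

COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}
BASES = "ACGU"


def revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def brute_force_sites(guide: str, ppm: float, transcript: str) -> dict[int, str]:
    """Position-by-position reference implementation of the tier rules."""
    g = guide.upper().replace("T", "U")[:30]
    t = transcript.upper().replace("T", "U")
    L = len(g)
    out = {}
    for t1 in range(L, len(t) + 1):
        window = t[t1 - L:t1]
        # guide position g_i pairs with window base L-1-(i-1), antiparallel
        mask = [window[L - i] == COMP[g[i - 1]] for i in range(1, L + 1)]
        ext = ppm >= 1 and sum(mask[1:25]) >= 20
        c315 = ppm >= 5 and L >= 15 and all(mask[2:15])
        c316 = ppm >= 10 and L >= 16 and all(mask[2:16])
        c417 = ppm >= 50 and L >= 17 and all(mask[3:17])
        for ok, tier in ((ext, "extensive20"), (c315, "contig_g3g15"),
                         (c316, "contig_g3g16"), (c417, "contig_g4g17")):
            if ok:
                out[t1] = tier
                break
    return out


def _mutate(seq: str, n_mm: int, rng: np.random.Generator) -> str:
    chars = list(seq)
    for i in rng.choice(len(chars), size=min(n_mm, len(chars)), replace=False):
        chars[i] = rng.choice([b for b in BASES if b != chars[i]])
    return "".join(chars)


class TestPairMask:
    def test_exact_revcomp_all_true(self, rng):
        g = "".join(rng.choice(list(BASES), 22))
        assert pairing.pair_mask(g, revcomp(g)).all()

    def test_guide_vs_itself_matches_oracle(self, rng):
        g = "".join(rng.choice(list(BASES), 20))
        mask = pairing.pair_mask(g, g)
        oracle = [g[len(g) - i] == COMP[g[i - 1]] for i in range(1, len(g) + 1)]
        assert mask.tolist() == oracle

    def test_single_mismatch_at_g10(self, rng):
        g = "".join(rng.choice(list(BASES), 21))
        window = list(revcomp(g))
        # g10 pairs with window index L-10 (0-based)
        j = len(g) - 10
        window[j] = COMP[window[j]]  # any non-complementary change
        mask = pairing.pair_mask(g, "".join(window))
        assert not mask[9] and mask.sum() == len(g) - 1

    def test_wobble_flag(self):
        assert not pairing.pair_mask("G", "U")[0]
        assert pairing.pair_mask("G", "U", wobble=True)[0]
        assert pairing.pair_mask("U", "G", wobble=True)[0]
        assert not pairing.pair_mask("A", "G", wobble=True)[0]

    def test_t_accepted_as_u(self):
        assert pairing.pair_mask("A", "T")[0]

    def test_length_mismatch_and_alphabet_errors(self):
        with pytest.raises(ValueError):
            pairing.pair_mask("AC", "A")
        with pytest.raises(ValueError):
            pairing.encode("ACGN")

    def test_mask_capped_at_30(self, rng):
        g = "".join(rng.choice(list(BASES), 35))
        assert len(pairing.pair_mask(g, revcomp(g))) == 30


class TestEvaluateTier:
    def _mask(self, paired: set[int], n: int = 30) -> np.ndarray:
        return np.array([i in paired for i in range(1, n + 1)])

    def test_extensive20_at_2ppm(self):
        mask = self._mask(set(range(2, 22)))  # 20 paired in g2..g21
        assert pairing.evaluate_tier(mask, 2.0) == "extensive20"

    def test_exact_g4g17_at_60ppm(self):
        mask = self._mask(set(range(4, 18)) | {20, 22, 25, 27})  # 18 paired
        assert pairing.evaluate_tier(mask, 60.0) == "contig_g4g17"

    def test_perfect_duplex_below_floor_is_none(self):
        mask = self._mask(set(range(1, 31)))
        assert pairing.evaluate_tier(mask, 0.5) == "none"

    def test_g3g15_needs_5ppm(self):
        mask = self._mask(set(range(3, 16)))
        assert pairing.evaluate_tier(mask, 5.0) == "contig_g3g15"
        assert pairing.evaluate_tier(mask, 4.9) == "none"

    def test_g3g16_never_reported(self):
        # its floor (10 ppm) always unlocks the lower-floor g3-g15 subset
        mask = self._mask(set(range(3, 17)))
        assert pairing.evaluate_tier(mask, 10.0) == "contig_g3g15"

    @given(st.sets(st.integers(1, 30)), st.sampled_from([0.5, 1, 5, 10, 50]))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_pairing_and_abundance(self, paired, ppm):
        mask = self._mask(paired)
        base = set(pairing.satisfied_clauses(mask, ppm))
        # adding any paired position keeps every satisfied clause
        for extra in set(range(1, 31)) - paired:
            more = self._mask(paired | {extra})
            assert base <= set(pairing.satisfied_clauses(more, ppm))
        # raising abundance keeps every satisfied clause
        assert base <= set(pairing.satisfied_clauses(mask, ppm * 10))


class TestScanTranscript:
    def test_matches_brute_force_on_random_transcripts(self, rng):
        """Exhaustive oracle equality on 100 transcripts <= 500 nt."""
        for k in range(100):
            glen = int(rng.integers(16, 31))
            guide = "".join(rng.choice(list(BASES), glen))
            ppm = float(rng.choice([0.5, 2.0, 7.0, 60.0]))
            tlen = int(rng.integers(glen, 501))
            t = list("".join(rng.choice(list(BASES), tlen)))
            # embed 0-3 mutated complements so qualifying sites exist
            for _ in range(int(rng.integers(0, 4))):
                site = _mutate(revcomp(guide), int(rng.integers(0, 7)), rng)
                p = int(rng.integers(0, tlen - glen + 1))
                t[p:p + glen] = site
            transcript = "".join(t)
            got = {r.t1_position: r.tier
                   for r in pairing.scan_transcript(guide, ppm, transcript,
                                                    compute_delta_g=False)}
            assert got == brute_force_sites(guide, ppm, transcript), \
                f"disagreement on case {k}"

    def test_planted_site_cleavage_coordinate(self, rng):
        guide = "".join(rng.choice(list(BASES), 25))
        t = list("".join(rng.choice(list(BASES), 200)))
        t[120 - 25:120] = revcomp(guide)
        res = pairing.scan_transcript(guide, 60.0, "".join(t))
        hit = [r for r in res if r.t1_position == 120]
        assert hit and hit[0].predicted_cleavage == 111

    def test_random_guide_no_sites_on_random_2kb(self, rng):
        guide = "".join(rng.choice(list(BASES), 26))
        transcript = "".join(rng.choice(list(BASES), 2000))
        assert pairing.scan_transcript(guide, 1.0, transcript,
                                       compute_delta_g=False) == []

    def test_overlapping_windows_both_reported(self):
        guide = "A" * 21
        transcript = "U" * 22  # every window is a perfect duplex
        res = pairing.scan_transcript(guide, 2.0, transcript)
        assert [r.t1_position for r in res] == [21, 22]

    def test_transcript_shorter_than_guide(self):
        assert pairing.scan_transcript("A" * 20, 9.0, "U" * 10) == []

    def test_planted_truth_recall_and_decoy_fp(self, small_study):
        """100% recall of planted qualifying sites; 0 decoy false positives."""
        sp = small_study.pool.species.set_index("pirna_id")
        seqs = small_study.transcriptome.sequences
        for _, s in small_study.truth.sites.iterrows():
            guide = sp.loc[s["pirna_id"]]
            res = pairing.scan_transcript(
                str(guide["sequence"]), float(guide["mean_ppm"]),
                seqs[s["transcript_id"]], compute_delta_g=False)
            at_site = [r for r in res if r.t1_position == s["t1_position"]]
            if s["is_decoy"]:
                assert not at_site
            else:
                assert at_site and at_site[0].tier == s["tier"]


class TestSeedTargets:
    def _tables(self):
        guides = pd.DataFrame({
            "pirna_id": ["a", "b"],
            "sequence": ["UGAGGUAGUAGGUUGUAUAGUU", "UGAGGUAGUAGGUUGUAUAGUU"],
            "molecules_per_cell": [999.0, 2000.0],
        })
        seed_site = revcomp(guides.loc[0, "sequence"][1:8])
        utr3 = "A" * 30 + seed_site + "A" * 30
        transcripts = pd.DataFrame({
            "transcript_id": ["t1"],
            "sequence": "G" * 50 + utr3,
            "utr3_len": [len(utr3)],
        })
        return guides, transcripts

    def test_molecule_floor_strict(self):
        guides, transcripts = self._tables()
        out = pairing.seed_targets(guides, transcripts)
        assert set(out["pirna_id"]) == {"b"}  # 999 and exactly-1000 excluded

    def test_exactly_1000_excluded(self):
        guides, transcripts = self._tables()
        guides.loc[0, "molecules_per_cell"] = 1000.0
        out = pairing.seed_targets(guides, transcripts)
        assert set(out["pirna_id"]) == {"b"}

    def test_site_position(self):
        guides, transcripts = self._tables()
        out = pairing.seed_targets(guides, transcripts)
        assert out["utr3_offset"].tolist() == [31]

    def test_no_utr_skipped(self):
        guides, transcripts = self._tables()
        transcripts["utr3_len"] = 0
        assert pairing.seed_targets(guides, transcripts).empty


class TestTranslationCandidates:
    def _setup(self, extra_paired: int):
        guide = "UGAGGUAGUAGGUUGUAUAGUUACCGUAUA"[:30]
        g = guide[:30]
        # build a UTR window pairing g2-g8 fully plus extra_paired in g9-g30
        mask = {i for i in range(2, 9)}
        mask |= set(range(9, 9 + extra_paired))
        window = []
        for i in range(1, len(g) + 1):
            window.append(COMP[g[i - 1]] if i in mask else g[i - 1])
        site = "".join(reversed(window))
        motif = "UUUUUUU"
        utr3 = "C" * 10 + motif + "C" * 5 + site + "C" * 10
        guides = pd.DataFrame({"pirna_id": ["g1"], "sequence": [guide],
                               "locus": ["pi9"]})
        transcripts = pd.DataFrame({
            "transcript_id": ["t1"], "sequence": ["G" * 40 + utr3],
            "utr3_len": [len(utr3)]})
        return guides, transcripts, [motif]

    def test_boundary_12_accepted_11_rejected(self):
        for extra, expected in ((11, 0), (12, 1)):
            guides, transcripts, motifs = self._setup(extra)
            out = pairing.translation_candidates(guides, transcripts, motifs)
            assert len(out) == expected

    def test_no_motif_rejected(self):
        guides, transcripts, _ = self._setup(14)
        out = pairing.translation_candidates(guides, transcripts, ["AGAGAGA"])
        assert out.empty

    def test_empty_motifs_error(self):
        guides, transcripts, _ = self._setup(14)
        with pytest.raises(ValueError):
            pairing.translation_candidates(guides, transcripts, [])


class TestDeltaG:
    def test_no_pairs_zero(self):
        mask = np.zeros(20, bool)
        assert pairing.duplex_delta_g(mask, "A" * 20, "U" * 20) == 0.0

    def test_gc_more_stable_than_au(self):
        n = 21
        mask = np.ones(n, bool)
        dg_gc = pairing.duplex_delta_g(mask, "GC" * 11, None)
        dg_au = pairing.duplex_delta_g(mask, "AU" * 11, None)
        assert dg_gc < dg_au < 0

    @given(st.sets(st.integers(0, 19)), st.integers(0, 19))
    @settings(max_examples=200, deadline=None)
    def test_adding_pair_never_raises_dg(self, paired, extra):
        guide = "GCAUGCAUGCAUGCAUGCAU"
        mask = np.array([i in paired for i in range(20)])
        more = mask.copy()
        more[extra] = True
        dg0 = pairing.duplex_delta_g(mask, guide, None)
        dg1 = pairing.duplex_delta_g(more, guide, None)
        assert dg1 <= dg0 + 1e-12
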