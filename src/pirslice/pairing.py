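"""Guide–target complementarity under abundance-tiered pairing rules.

A piRNA guide binds its target antiparallel: guide position g1 (the guide's
5' end) pairs with target position t1, and successive guide positions g2, g3,
... pair with transcript nucleotides walking 3'->5' along the transcript.  In
transcript coordinates a site therefore spans ``[t1 - L + 1, t1]`` (1-based,
inclusive) for a guide of effective length L.  PIWI proteins cut the target
between the nucleotides paired to g10 and g11, so the 5' end of the 3'
cleavage fragment sits opposite g10, i.e. at transcript coordinate
``t1 - 9``.

Whether a candidate site qualifies as a cleavage target depends jointly on
the extent of pairing and on the guide's abundance.  Four clauses are
recognised, each with its own abundance floor (ppm of the small-RNA library):

========== ===========================================
>= 1 ppm    >= 20 nucleotides paired between g2 and g25
>= 5 ppm    contiguous pairing g3–g15
>= 10 ppm   contiguous pairing g3–g16
>= 50 ppm   contiguous pairing g4–g17
========== ===========================================

The clauses form a disjunction: a site qualifies if any clause whose
abundance floor the guide meets has its pairing pattern satisfied.  The
reported tier is the satisfied clause with the lowest abundance floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "PairingResult",
    "encode",
    "pair_mask",
    "evaluate_tier",
    "scan_transcript",
    "scan_pool",
    "seed_targets",
    "translation_candidates",
    "duplex_delta_g",
    "TIER_CLAUSES",
    "MAX_GUIDE_SPAN",
]

# RNA alphabet encoding; T is accepted as U.
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_IDX_BASE = "ACGU"
# Watson-Crick complement by index: A<->U, C<->G
_WC = np.array([3, 2, 1, 0], dtype=np.int8)

#: Guide positions beyond g30 never participate in any clause.
MAX_GUIDE_SPAN = 30

#: (tier name, abundance floor in ppm), ordered by ascending floor.
TIER_CLAUSES = (
    ("extensive20", 1.0),
    ("contig_g3g15", 5.0),
    ("contig_g3g16", 10.0),
    ("contig_g4g17", 50.0),
)

# Nearest-neighbour RNA/RNA stack free energies (kcal/mol, 37 C), keyed by the
# guide-strand dinucleotide 5'-XY-3' of a Watson-Crick stack (Xia et al. 1998
# Turner parameters; non-listed entries filled by the XY -> comp(Y)comp(X)
# symmetry of a duplex read from the opposite strand).
NN_STACK_DG = {
    "AA": -0.93, "AC": -2.24, "AG": -2.08, "AU": -1.10,
    "CA": -2.11, "CC": -3.26, "CG": -2.36, "CU": -2.08,
    "GA": -2.35, "GC": -3.42, "GG": -3.26, "GU": -2.24,
    "UA": -1.33, "UC": -2.35, "UG": -2.11, "UU": -0.93,
}


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as int8 indices (A=0, C=1, G=2, U/T=3)."""
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGU(T) base in sequence: {exc}") from None


@dataclass
class PairingResult:
    """One qualifying guide-target site."""

    pirna_id: str
    transcript_id: str
    t1_position: int  # 1-based transcript coordinate paired to g1
    mask: np.ndarray  # per guide-position pairing indicator, g1..g<=30
    paired_g2_g25: int
    run_start: int  # 1-based g index of longest contiguous paired run
    run_end: int
    tier: str
    seed_match_g2g8: bool
    predicted_cleavage: int  # = t1_position - 9
    delta_g0: float = field(default=np.nan)

    def __post_init__(self) -> None:
        assert self.predicted_cleavage == self.t1_position - 9


def _effective(guide: np.ndarray) -> np.ndarray:
    return guide[:MAX_GUIDE_SPAN]


def pair_mask(guide: str | np.ndarray, window: str | np.ndarray, *,
              wobble: bool = False) -> np.ndarray:
    """Antiparallel Watson-Crick pairing mask of a guide against one window.

    ``window`` is the transcript substring covered by the site, given 5'->3'
    in transcript orientation and the same length as the guide.  ``mask[i]``
    is True iff guide position g(i+1) is complementary to its partner; mask
    length is capped at 30 guide positions.  G:U wobble counts as unpaired
    unless ``wobble`` is set.
    """
    g = encode(guide) if isinstance(guide, str) else np.asarray(guide, dtype=np.int8)
    w = encode(window) if isinstance(window, str) else np.asarray(window, dtype=np.int8)
    if len(g) != len(w):
        raise ValueError(f"window length {len(w)} != guide length {len(g)}")
    partner = w[::-1]  # partner[i] faces guide position g(i+1)
    mask = partner == _WC[g]
    if wobble:
        mask |= ((g == _BASE_INDEX["G"]) & (partner == _BASE_INDEX["U"])) | (
            (g == _BASE_INDEX["U"]) & (partner == _BASE_INDEX["G"]))
    return mask[:MAX_GUIDE_SPAN]


def _clause_satisfied(mask: np.ndarray, tier: str) -> bool:
    n = len(mask)
    if tier == "extensive20":
        return int(mask[1:25].sum()) >= 20
    if tier == "contig_g3g15":
        return n >= 15 and bool(mask[2:15].all())
    if tier == "contig_g3g16":
        return n >= 16 and bool(mask[2:16].all())
    if tier == "contig_g4g17":
        return n >= 17 and bool(mask[3:17].all())
    raise ValueError(f"unknown tier {tier!r}")


def satisfied_clauses(mask: np.ndarray, abundance_ppm: float) -> list[str]:
    """All clauses whose abundance floor is met and whose pattern holds."""
    return [t for t, floor in TIER_CLAUSES
            if abundance_ppm >= floor and _clause_satisfied(mask, t)]


def evaluate_tier(mask: np.ndarray, abundance_ppm: float) -> str:
    """Reported tier: satisfied clause with the lowest abundance floor.

    Returns ``"none"`` when no clause qualifies.
    """
    hits = satisfied_clauses(mask, abundance_ppm)
    return hits[0] if hits else "none"


def _longest_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, end) 1-based guide indices of the longest paired run; (0, 0) if none."""
    best = (0, 0)
    best_len = 0
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        if (not m or i == len(mask) - 1) and start is not None:
            end = i if m else i - 1
            if end - start + 1 > best_len:
                best_len = end - start + 1
                best = (start + 1, end + 1)
            start = None
    return best


def scan_transcript(guide: str, abundance_ppm: float, transcript: str, *,
                    pirna_id: str = "guide", transcript_id: str = "transcript",
                    wobble: bool = False, compute_delta_g: bool = True,
                    ) -> list[PairingResult]:
    """Evaluate every window of a transcript against one guide.

    Returns qualifying sites (tier != none) sorted by coordinate.  Overlapping
    qualifying windows are all reported.
    """
    g_full = encode(guide)
    g = _effective(g_full)
    L = len(g)
    enc_t = encode(transcript)
    if len(enc_t) < L:
        return []
    # windows[j] covers transcript[j : j+L]; its t1 is j+L (1-based).
    windows = sliding_window_view(enc_t, L)
    # Full pairing would make the window equal the guide's reverse complement.
    mask_win = windows == _WC[g][::-1][None, :]
    if wobble:
        gw = g[::-1][None, :]
        mask_win = mask_win | (
            ((gw == _BASE_INDEX["G"]) & (windows == _BASE_INDEX["U"]))
            | ((gw == _BASE_INDEX["U"]) & (windows == _BASE_INDEX["G"])))
    mask_g = mask_win[:, ::-1]  # column i <-> guide position g(i+1)

    paired_g2_g25 = mask_g[:, 1:25].sum(axis=1)
    ok_ext = (paired_g2_g25 >= 20) if abundance_ppm >= 1.0 else np.zeros(len(mask_g), bool)
    ok_315 = mask_g[:, 2:15].all(axis=1) if (L >= 15 and abundance_ppm >= 5.0) else np.zeros(len(mask_g), bool)
    ok_316 = mask_g[:, 2:16].all(axis=1) if (L >= 16 and abundance_ppm >= 10.0) else np.zeros(len(mask_g), bool)
    ok_417 = mask_g[:, 3:17].all(axis=1) if (L >= 17 and abundance_ppm >= 50.0) else np.zeros(len(mask_g), bool)
    any_ok = ok_ext | ok_315 | ok_316 | ok_417

    results: list[PairingResult] = []
    for j in np.flatnonzero(any_ok):
        mask = mask_g[j]
        tier = ("extensive20" if ok_ext[j] else
                "contig_g3g15" if ok_315[j] else
                "contig_g3g16" if ok_316[j] else "contig_g4g17")
        t1 = int(j) + L
        run_start, run_end = _longest_run(mask)
        dg = duplex_delta_g(mask, g, windows[j]) if compute_delta_g else np.nan
        results.append(PairingResult(
            pirna_id=pirna_id, transcript_id=transcript_id, t1_position=t1,
            mask=mask, paired_g2_g25=int(paired_g2_g25[j]),
            run_start=run_start, run_end=run_end, tier=tier,
            seed_match_g2g8=bool(mask[1:8].all()),
            predicted_cleavage=t1 - 9, delta_g0=dg))
    return results


def scan_pool(pool: pd.DataFrame, transcripts: dict[str, str], *,
              wobble: bool = False, compute_delta_g: bool = False,
              ) -> pd.DataFrame:
    """Scan every (guide, transcript) combination.

    ``pool`` needs columns ``pirna_id``, ``sequence``, ``mean_ppm`` and
    optionally ``locus``.  Returns a tidy site table.
    """
    rows = []
    loci = (dict(zip(pool["pirna_id"], pool["locus"]))
            if "locus" in pool.columns else {})
    for _, guide in pool.iterrows():
        for tid, seq in transcripts.items():
            for r in scan_transcript(
                    guide["sequence"], float(guide["mean_ppm"]), seq,
                    pirna_id=str(guide["pirna_id"]), transcript_id=tid,
                    wobble=wobble, compute_delta_g=compute_delta_g):
                rows.append({
                    "pirna_id": r.pirna_id, "transcript_id": r.transcript_id,
                    "t1_position": r.t1_position, "tier": r.tier,
                    "paired_g2_g25": r.paired_g2_g25,
                    "run_start": r.run_start, "run_end": r.run_end,
                    "seed_match_g2g8": r.seed_match_g2g8,
                    "predicted_cleavage": r.predicted_cleavage,
                    "delta_g0": r.delta_g0,
                    "locus": loci.get(r.pirna_id, ""),
                })
    cols = ["pirna_id", "transcript_id", "t1_position", "tier",
            "paired_g2_g25", "run_start", "run_end", "seed_match_g2g8",
            "predicted_cleavage", "delta_g0", "locus"]
    return pd.DataFrame(rows, columns=cols)


def _revcomp(seq: str) -> str:
    return "".join(_IDX_BASE[_WC[_BASE_INDEX[b]]] for b in reversed(seq.upper()))


def seed_targets(guides: pd.DataFrame, transcripts: pd.DataFrame, *,
                 min_molecules: float = 1000.0) -> pd.DataFrame:
    """miRNA-like candidate sites: perfect g2–g8 complements in 3' UTRs.

    ``guides`` needs ``pirna_id``, ``sequence`` and ``molecules_per_cell``;
    guides below ``min_molecules`` are skipped (the convention is a strict
    ``>`` on 1,000 molecules per cell when the default is used).
    ``transcripts`` needs ``transcript_id``, ``sequence`` and ``utr3_len``
    (transcripts without an annotated 3' UTR are skipped).
    """
    rows = []
    for _, g in guides.iterrows():
        if not float(g["molecules_per_cell"]) > min_molecules:
            continue
        seed_site = _revcomp(str(g["sequence"])[1:8])  # complement of g2..g8
        for _, t in transcripts.iterrows():
            utr3_len = int(t.get("utr3_len", 0) or 0)
            if utr3_len <= 0:
                continue
            utr3 = str(t["sequence"]).upper().replace("T", "U")[-utr3_len:]
            start = 0
            while True:
                k = utr3.find(seed_site, start)
                if k < 0:
                    break
                rows.append({"pirna_id": g["pirna_id"],
                             "transcript_id": t["transcript_id"],
                             "utr3_offset": k + 1})
                start = k + 1
    return pd.DataFrame(rows, columns=["pirna_id", "transcript_id", "utr3_offset"])


def translation_candidates(guides: pd.DataFrame, transcripts: pd.DataFrame,
                           motif_set: list[str], *,
                           min_g9_g30_paired: int = 12) -> pd.DataFrame:
    """Translation-regulation candidates.

    A transcript qualifies when its 3' UTR contains at least one motif
    occurrence (e.g. an ELAVL1-binding motif) and a site fully paired at
    g2–g8 with at least ``min_g9_g30_paired`` additional paired positions in
    g9–g30.  Candidates are labelled by guide locus when available.
    """
    if not motif_set:
        raise ValueError("motif_set must be nonempty")
    motifs = [m.upper().replace("T", "U") for m in motif_set]
    rows = []
    for _, t in transcripts.iterrows():
        utr3_len = int(t.get("utr3_len", 0) or 0)
        if utr3_len <= 0:
            continue
        utr3 = str(t["sequence"]).upper().replace("T", "U")[-utr3_len:]
        if not any(m in utr3 for m in motifs):
            continue
        enc_u = encode(utr3)
        for _, g in guides.iterrows():
            gseq = _effective(encode(str(g["sequence"])))
            L = len(gseq)
            if len(enc_u) < L:
                continue
            windows = sliding_window_view(enc_u, L)
            mask_g = (windows == _WC[gseq][::-1][None, :])[:, ::-1]
            ok = mask_g[:, 1:8].all(axis=1) & (mask_g[:, 8:30].sum(axis=1) >= min_g9_g30_paired)
            for j in np.flatnonzero(ok):
                rows.append({"pirna_id": g["pirna_id"],
                             "transcript_id": t["transcript_id"],
                             "locus": g.get("locus", ""),
                             "utr3_t1": int(j) + L,
                             "paired_g9_g30": int(mask_g[j, 8:30].sum())})
    return pd.DataFrame(rows, columns=["pirna_id", "transcript_id", "locus",
                                       "utr3_t1", "paired_g9_g30"])


def duplex_delta_g(mask: np.ndarray, guide: str | np.ndarray,
                   window: str | np.ndarray, *, init_penalty: float = 0.0,
                   loop_penalty: float = 0.0) -> float:
    """Stacking free energy of the predicted duplex (kcal/mol, 37 C).

    Nearest-neighbour stack terms are summed over consecutive paired guide
    positions; unpaired positions each add ``loop_penalty`` and a duplex with
    at least one stack adds ``init_penalty``.  Defaults report the bare
    stacking sum, so more negative always means more stable and adding a
    stack can never raise the value.
    """
    g = encode(guide) if isinstance(guide, str) else np.asarray(guide, dtype=np.int8)
    g = _effective(g)
    mask = np.asarray(mask, dtype=bool)
    dg = 0.0
    n_stacks = 0
    for i in range(min(len(mask), len(g)) - 1):
        if mask[i] and mask[i + 1]:
            dg += NN_STACK_DG[_IDX_BASE[g[i]] + _IDX_BASE[g[i + 1]]]
            n_stacks += 1
    dg += loop_penalty * int((~mask).sum())
    if n_stacks:
        dg += init_penalty
    return dg
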