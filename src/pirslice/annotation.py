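"""Genomic context of piRNA origins: transcription, conservation, repeats.

Works on plain interval tables (bedGraph-style DataFrames with chrom, start,
end and, where relevant, value columns; half-open 0-based coordinates).

Conservation is profiled over guide positions g2-g30 (g1 is skipped because
its base composition is constrained by the 1U bias), so the intervals handed
to :func:`conservation_profile` span exactly the profiled positions: the
5'-most profiled position (g2 by default) sits at ``start`` on the plus
strand and at ``end - 1`` on the minus strand.  Use :func:`g_window` to cut
such windows out of full piRNA origin intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = ["polii_density", "g_window", "conservation_profile",
           "repeat_overlap", "repeat_fraction", "sample_segments",
           "matched_random_intervals"]

PAUSE_EXCLUSION_BP = 500
G_PROFILE_START, G_PROFILE_END = 2, 30


def polii_density(track: pd.DataFrame, gene_models: pd.DataFrame, *,
                  depth: float | None = None,
                  pause_exclusion_bp: int = PAUSE_EXCLUSION_BP) -> pd.Series:
    """Gene-body Pol II density from nascent (GRO-seq) coverage.

    Promoter-proximal pausing inflates signal near the TSS, so the
    ``pause_exclusion_bp`` nearest the TSS (strand-aware) are excluded.
    Density = signal in the remaining body / total library signal * 1e6 /
    body length in kb (ppm per kb).  Genes no longer than the exclusion
    window get NaN.
    """
    if depth is None:
        depth = float((track["value"]
                       * (track["end"] - track["start"])).sum())
    if depth <= 0:
        raise ValueError("library depth must be positive")
    by_chrom = dict(tuple(track.groupby("chrom")))
    out = {}
    for _, g in gene_models.iterrows():
        if g["end"] - g["start"] <= pause_exclusion_bp:
            out[g["gene_id"]] = np.nan
            continue
        if g.get("strand", "+") == "-":
            body_start, body_end = g["start"], g["end"] - pause_exclusion_bp
        else:
            body_start, body_end = g["start"] + pause_exclusion_bp, g["end"]
        sub = by_chrom.get(g["chrom"])
        if sub is None:
            out[g["gene_id"]] = 0.0
            continue
        lo = np.maximum(sub["start"].to_numpy(), body_start)
        hi = np.minimum(sub["end"].to_numpy(), body_end)
        covered = np.clip(hi - lo, 0, None)
        reads = float((sub["value"].to_numpy() * covered).sum())
        kb = (body_end - body_start) / 1e3
        out[g["gene_id"]] = reads / depth * 1e6 / kb
    return pd.Series(out, name="density_ppm_per_kb")


def g_window(origins: pd.DataFrame, *, g_start: int = G_PROFILE_START,
             g_end: int = G_PROFILE_END) -> pd.DataFrame:
    """Cut the g_start..g_end window out of full origin intervals.

    Full origins have g1 at their 5' end (``start`` on plus, ``end - 1`` on
    minus).  Windows are clipped to the origin's own extent when the piRNA
    is shorter than ``g_end``.
    """
    out = origins.copy()
    span = g_end - g_start + 1
    minus = out["strand"] == "-"
    plus_start = out["start"] + (g_start - 1)
    out.loc[~minus, "start"] = plus_start[~minus]
    out.loc[~minus, "end"] = np.minimum(plus_start[~minus] + span,
                                        origins.loc[~minus, "end"])
    minus_end = out["end"] - (g_start - 1)
    out.loc[minus, "end"] = minus_end[minus]
    out.loc[minus, "start"] = np.maximum(minus_end[minus] - span,
                                         origins.loc[minus, "start"])
    return out


def conservation_profile(intervals: pd.DataFrame, conservation: pd.DataFrame,
                         *, g_start: int = G_PROFILE_START,
                         g_end: int = G_PROFILE_END) -> dict:
    """Per-piRNA median conservation over g_start..g_end + cohort summary.

    ``intervals`` span exactly the profiled guide positions (see module
    docstring): on the plus strand g_i sits at ``start + (i - g_start)``, on
    the minus strand at ``end - 1 - (i - g_start)``; in particular a
    minus-strand g2 maps to ``end - 1``.  Intervals falling off the score
    track are skipped and counted in the log.  Returns per-piRNA medians, a
    per-position matrix, the cohort median/IQR and a skip log.
    """
    pos_index: dict[str, pd.Series] = {}
    for chrom, sub in conservation.groupby("chrom"):
        pos_index[chrom] = pd.Series(sub["value"].to_numpy(),
                                     index=sub["start"].to_numpy())
    g_range = np.arange(g_start, g_end + 1)
    rows, ids, skipped = [], [], 0
    for _, o in intervals.iterrows():
        if o["strand"] == "-":
            coords = o["end"] - 1 - (g_range - g_start)
            coords = np.where(coords >= o["start"], coords, -1)
        else:
            coords = o["start"] + (g_range - g_start)
            coords = np.where(coords < o["end"], coords, -1)
        track = pos_index.get(o["chrom"])
        if track is None:
            skipped += 1
            continue
        vals = track.reindex(coords).to_numpy(float)
        vals[coords < 0] = np.nan
        if np.all(np.isnan(vals)):
            skipped += 1
            continue
        rows.append(vals)
        ids.append(o.get("pirna_id", len(ids)))
    mat = (np.vstack(rows) if rows
           else np.empty((0, len(g_range))))
    with np.errstate(invalid="ignore"):
        per_pirna = pd.Series(np.nanmedian(mat, axis=1) if len(mat) else [],
                              index=ids, name="median_score", dtype=float)
    cohort = {
        "median": float(per_pirna.median()) if len(per_pirna) else np.nan,
        "iqr": ((float(per_pirna.quantile(0.25)),
                 float(per_pirna.quantile(0.75)))
                if len(per_pirna) else (np.nan, np.nan)),
    }
    with np.errstate(invalid="ignore"):
        position_median = (pd.Series(np.nanmedian(mat, axis=0), index=g_range)
                           if len(mat) else pd.Series(dtype=float))
    return {"per_pirna": per_pirna, "cohort": cohort,
            "position_median": position_median, "skipped": skipped}


def _trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in intervals.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(sub["start"], sub["end"])
            if e > s)
    return trees


def repeat_overlap(origins: pd.DataFrame, repeats: pd.DataFrame, *,
                   rule: str = "any") -> pd.Series:
    """Per-origin repeat overlap flag.

    ``rule='any'``: >= 1 bp of overlap counts.  ``rule='majority'``: more
    than half of the origin's bases must be inside repeats.
    """
    if rule not in ("any", "majority"):
        raise ValueError(f"unknown rule {rule!r}")
    trees = _trees(repeats)
    flags = []
    for _, o in origins.iterrows():
        tree = trees.get(o["chrom"])
        s, e = int(o["start"]), int(o["end"])
        if tree is None:
            flags.append(False)
            continue
        hits = tree.overlap(s, e)
        if rule == "any":
            flags.append(bool(hits))
        else:
            covered = sum(min(e, iv.end) - max(s, iv.begin) for iv in hits)
            flags.append(covered > (e - s) / 2)
    return pd.Series(flags, index=origins["pirna_id"].to_numpy(),
                     name="repeat_origin")


def repeat_fraction(origins: pd.DataFrame, repeats: pd.DataFrame, *,
                    rule: str = "any") -> float:
    """Fraction of origin intervals overlapping repeats (see repeat_overlap)."""
    if origins.empty:
        raise ValueError("no origin intervals")
    return float(repeat_overlap(origins, repeats, rule=rule).mean())


def sample_segments(chrom_sizes: dict[str, int], n: int, length: int,
                    rng: np.random.Generator) -> pd.DataFrame:
    """N random fixed-length stranded segments, chromosomes weighted by size."""
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    ok = sizes >= length
    if not ok.any():
        raise ValueError("no chromosome can hold a segment of that length")
    p = np.where(ok, sizes, 0.0)
    p /= p.sum()
    picks = rng.choice(len(chroms), size=n, p=p)
    starts = np.array([rng.integers(0, chrom_sizes[chroms[i]] - length + 1)
                       for i in picks])
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    return pd.DataFrame({
        "chrom": [chroms[i] for i in picks],
        "start": starts, "end": starts + length,
        "pirna_id": [f"segment_{k}" for k in range(n)],
        "strand": strands,
    })


def matched_random_intervals(origins: pd.DataFrame,
                             chrom_sizes: dict[str, int],
                             rng: np.random.Generator) -> pd.DataFrame:
    """Length- and chromosome-matched random intervals for a null comparison."""
    rows = []
    for _, o in origins.iterrows():
        size = chrom_sizes[o["chrom"]]
        L = int(o["end"] - o["start"])
        if L >= size:
            start = 0
        else:
            start = int(rng.integers(0, size - L))
        rows.append((o["chrom"], start, start + L, o["pirna_id"],
                     o.get("strand", "+")))
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "pirna_id", "strand"])
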