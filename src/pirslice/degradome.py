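"""Cleavage evidence from 5'-monophosphate long-RNA 5'-end data.

PIWI slicing leaves a 5'-monophosphate on the 3' cleavage fragment, so the
5' end of a degradome read marks a candidate cleavage site.  Reads sharing a
5' end are merged into one 5'-monophosphorylated RNA species; a predicted
site counts as supported when the species at the exact predicted coordinate
is detectable in controls (>= 0.1 ppm) and, for guides removed by a locus
deletion, drops >= 8-fold in the mutant.  Because replicate pairings are few
and precious, evidence is evaluated over every (control, mutant) replicate
pairing (4 x 4 = 16 in the reference design) and summarised by the median
and IQR of the per-pairing target-set sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DETECT_PPM = 0.1
MIN_FOLD = 8.0
PSEUDOCOUNT_PPM = 0.01
TARGET_CLASS_FOLD = 1.25

__all__ = ["collapse_five_prime", "site_evidence", "permutation_calls",
           "fraction_cleaved", "call_targets", "PermutationSummary"]


def collapse_five_prime(end_table: pd.DataFrame,
                        library_sizes: dict | None = None,
                        transcript_lengths: dict | None = None,
                        ) -> tuple[pd.DataFrame, dict]:
    """Merge per-read 5'-end records into 5'-RNA species with ppm.

    ``end_table`` columns: genotype, replicate, transcript_id, position and
    either ``count`` (pre-tallied) or one row per read.  ppm is normalised
    per (genotype, replicate) library; by default the library size is the
    observed total, or pass nominal sizes keyed by (genotype, replicate).
    Records outside their transcript are rejected and logged.
    """
    df = end_table.copy()
    if "count" not in df.columns:
        df["count"] = 1
    log = {"rejected": 0}
    if transcript_lengths:
        lens = df["transcript_id"].map(transcript_lengths)
        bad = (df["position"] < 1) | (df["position"] > lens)
        log["rejected"] = int(bad.sum())
        df = df[~bad]
    if df.empty:
        return (pd.DataFrame(columns=["genotype", "replicate", "transcript_id",
                                      "position", "count", "ppm"]), log)
    out = df.groupby(["genotype", "replicate", "transcript_id", "position"],
                     as_index=False)["count"].sum()
    totals = out.groupby(["genotype", "replicate"])["count"].transform("sum")
    if library_sizes is not None:
        idx = pd.MultiIndex.from_frame(out[["genotype", "replicate"]])
        totals = pd.Series(idx.map(library_sizes.get).to_numpy(float),
                           index=out.index)
    out["ppm"] = out["count"] / totals * 1e6
    return out, log


def site_evidence(control_ppm: float, mutant_ppm: float, *,
                  detect_ppm: float = DETECT_PPM, min_fold: float = MIN_FOLD,
                  pseudocount: float = PSEUDOCOUNT_PPM,
                  mode: str = "ablated") -> dict:
    """Evidence verdict for one predicted site from one replicate pairing.

    ``mode='ablated'``: the guide's locus is deleted in the mutant, so the
    product must be detected in control AND decrease >= min_fold.
    ``mode='control'``: the guide is retained, so the product must simply be
    detectable in both genotypes.
    """
    detected = control_ppm >= detect_ppm
    fold = (control_ppm + pseudocount) / (mutant_ppm + pseudocount)
    if mode == "ablated":
        passes = bool(detected and fold >= min_fold)
    elif mode == "control":
        passes = bool(detected and mutant_ppm >= detect_ppm)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {"detected": bool(detected), "fold": float(fold), "passes": passes}


def _site_ppm_matrix(signal: pd.DataFrame, sites: pd.DataFrame,
                     replicates: list[str]) -> pd.DataFrame:
    """ppm of each site's predicted coordinate in each replicate (0 if absent)."""
    key = sites[["transcript_id", "predicted_cleavage"]].rename(
        columns={"predicted_cleavage": "position"})
    out = pd.DataFrame(0.0, index=sites.index, columns=replicates)
    for rep in replicates:
        sub = signal[signal["replicate"] == rep]
        lookup = sub.set_index(["transcript_id", "position"])["ppm"]
        idx = pd.MultiIndex.from_frame(key)
        out[rep] = lookup.reindex(idx).fillna(0.0).to_numpy()
    return out


@dataclass
class PermutationSummary:
    per_pairing_sets: dict[tuple[str, str], pd.Index]
    support: pd.Series          # per site: number of passing pairings
    n_pairings: int
    set_sizes: list[int]

    @property
    def median_size(self) -> float:
        return float(np.median(self.set_sizes))

    @property
    def iqr_size(self) -> tuple[float, float]:
        return (float(np.percentile(self.set_sizes, 25)),
                float(np.percentile(self.set_sizes, 75)))


def permutation_calls(signal: pd.DataFrame, predicted_targets: pd.DataFrame,
                      control_reps: list[str], mutant_reps: list[str], *,
                      mode: str = "ablated", detect_ppm: float = DETECT_PPM,
                      min_fold: float = MIN_FOLD,
                      pseudocount: float = PSEUDOCOUNT_PPM,
                      fold_on: str = "pairing") -> PermutationSummary:
    """Evaluate site evidence on every control x mutant replicate pairing.

    ``predicted_targets`` needs columns transcript_id and predicted_cleavage
    (one row per candidate site).  Returns the per-pairing passing sets, the
    per-site support count and the distribution of set sizes.

    ``fold_on='pairing'`` (default) computes the fold change within each
    replicate pairing; ``fold_on='means'`` computes one fold change from the
    group-mean ppm while detection stays per-replicate.
    """
    if not control_reps or not mutant_reps:
        raise ValueError("need >= 1 replicate per genotype")
    if fold_on not in ("pairing", "means"):
        raise ValueError(f"unknown fold_on {fold_on!r}")
    ctl = _site_ppm_matrix(signal, predicted_targets, control_reps)
    mut = _site_ppm_matrix(signal, predicted_targets, mutant_reps)
    mean_fold = ((ctl.mean(axis=1) + pseudocount)
                 / (mut.mean(axis=1) + pseudocount))
    sets = {}
    support = pd.Series(0, index=predicted_targets.index)
    sizes = []
    for c in control_reps:
        for m in mutant_reps:
            cp, mp = ctl[c], mut[m]
            detected = cp >= detect_ppm
            if fold_on == "means":
                fold = mean_fold
            else:
                fold = (cp + pseudocount) / (mp + pseudocount)
            if mode == "ablated":
                passing = detected & (fold >= min_fold)
            else:
                passing = detected & (mp >= detect_ppm)
            sets[(c, m)] = predicted_targets.index[passing]
            support[passing] += 1
            sizes.append(int(passing.sum()))
    return PermutationSummary(per_pairing_sets=sets, support=support,
                              n_pairings=len(control_reps) * len(mutant_reps),
                              set_sizes=sizes)


def fraction_cleaved(product_ppm: float, target_steady_state: float) -> float:
    """Ratio of 3' cleavage-product abundance to the target's steady state.

    Both quantities must be on matched units (ppm of their own libraries, or
    molecules per cell).  The ratio is not clipped.
    """
    if target_steady_state <= 0:
        raise ValueError("target steady-state level must be positive")
    return float(product_ppm) / float(target_steady_state)


def call_targets(sites: pd.DataFrame, signal: pd.DataFrame,
                 ablated_loci: set[str], control_reps: list[str],
                 mutant_reps: list[str], *,
                 expression: pd.DataFrame | None = None,
                 steady_state: pd.Series | None = None,
                 repeat_flags: pd.Series | None = None,
                 min_support_frac: float = 0.5,
                 detect_ppm: float = DETECT_PPM, min_fold: float = MIN_FOLD,
                 pseudocount: float = PSEUDOCOUNT_PPM,
                 fold_on: str = "pairing") -> dict:
    """Join pairing, degradome, exclusivity and expression evidence.

    ``sites`` is a qualifying-site table from the pairing engine with a
    ``locus`` column.  Sites of ablated-locus guides are tested under the
    detected-and-lost rule; a site also explained by a qualifying
    retained-locus guide at the same cleavage coordinate is excluded
    (exclusivity).  Sites of retained-locus guides form the control set under
    the detected-in-both rule.  A target is called when it passes in at least
    ``min_support_frac`` of the replicate pairings.

    ``expression``, if given, must be indexed by transcript with columns
    ``log2fc`` and ``fdr`` (two-allele consensus); targets are then split at
    a 1.25-fold steady-state increase (a fold of exactly 1.25 falls in the
    <=1.25 class).
    """
    if expression is not None:
        missing = set(sites["transcript_id"]) - set(expression.index)
        if missing:
            raise ValueError(
                f"transcripts absent from expression results: {sorted(missing)[:5]}")
    sites = sites.reset_index(drop=True)
    is_abl = sites["locus"].isin(ablated_loci)
    coord = list(zip(sites["transcript_id"], sites["predicted_cleavage"]))
    retained_coords = {c for c, a in zip(coord, is_abl) if not a}
    exclusive = np.array([c not in retained_coords for c in coord])

    out = {}
    for label, mask, mode in (("ablated", is_abl & exclusive, "ablated"),
                              ("control", ~is_abl, "control")):
        sub = sites[mask].copy()
        if sub.empty:
            out[label] = {"sites": sub, "summary": None}
            continue
        summ = permutation_calls(signal, sub, control_reps, mutant_reps,
                                 mode=mode, detect_ppm=detect_ppm,
                                 min_fold=min_fold, pseudocount=pseudocount,
                                 fold_on=fold_on)
        sub["support"] = summ.support
        sub["called"] = summ.support >= np.ceil(
            min_support_frac * summ.n_pairings)
        ctl_ppm = _site_ppm_matrix(signal, sub, control_reps).mean(axis=1)
        sub["product_ppm"] = ctl_ppm
        if steady_state is not None:
            ss = sub["transcript_id"].map(steady_state)
            sub["fraction_cleaved"] = [
                fraction_cleaved(p, s) if s > 0 else np.nan
                for p, s in zip(ctl_ppm, ss)]
        if expression is not None:
            sub["log2fc"] = sub["transcript_id"].map(expression["log2fc"])
            sub["fdr"] = sub["transcript_id"].map(expression["fdr"])
            sub["increase_class"] = np.where(
                2.0 ** sub["log2fc"] > TARGET_CLASS_FOLD,
                ">1.25", "<=1.25")
        if repeat_flags is not None:
            sub["repeat_origin"] = sub["pirna_id"].map(repeat_flags)
        out[label] = {"sites": sub, "summary": summ}
    out["excluded_nonexclusive"] = sites[is_abl & ~exclusive]
    return out
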