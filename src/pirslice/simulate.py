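"""Synthetic study generator with a machine-readable planted truth table.

Everything the downstream pipeline consumes can be generated here: a piRNA
pool with log-spread abundances assigned to genomic loci, transcripts
carrying planted target sites of each complementarity tier (plus near-miss
decoys), genotype-structured replicate counts with negative-binomial noise,
degradome 5'-end tables whose planted signals vanish when the guide's locus
is deleted, spike-in-containing small-RNA reads, genome-annotation tracks and
noisy burst-kinetics time courses.

The planted-target composition mirrors the in vivo structure: a small class
of efficiently cleaved, clearly derepressed targets (fold increase 1.4-4.4,
median 2); a much larger class of weakly cleaved targets whose steady-state
level barely moves (~+5%); and targets of guides from loci retained in every
genotype, which serve as the control set.  All generators are pure functions
of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import pairing
from .kinetics import burst_model

DNA = np.array(list("ACGT"))
_DNA_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

__all__ = ["SimConfig", "demo_config", "PirnaPool", "Transcriptome",
           "TruthTable",
           "gen_pirna_pool", "gen_transcriptome_with_sites",
           "gen_smallrna_reads", "default_spike_mix", "gen_degradome",
           "gen_count_matrices", "gen_genome_annotation",
           "gen_kinetic_timecourse", "simulate_all", "SimulatedStudy"]


def _revcomp_dna(seq: str) -> str:
    return "".join(_DNA_COMP[b] for b in reversed(seq))


@dataclass
class SimConfig:
    """Study conditions for the simulator.  ``seed`` is mandatory."""

    seed: int
    # --- piRNA pool ---
    n_pirnas: int = 100
    loci: tuple[str, ...] = ("pi9", "pi17", "ctlA", "ctlB")
    abundance_sigma_log10: float = 1.0   # log-normal spread of species ppm
    replicate_cv: float = 0.15           # biological jitter across replicates
    total_pirnas_per_cell: float = 1e7
    cell_volume_um3: float = 1800.0
    # small-RNA replicates per genotype; the control design has 12 libraries
    smallrna_replicates: dict[str, int] = field(
        default_factory=lambda: {"control": 12, "pi9pi17": 4})
    genotypes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"control": (), "pi9pi17": ("pi9", "pi17")})
    smallrna_residual_ppm: float = 0.02  # residual signal of deleted species
    # --- reads ---
    smallrna_depth: int = 1_000_000
    duplicate_fraction: float = 0.2      # exact PCR duplicates injected
    spike_fraction: float = 0.01         # library share of spike-in reads
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    # --- transcriptome & planted sites ---
    n_transcripts: int = 200
    utr5_len: int = 100
    cds_len: int = 900
    utr3_len: int = 500
    n_strong: int = 20        # efficiently cleaved, clearly derepressed
    n_weak: int = 120         # cleaved with little steady-state consequence
    n_control_targets: int = 40  # targets of retained-locus guides
    n_decoys: int = 20        # one paired base short of qualifying
    min_guide_ppm: float = 50.0  # planted guides are abundant species
    strong_efficiency: tuple[float, float] = (0.05, 0.3)
    weak_efficiency: tuple[float, float] = (0.0005, 0.002)
    strong_fold_range: tuple[float, float] = (1.4, 4.4)  # median ~2
    weak_fold: float = 1.05
    expression_median: float = 200.0     # baseline NB mean (counts)
    expression_sigma_ln: float = 1.0
    # --- degradome ---
    degradome_depth: int = 1_000_000
    degradome_replicates: dict[str, int] = field(
        default_factory=lambda: {"control": 4, "pi9pi17": 4})
    # Background occupancy is kept sparse (~0.015 * 1e6 reads over ~3e5
    # positions, i.e. ~0.05 reads/position) so that almost every position is
    # empty and the 0.1 ppm detection threshold separates signal from noise,
    # matching the per-position occupancy of real 5'-monophosphate libraries.
    degradome_background_fraction: float = 0.015
    degradome_capture: float = 0.05      # site ppm per (efficiency x TPM)
    ablation_factor: float = 100.0       # signal loss when the locus is gone
    # --- count matrices ---
    nb_dispersion: float = 0.05
    rna_replicates: int = 4              # per group (control, em1, em2)
    rfp_replicates: int = 4
    gro_replicates: int = 3
    gro_scale: float = 0.05              # coverage per base per baseline unit
    gro_pause_factor: float = 5.0        # 5' pause bump inside first 500 bp
    # --- annotation tracks ---
    repeat_prob_targeted: float = 0.41
    repeat_prob_untargeted: float = 0.17

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory: no hidden randomness")
        for name in ("n_pirnas", "n_transcripts", "smallrna_depth",
                     "degradome_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for geno, abl in self.genotypes.items():
            unknown = set(abl) - set(self.loci)
            if unknown:
                raise ValueError(
                    f"genotype {geno!r} ablates unknown loci {sorted(unknown)}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def demo_config(seed: int) -> SimConfig:
    """Demo study conditions for end-to-end target recovery.

    100 piRNAs, 200 transcripts, 20 planted cleavage targets (efficiency
    >= 0.05), 4+4 degradome replicates at depth 1e6.  The weak class is
    made complementarity-only (efficiency 0, fold 1): those sites qualify on
    pairing but leave no cleavage product and no derepression, so target
    recovery is well-defined and the complementarity-only site population
    carries no expression shift.
    """
    return SimConfig(seed=seed, weak_efficiency=(0.0, 0.0), weak_fold=1.0)


@dataclass
class PirnaPool:
    """Simulated piRNA species with per-replicate ppm."""

    species: pd.DataFrame       # pirna_id, prefix, sequence, locus, mean_ppm
    ppm: pd.DataFrame           # index pirna_id, one column per replicate
    replicate_genotype: dict[str, str]

    def replicates(self, genotype: str) -> list[str]:
        return [r for r, g in self.replicate_genotype.items() if g == genotype]


@dataclass
class Transcriptome:
    transcripts: pd.DataFrame   # transcript_id, sequence, utr5/cds/utr3_len,
    #                             baseline_mean

    @property
    def sequences(self) -> dict[str, str]:
        return dict(zip(self.transcripts["transcript_id"],
                        self.transcripts["sequence"]))

    def lengths(self) -> pd.Series:
        return self.transcripts.set_index("transcript_id")["sequence"].str.len()

    def tpm(self) -> pd.Series:
        """Baseline steady-state abundance on the TPM scale."""
        t = self.transcripts.set_index("transcript_id")
        rate = t["baseline_mean"] / t["sequence"].str.len()
        return rate / rate.sum() * 1e6


@dataclass
class TruthTable:
    """Planted ground truth: every site, decoys included."""

    sites: pd.DataFrame
    # columns: pirna_id, transcript_id, t1_position, requested_pattern, tier,
    #          seed_match, predicted_cleavage, cleavage_efficiency,
    #          derepression_fold, target_class, is_decoy
    ablated_loci: dict[str, tuple[str, ...]]

    def planted(self) -> pd.DataFrame:
        return self.sites[~self.sites["is_decoy"]]

    def validate(self, transcriptome: Transcriptome) -> None:
        lengths = self.transcripts_lengths(transcriptome)
        for _, s in self.sites.iterrows():
            L = lengths[s["transcript_id"]]
            if not (1 <= s["t1_position"] <= L):
                raise AssertionError("planted site outside its transcript")
        bad = self.sites[self.sites["is_decoy"]
                         & (self.sites["tier"] != "none")]
        if len(bad):
            raise AssertionError("decoys must not reach a qualifying tier")

    @staticmethod
    def transcripts_lengths(transcriptome: Transcriptome) -> dict[str, int]:
        return transcriptome.transcripts.set_index("transcript_id")[
            "sequence"].str.len().to_dict()


# ---------------------------------------------------------------------------
# piRNA pool
# ---------------------------------------------------------------------------

def gen_pirna_pool(cfg: SimConfig, rng: np.random.Generator | None = None,
                   ) -> PirnaPool:
    """Log-normally spread piRNA species with per-replicate ppm.

    Every replicate's ppm column sums to 1e6.  Species of loci ablated in a
    genotype collapse to a residual trace (default 0.02 ppm scale) in that
    genotype's replicates, so the <=0.1 ppm "undetectable" rule is exercised
    rather than trivialised.
    """
    rng = cfg.rng() if rng is None else rng
    prefixes: list[str] = []
    seen: set[str] = set()
    tries = 0
    while len(prefixes) < cfg.n_pirnas:
        p = "".join(DNA[rng.integers(0, 4, 25)])
        tries += 1
        if p not in seen:
            seen.add(p)
            prefixes.append(p)
        if tries > 50 * cfg.n_pirnas:
            raise RuntimeError("could not draw unique 25-nt prefixes")
    suffix_len = rng.integers(0, 7, cfg.n_pirnas)
    seqs = [p + "".join(DNA[rng.integers(0, 4, k)])
            for p, k in zip(prefixes, suffix_len)]
    loci = rng.choice(cfg.loci, cfg.n_pirnas)
    raw = 10.0 ** rng.normal(0.0, cfg.abundance_sigma_log10, cfg.n_pirnas)
    mean_ppm = raw / raw.sum() * 1e6

    species = pd.DataFrame({
        "pirna_id": [f"pir_{i:04d}" for i in range(cfg.n_pirnas)],
        "prefix": prefixes, "sequence": seqs, "locus": loci,
        "mean_ppm": mean_ppm,
    })

    cols = {}
    replicate_genotype = {}
    sigma = math.sqrt(math.log(1.0 + cfg.replicate_cv ** 2))
    for genotype, n_rep in cfg.smallrna_replicates.items():
        ablated = set(cfg.genotypes.get(genotype, ()))
        gone = species["locus"].isin(ablated).to_numpy()
        for r in range(1, n_rep + 1):
            name = f"{genotype}_{r}"
            replicate_genotype[name] = genotype
            jitter = np.exp(rng.normal(-sigma ** 2 / 2, sigma, cfg.n_pirnas))
            vals = mean_ppm * jitter
            if gone.any():
                # residual trace stays on the configured ppm scale: retained
                # species are renormalised around it, not with it
                vals = vals.copy()
                vals[gone] = cfg.smallrna_residual_ppm * np.exp(
                    rng.normal(-sigma ** 2 / 2, sigma, int(gone.sum())))
                residual_total = vals[gone].sum()
                vals[~gone] *= (1e6 - residual_total) / vals[~gone].sum()
                cols[name] = vals
            else:
                cols[name] = vals / vals.sum() * 1e6
    ppm = pd.DataFrame(cols, index=species["pirna_id"])
    return PirnaPool(species=species, ppm=ppm,
                     replicate_genotype=replicate_genotype)


# ---------------------------------------------------------------------------
# transcriptome and planted sites
# ---------------------------------------------------------------------------

_PATTERN_CYCLE = ("extensive20", "contig_g3g15", "contig_g3g16", "contig_g4g17")


def _paired_positions(pattern: str, L: int, rng: np.random.Generator,
                      decoy: bool = False) -> set[int]:
    """1-based guide positions to pair for a requested pattern.

    Decoys get one fewer paired base than the pattern requires, with the
    missing base placed so no clause can rescue the site.
    """
    if pattern == "extensive20":
        n_mm = 5 if decoy else 4  # 24 positions g2..g25, 20 (or 19) paired
        anchor = int(rng.integers(4, 16))  # breaks every contiguous clause
        others = [p for p in range(2, 26) if p != anchor]
        mm = {anchor, *rng.choice(others, n_mm - 1, replace=False).tolist()}
        return {p for p in range(2, 26) if p not in mm}
    if pattern == "contig_g3g15":
        run = set(range(3, 16))
    elif pattern == "contig_g3g16":
        run = set(range(3, 17))
    elif pattern == "contig_g4g17":
        run = set(range(4, 18))
    elif pattern == "seed_only":
        run = set(range(2, 9))
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    if decoy:
        interior = sorted(run)[1:-1]
        run = run - {int(rng.choice(interior))}
    return {p for p in run if p <= L}


def _write_site(seq_chars: list[str], t1_idx0: int, guide: str,
                paired: set[int], rng: np.random.Generator) -> None:
    """Overwrite the window ending at ``t1_idx0`` (0-based) in place."""
    g = guide.upper()[:pairing.MAX_GUIDE_SPAN]
    L = len(g)
    if t1_idx0 - L + 1 < 0 or t1_idx0 >= len(seq_chars):
        raise ValueError("transcript too short for requested site")
    for i in range(1, L + 1):
        pos = t1_idx0 - (i - 1)
        comp = _DNA_COMP[g[i - 1].replace("U", "T")]
        if i in paired:
            seq_chars[pos] = comp
        else:
            choices = [b for b in "ACGT" if b != comp]
            seq_chars[pos] = str(rng.choice(choices))


def gen_transcriptome_with_sites(cfg: SimConfig, pool: PirnaPool,
                                 rng: np.random.Generator | None = None,
                                 ) -> tuple[Transcriptome, TruthTable]:
    """Random transcripts with planted target sites and recorded truth.

    Site construction pairs exactly the guide positions its pattern requires
    and mismatches the rest, so each site satisfies its clause and fails all
    stricter ones.  The recorded tier is the engine-evaluated verdict (a
    g3–g16 construct reports under the lower-floor g3–g15 clause, which is a
    strict subset of its pattern).  Near-miss decoys (one paired base short)
    are planted and recorded with tier ``none``.
    """
    rng = cfg.rng() if rng is None else rng
    n = cfg.n_transcripts
    lens5 = np.maximum(20, rng.normal(cfg.utr5_len, cfg.utr5_len * 0.2, n)).astype(int)
    lensc = np.maximum(150, rng.normal(cfg.cds_len, cfg.cds_len * 0.2, n)).astype(int)
    lens3 = np.maximum(60, rng.normal(cfg.utr3_len, cfg.utr3_len * 0.2, n)).astype(int)
    total = lens5 + lensc + lens3
    seqs = ["".join(DNA[rng.integers(0, 4, L)]) for L in total]
    baseline = cfg.expression_median * np.exp(
        rng.normal(0.0, cfg.expression_sigma_ln, n))
    tx = pd.DataFrame({
        "transcript_id": [f"T{i:04d}" for i in range(n)],
        "sequence": seqs,
        "utr5_len": lens5, "cds_len": lensc, "utr3_len": lens3,
        "baseline_mean": baseline,
    })

    ablated_union = sorted({l for abl in cfg.genotypes.values() for l in abl})
    sp = pool.species
    eligible_abl = sp[(sp["locus"].isin(ablated_union))
                      & (sp["mean_ppm"] >= cfg.min_guide_ppm)]
    eligible_ctl = sp[(~sp["locus"].isin(ablated_union))
                      & (sp["mean_ppm"] >= cfg.min_guide_ppm)]
    n_sites = cfg.n_strong + cfg.n_weak + cfg.n_control_targets + cfg.n_decoys
    if n_sites > n:
        raise ValueError("more planted sites than transcripts")
    if n_sites and (eligible_abl.empty or eligible_ctl.empty):
        raise ValueError("no sufficiently abundant guides to plant sites")

    classes = (["strong"] * cfg.n_strong + ["weak"] * cfg.n_weak
               + ["control"] * cfg.n_control_targets
               + ["decoy"] * cfg.n_decoys)
    site_transcripts = rng.choice(n, size=n_sites, replace=False)

    rows = []
    for k, (tclass, ti) in enumerate(zip(classes, site_transcripts)):
        if tclass == "control":
            guide = eligible_ctl.iloc[int(rng.integers(0, len(eligible_ctl)))]
        else:
            guide = eligible_abl.iloc[int(rng.integers(0, len(eligible_abl)))]
        pattern = _PATTERN_CYCLE[k % len(_PATTERN_CYCLE)]
        gseq = str(guide["sequence"])[:pairing.MAX_GUIDE_SPAN]
        L = len(gseq)
        chars = list(tx.loc[ti, "sequence"])
        if len(chars) < L + 20:
            raise ValueError("transcript too short for requested site")
        t1_idx0 = int(rng.integers(L + 9, len(chars) - 10))
        paired = _paired_positions(pattern, L, rng, decoy=(tclass == "decoy"))
        _write_site(chars, t1_idx0, gseq, paired, rng)
        tx.loc[ti, "sequence"] = "".join(chars)

        window = tx.loc[ti, "sequence"][t1_idx0 - L + 1: t1_idx0 + 1]
        mask = pairing.pair_mask(gseq, window)
        tier = pairing.evaluate_tier(mask, float(guide["mean_ppm"]))
        if tclass == "decoy" and tier != "none":
            raise AssertionError("decoy unexpectedly qualifies")
        if tclass != "decoy" and pattern != "seed_only" and tier == "none":
            raise AssertionError("planted site failed to qualify")

        if tclass == "strong":
            eff = float(rng.uniform(*cfg.strong_efficiency))
            lo, hi = np.log2(cfg.strong_fold_range[0]), np.log2(cfg.strong_fold_range[1])
            fold = float(2.0 ** rng.triangular(lo, 1.0, hi))
        elif tclass == "weak":
            eff = float(rng.uniform(*cfg.weak_efficiency))
            fold = cfg.weak_fold
        elif tclass == "control":
            eff = float(rng.uniform(*cfg.strong_efficiency)) if k % 2 else \
                float(rng.uniform(*cfg.weak_efficiency))
            fold = 1.0
        else:  # decoy: not a target at all
            eff, fold = 0.0, 1.0
        rows.append({
            "pirna_id": guide["pirna_id"], "transcript_id": tx.loc[ti, "transcript_id"],
            "t1_position": t1_idx0 + 1, "requested_pattern": pattern,
            "tier": tier, "seed_match": bool(mask[1:8].all()),
            "predicted_cleavage": t1_idx0 + 1 - 9,
            "cleavage_efficiency": eff, "derepression_fold": fold,
            "target_class": tclass, "is_decoy": tclass == "decoy",
            "locus": guide["locus"],
        })
    sites = pd.DataFrame(rows, columns=[
        "pirna_id", "transcript_id", "t1_position", "requested_pattern",
        "tier", "seed_match", "predicted_cleavage", "cleavage_efficiency",
        "derepression_fold", "target_class", "is_decoy", "locus"])
    truth = TruthTable(sites=sites, ablated_loci=dict(cfg.genotypes))
    transcriptome = Transcriptome(transcripts=tx)
    return transcriptome, truth


# ---------------------------------------------------------------------------
# small RNA reads
# ---------------------------------------------------------------------------

def default_spike_mix(n_oligos: int = 9, molecules: float = 1e6,
                      seed: int = 7) -> pd.DataFrame:
    """Equimolar synthetic spike-in oligos (25-40 nt)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_oligos):
        L = int(rng.integers(25, 41))
        rows.append({"spike_id": f"spike_{i + 1}",
                     "sequence": "".join(DNA[rng.integers(0, 4, L)]),
                     "molecules": molecules})
    return pd.DataFrame(rows)


def _random_kmers(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    if n == 0:
        return np.array([], dtype=object)
    arr = DNA[rng.integers(0, 4, (n, k))]
    return np.array(["".join(row) for row in arr], dtype=object)


def gen_smallrna_reads(pool: PirnaPool, spike_mix: pd.DataFrame, depth: int,
                       cfg: SimConfig, rng: np.random.Generator | None = None,
                       *, ppm_column: str | None = None) -> list[str]:
    """Raw small-RNA reads: UMI5(9) + insert + UMI3(9) + constant adapter.

    Species are sampled proportionally to their ppm (``ppm_column`` of the
    pool's replicate matrix, or the species mean), inserts are
    3'-heterogeneous (random trim of the representative sequence back to the
    25-nt prefix), spike-in reads occupy ``cfg.spike_fraction`` of the
    library proportionally to the molar mix, and ``cfg.duplicate_fraction``
    of the final reads are exact PCR duplicates.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = cfg.rng() if rng is None else rng
    if ppm_column is not None:
        weights = pool.ppm[ppm_column].to_numpy(float)
    else:
        weights = pool.species["mean_ppm"].to_numpy(float)
    n_unique = int(round(depth * (1.0 - cfg.duplicate_fraction)))

    spike_w = spike_mix["molecules"].to_numpy(float)
    p = np.concatenate([
        weights / weights.sum() * (1.0 - cfg.spike_fraction),
        spike_w / spike_w.sum() * cfg.spike_fraction])
    counts = rng.multinomial(n_unique, p / p.sum())

    seqs = list(pool.species["sequence"]) + list(spike_mix["sequence"])
    is_spike = [False] * len(pool.species) + [True] * len(spike_mix)
    inserts = np.empty(n_unique, dtype=object)
    pos = 0
    for seq, c, spike in zip(seqs, counts, is_spike):
        if c == 0:
            continue
        if spike:
            inserts[pos:pos + c] = seq
        else:
            trims = rng.integers(0, len(seq) - 25 + 1, c)
            uniq, inv = np.unique(trims, return_inverse=True)
            variants = np.array([seq[:len(seq) - t] for t in uniq], dtype=object)
            inserts[pos:pos + c] = variants[inv]
        pos += c
    umi5 = _random_kmers(rng, n_unique, 9)
    umi3 = _random_kmers(rng, n_unique, 9)
    reads = np.array([u5 + ins + u3 + cfg.adapter
                      for u5, ins, u3 in zip(umi5, inserts, umi3)], dtype=object)
    n_dup = depth - n_unique
    if n_dup > 0:
        reads = np.concatenate([reads, rng.choice(reads, n_dup, replace=True)])
    rng.shuffle(reads)
    return reads.tolist()


# ---------------------------------------------------------------------------
# degradome
# ---------------------------------------------------------------------------

def gen_degradome(truth: TruthTable, pool: PirnaPool,
                  transcriptome: Transcriptome, cfg: SimConfig,
                  rng: np.random.Generator | None = None,
                  ) -> tuple[pd.DataFrame, dict[tuple[str, str], int]]:
    """5'-monophosphate 5'-end count tables per replicate per genotype.

    Planted signal lands at the predicted cleavage coordinate with Poisson
    mean ``efficiency x target TPM x capture x depth/1e6`` (reduced by the
    ablation factor in genotypes lacking the guide's locus, and scaled by the
    target's derepression there), on top of a uniform sparse background.
    Returns a long table (genotype, replicate, transcript_id, position,
    count) and the nominal library size of each (genotype, replicate).
    """
    rng = cfg.rng() if rng is None else rng
    tpm = transcriptome.tpm()
    lengths = transcriptome.lengths()
    total_pos = int(lengths.sum())
    bg_per_pos = cfg.degradome_depth * cfg.degradome_background_fraction / total_pos

    tids = lengths.index.to_numpy()
    tx_lens = lengths.to_numpy()
    offsets = np.concatenate([[0], np.cumsum(tx_lens)])
    planted = truth.planted()

    records = []
    lib_sizes: dict[tuple[str, str], int] = {}
    for genotype, n_rep in cfg.degradome_replicates.items():
        ablated = set(cfg.genotypes[genotype])
        for r in range(1, n_rep + 1):
            rep = f"{genotype}_{r}"
            lib_sizes[(genotype, rep)] = cfg.degradome_depth
            # background: sparse uniform 5' ends across every position
            n_bg = rng.poisson(bg_per_pos * total_pos)
            flat = rng.integers(0, total_pos, n_bg)
            tx_idx = np.searchsorted(offsets, flat, side="right") - 1
            pos_in_tx = flat - offsets[tx_idx] + 1  # 1-based
            bg = pd.DataFrame({"transcript_id": tids[tx_idx],
                               "position": pos_in_tx})
            bg = bg.groupby(["transcript_id", "position"]).size().rename(
                "count").reset_index()
            bg["genotype"] = genotype
            bg["replicate"] = rep
            records.append(bg)
            # planted cleavage products
            for _, s in planted.iterrows():
                if s["cleavage_efficiency"] <= 0:
                    continue
                lam = (s["cleavage_efficiency"] * tpm[s["transcript_id"]]
                       * cfg.degradome_capture * cfg.degradome_depth / 1e6)
                if s["locus"] in ablated:
                    lam = lam / cfg.ablation_factor * s["derepression_fold"]
                c = int(rng.poisson(lam))
                if c > 0:
                    records.append(pd.DataFrame({
                        "transcript_id": [s["transcript_id"]],
                        "position": [s["predicted_cleavage"]],
                        "count": [c], "genotype": [genotype],
                        "replicate": [rep]}))
    if records:
        df = pd.concat(records, ignore_index=True)
        df = df.groupby(["genotype", "replicate", "transcript_id", "position"],
                        as_index=False)["count"].sum()
    else:
        df = pd.DataFrame(columns=["genotype", "replicate", "transcript_id",
                                   "position", "count"])
    return df, lib_sizes


# ---------------------------------------------------------------------------
# count matrices (RNA-seq, ribosome footprints, GRO-seq)
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float
             ) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def gen_count_matrices(truth: TruthTable, transcriptome: Transcriptome,
                       cfg: SimConfig, rng: np.random.Generator | None = None,
                       ) -> dict:
    """NB-distributed RNA-seq / RFP counts and GRO-seq coverage.

    Targets of ablated-locus guides are multiplied by their derepression
    fold in both mutant alleles; ribosome footprints track mRNA abundance so
    translational efficiency is unchanged by design (a null model for the
    translation tests); GRO-seq coverage is flat across each gene except a
    pause bump confined to the first 500 bp.
    """
    rng = cfg.rng() if rng is None else rng
    tx = transcriptome.transcripts.set_index("transcript_id")
    base = tx["baseline_mean"]

    fold = pd.Series(1.0, index=base.index)
    for _, s in truth.planted().iterrows():
        mutant_abl = {l for g, abl in cfg.genotypes.items() if abl for l in abl}
        if s["locus"] in mutant_abl:
            fold[s["transcript_id"]] *= s["derepression_fold"]

    samples = []
    for grp in ("control", "em1", "em2"):
        for r in range(1, cfg.rna_replicates + 1):
            samples.append((f"rna_{grp}_{r}", "rna", grp, r))
    for grp in ("control", "em1", "em2"):
        for r in range(1, cfg.rfp_replicates + 1):
            samples.append((f"rfp_{grp}_{r}", "rfp", grp, r))

    counts = {}
    for name, assay, grp, _ in samples:
        mean = base.to_numpy(float).copy()
        if grp != "control":
            mean = mean * fold.to_numpy(float)
        if assay == "rfp":
            mean = mean * 0.8  # footprint libraries run a little shallower
        counts[name] = _nb_draw(rng, mean, cfg.nb_dispersion)
    count_df = pd.DataFrame(counts, index=base.index)
    sheet = pd.DataFrame(samples, columns=["sample", "assay", "group",
                                           "replicate"])
    sheet["genotype"] = np.where(sheet["group"] == "control", "control",
                                 "pi9pi17")
    sheet["allele"] = sheet["group"].where(sheet["group"] != "control",
                                           "control")

    # GRO-seq: flat nascent coverage per gene plus a promoter-proximal bump
    gro_tracks = {}
    gro_depths = {}
    lengths = tx["sequence"].str.len()
    for r in range(1, cfg.gro_replicates + 1):
        rows = []
        for tid in base.index:
            L = int(lengths[tid])
            body = max(base[tid] * cfg.gro_scale, 0.01)
            pause = body * cfg.gro_pause_factor
            noise = float(np.exp(rng.normal(0, 0.05)))
            cut = min(500, L)
            rows.append((tid, 0, cut, pause * noise))
            if L > cut:
                rows.append((tid, cut, L, body * noise))
        track = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        depth = float((track["value"] * (track["end"] - track["start"])).sum())
        gro_tracks[f"gro_{r}"] = track
        gro_depths[f"gro_{r}"] = depth
    gene_models = pd.DataFrame({
        "gene_id": base.index, "chrom": base.index,
        "start": 0, "end": lengths.values, "strand": "+",
        "tss": 0})
    return {"counts": count_df, "samples": sheet, "gro_tracks": gro_tracks,
            "gro_depths": gro_depths, "gene_models": gene_models,
            "lengths": lengths}


# ---------------------------------------------------------------------------
# genome annotation tracks
# ---------------------------------------------------------------------------

def gen_genome_annotation(pool: PirnaPool, truth: TruthTable, cfg: SimConfig,
                          rng: np.random.Generator | None = None) -> dict:
    """piRNA origin intervals, a conservation track and a repeat annotation.

    Each locus is laid out on its own contig; piRNA origins are tiled with
    gaps and random strands.  A repeat interval overlaps each origin with the
    class-specific probability (targeted vs untargeted piRNAs), emulating the
    repeat-origin enrichment of target-cleaving piRNAs.
    """
    rng = cfg.rng() if rng is None else rng
    targeted = set(truth.planted()["pirna_id"])
    origin_rows, repeat_rows, cons_rows = [], [], []
    offsets = {locus: 0 for locus in cfg.loci}
    for _, sp in pool.species.iterrows():
        locus = sp["locus"]
        chrom = f"cluster_{locus}"
        L = len(sp["sequence"])
        start = offsets[locus] + int(rng.integers(10, 50))
        end = start + L
        offsets[locus] = end
        strand = "+" if rng.random() < 0.5 else "-"
        origin_rows.append((chrom, start, end, sp["pirna_id"], strand))
        p_rep = (cfg.repeat_prob_targeted if sp["pirna_id"] in targeted
                 else cfg.repeat_prob_untargeted)
        if rng.random() < p_rep:
            # pad < minimum inter-origin gap so a repeat never reaches the
            # neighbouring origin and the planted overlap probabilities hold
            pad = int(rng.integers(0, 9))
            repeat_rows.append((chrom, max(0, start - pad), end + pad))
        scores = rng.normal(0.0, 0.5, L).round(3)
        for i, sc in enumerate(scores):
            cons_rows.append((chrom, start + i, start + i + 1, sc))
    origins = pd.DataFrame(origin_rows, columns=["chrom", "start", "end",
                                                 "pirna_id", "strand"])
    repeats = pd.DataFrame(repeat_rows, columns=["chrom", "start", "end"])
    conservation = pd.DataFrame(cons_rows, columns=["chrom", "start", "end",
                                                    "value"])
    return {"origins": origins, "repeats": repeats,
            "conservation": conservation}


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def gen_kinetic_timecourse(k2: float, k3: float, e_rel: float, times,
                           noise_sd: float = 0.0,
                           seed: int | np.random.Generator = 0):
    """Burst-model time course with Gaussian noise, truncated at zero."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    times = np.asarray(times, dtype=float)
    p = burst_model(times, k2, k3, e_rel)
    if noise_sd > 0:
        p = np.maximum(p + rng.normal(0, noise_sd, len(times)), 0.0)
    from .kinetics import KineticTimeCourse
    return KineticTimeCourse(times=times, p_rel=p)


# ---------------------------------------------------------------------------
# one-call study bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    cfg: SimConfig
    pool: PirnaPool
    transcriptome: Transcriptome
    truth: TruthTable
    spike_mix: pd.DataFrame
    degradome: pd.DataFrame
    degradome_lib_sizes: dict
    expression: dict
    annotation: dict


def simulate_all(cfg: SimConfig) -> SimulatedStudy:
    """Generate every pipeline input (reads excluded; see gen_smallrna_reads)."""
    rng = cfg.rng()
    pool = gen_pirna_pool(cfg, rng)
    transcriptome, truth = gen_transcriptome_with_sites(cfg, pool, rng)
    spike_mix = default_spike_mix()
    degradome, lib_sizes = gen_degradome(truth, pool, transcriptome, cfg, rng)
    expression = gen_count_matrices(truth, transcriptome, cfg, rng)
    annotation = gen_genome_annotation(pool, truth, cfg, rng)
    return SimulatedStudy(cfg=cfg, pool=pool, transcriptome=transcriptome,
                          truth=truth, spike_mix=spike_mix,
                          degradome=degradome, degradome_lib_sizes=lib_sizes,
                          expression=expression, annotation=annotation)
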