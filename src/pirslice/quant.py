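"""Small RNA-seq processing and absolute quantification of piRNA species.

Reads carry nine random nucleotides (UMIs) at both insert ends: the 5'
adapter contributes a 9-nt UMI before the insert and the 3' adapter begins
with a 9-nt UMI followed by its constant sequence (TGGAATTCTCGGGTGCCAAGG).
After adapter removal and PCR-duplicate elimination, inserts are grouped by
their 5' 25-nt prefix — piRNA 3' trimming leaves heterogeneous 3' ends, so a
prefix group is the operational definition of one piRNA species.

Abundance is expressed in ppm of the deduplicated library and converted to
absolute scale either via spike-in oligos of known molar amount or via a
total-piRNAs-per-cell constant (default 1e7).  With the median primary
spermatocyte volume of 1,800 um^3, one molecule per cell is ~0.92 pM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
UMI_LEN = 9
MIN_INSERT, MAX_INSERT = 14, 54
PREFIX_LEN = 25

AVOGADRO = 6.02214076e23
DEFAULT_CELL_VOLUME_UM3 = 1800.0
DEFAULT_PIRNAS_PER_CELL = 1e7
DEFAULT_TRANSCRIPTS_PER_CELL = 3.4e6

__all__ = [
    "DEFAULT_ADAPTER", "SpikeCalibration", "trim_and_dedup",
    "group_by_prefix", "filter_expressed", "classify_ablated",
    "fit_spike_calibration", "absolute_quantify", "poisson_detectability",
    "picomolar_per_molecule", "molecules_from_ppm", "molecules_from_tpm",
]


def picomolar_per_molecule(cell_volume_um3: float = DEFAULT_CELL_VOLUME_UM3) -> float:
    """Concentration (pM) of a single molecule in one cell.

    1 um^3 = 1e-15 L, so at 1,800 um^3 one molecule is ~0.92 pM (reported as
    "around 1 pM").
    """
    litres = cell_volume_um3 * 1e-15
    return 1.0 / (litres * AVOGADRO) / 1e-12


def molecules_from_ppm(ppm, total_per_cell: float = DEFAULT_PIRNAS_PER_CELL):
    """ppm of the small-RNA library -> molecules per cell (1 ppm of 1e7 = 10)."""
    return np.asarray(ppm, dtype=float) * total_per_cell / 1e6


def molecules_from_tpm(tpm, total_transcripts_per_cell: float = DEFAULT_TRANSCRIPTS_PER_CELL):
    """TPM -> transcript molecules per cell (3 TPM of 3.4e6 ~ 10 molecules)."""
    return np.asarray(tpm, dtype=float) * total_transcripts_per_cell / 1e6


def poisson_detectability(mean_molecules: float, dispersion: float | None = None) -> float:
    """Fraction of cells containing at least one molecule.

    Poisson branch: 1 - exp(-mean).  With a negative-binomial ``dispersion``
    alpha (var = mu + alpha mu^2): 1 - (1 + alpha mu)^(-1/alpha).
    """
    if mean_molecules < 0:
        raise ValueError("mean must be nonnegative")
    if dispersion is None or dispersion == 0:
        return 1.0 - float(np.exp(-mean_molecules))
    return 1.0 - float((1.0 + dispersion * mean_molecules) ** (-1.0 / dispersion))


def _find_adapter(read: str, adapter: str, min_anchor: int = 8,
                  max_mismatch: int = 1) -> int:
    """Position of the adapter's first base in ``read``, or -1.

    The adapter is located by an anchored prefix match: at least
    ``min_anchor`` nt of the adapter (or all remaining read, if shorter) with
    at most ``max_mismatch`` mismatches.  Exact occurrences are preferred.
    """
    k = read.find(adapter)
    if k >= 0:
        return k
    n, m = len(read), len(adapter)
    for i in range(0, n - min_anchor + 1):
        span = min(m, n - i)
        if span < min_anchor:
            break
        mm = 0
        for j in range(span):
            if read[i + j] != adapter[j]:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return i
    return -1


def trim_and_dedup(reads, adapter: str = DEFAULT_ADAPTER, *,
                   min_insert: int = MIN_INSERT, max_insert: int = MAX_INSERT,
                   ) -> tuple[pd.DataFrame, dict]:
    """Adapter-trim, UMI-strip and PCR-deduplicate raw reads.

    ``reads`` is an iterable of read sequences (5'UMI + insert + 3'UMI +
    constant adapter).  Returns one record per distinct (UMI5, insert, UMI3)
    tuple with inserts inside [min_insert, max_insert], plus a tally of
    dropped reads.
    """
    kept: dict[tuple[str, str, str], int] = {}
    log = {"total": 0, "no_adapter": 0, "bad_length": 0, "duplicates": 0}
    for read in reads:
        read = str(read).upper()
        log["total"] += 1
        k = _find_adapter(read, adapter)
        if k < 0 or k < 2 * UMI_LEN:
            log["no_adapter"] += 1
            continue
        umi5 = read[:UMI_LEN]
        umi3 = read[k - UMI_LEN:k]
        insert = read[UMI_LEN:k - UMI_LEN]
        if not (min_insert <= len(insert) <= max_insert):
            log["bad_length"] += 1
            continue
        key = (umi5, insert, umi3)
        if key in kept:
            log["duplicates"] += 1
        else:
            kept[key] = 1
    df = pd.DataFrame(
        [(u5, ins, u3) for (u5, ins, u3) in kept],
        columns=["umi5", "insert", "umi3"])
    return df, log


def group_by_prefix(inserts: pd.DataFrame | pd.Series, *,
                    prefix_len: int = PREFIX_LEN,
                    spike_sequences: set[str] | None = None,
                    ) -> tuple[pd.DataFrame, dict]:
    """Group deduplicated inserts by their 5' 25-nt prefix.

    Inserts shorter than the prefix are excluded (and logged); inserts whose
    full sequence is a known spike-in are tallied separately and excluded
    from the piRNA library.  Group ppm = group count / total grouped reads *
    1e6, so group ppm sums to 1e6.
    """
    seqs = inserts["insert"] if isinstance(inserts, pd.DataFrame) else inserts
    seqs = seqs.astype(str)
    spike_sequences = spike_sequences or set()
    is_spike = seqs.isin(spike_sequences)
    spike_counts = seqs[is_spike].value_counts()
    seqs = seqs[~is_spike]
    long_enough = seqs.str.len() >= prefix_len
    log = {"short": int((~long_enough).sum()),
           "spike_reads": int(is_spike.sum()),
           "grouped": int(long_enough.sum())}
    prefixes = seqs[long_enough].str.slice(0, prefix_len)
    counts = prefixes.value_counts()
    total = counts.sum()
    groups = pd.DataFrame({
        "prefix": counts.index,
        "count": counts.values,
        "ppm": counts.values / total * 1e6 if total else 0.0,
    })
    log["spike_counts"] = spike_counts.to_dict()
    return groups, log


def filter_expressed(ppm: pd.DataFrame, control_replicates: list[str], *,
                     min_ppm: float = 1.0) -> pd.DataFrame:
    """Keep species with >= min_ppm in EVERY control replicate (inclusive)."""
    if not control_replicates:
        raise ValueError("need at least one control replicate")
    if ppm.empty:
        return ppm
    keep = (ppm[control_replicates] >= min_ppm).all(axis=1)
    return ppm.loc[keep]


def classify_ablated(ppm: pd.DataFrame, mutant_replicates: list[str], *,
                     max_mean_ppm: float = 0.1) -> pd.Series:
    """True where a species is undetectable in mutants (mean <= 0.1 ppm)."""
    return ppm[mutant_replicates].mean(axis=1) <= max_mean_ppm


@dataclass
class SpikeCalibration:
    """Counts-per-molecule calibration from spike-in oligos.

    ``slope`` is the least-squares counts-vs-molecules slope through the
    origin over detected oligos.
    """
    oligos: pd.DataFrame  # spike_id, sequence, molecules, count
    slope: float = field(init=False)

    def __post_init__(self) -> None:
        det = self.oligos[self.oligos["count"] > 0]
        if len(det) < 2:
            raise ValueError("need >= 2 detected spike-in oligos for a fit")
        m = det["molecules"].to_numpy(float)
        c = det["count"].to_numpy(float)
        self.slope = float((c * m).sum() / (m * m).sum())
        if self.slope <= 0:
            raise ValueError("non-positive spike-in slope")


def fit_spike_calibration(spike_defs: pd.DataFrame,
                          spike_counts: dict[str, int]) -> SpikeCalibration:
    """Join observed deduplicated spike counts onto the oligo definitions."""
    df = spike_defs.copy()
    df["count"] = df["sequence"].map(lambda s: spike_counts.get(s, 0))
    return SpikeCalibration(oligos=df)


def absolute_quantify(pool: pd.DataFrame, *,
                      calibration: SpikeCalibration | None = None,
                      cell_count: float | None = None,
                      cell_volume_um3: float = DEFAULT_CELL_VOLUME_UM3,
                      total_per_cell: float = DEFAULT_PIRNAS_PER_CELL,
                      count_col: str = "count",
                      ppm_col: str = "mean_ppm") -> pd.DataFrame:
    """Attach molecules-per-cell and pM concentration to a species table.

    With a spike-in ``calibration`` and ``cell_count``, molecules per cell =
    deduplicated count / (counts per molecule) / cells.  Otherwise the ppm
    route is used: molecules = ppm * total_per_cell / 1e6.
    """
    out = pool.copy()
    if calibration is not None:
        if cell_count is None or cell_count <= 0:
            raise ValueError("spike-in quantification requires a positive cell_count")
        out["molecules_per_cell"] = (
            out[count_col].astype(float) / calibration.slope / cell_count)
    else:
        out["molecules_per_cell"] = molecules_from_ppm(
            out[ppm_col].to_numpy(float), total_per_cell)
    out["concentration_pM"] = (
        out["molecules_per_cell"] * picomolar_per_molecule(cell_volume_um3))
    return out
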