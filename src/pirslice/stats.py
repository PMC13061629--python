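"""Differential abundance and the distribution-level tests.

The differential test is a negative-binomial Wald test on the log2 ratio of
normalised group means: library sizes come from median-of-ratios
normalisation, gene-wise dispersions are estimated by moments and shrunk
toward a mean-dispersion trend, and p-values are Benjamini-Hochberg
corrected.  Mutant lines exist as two independently derived alleles; a
change is accepted only when significant in both with the same sign, and
the reported fold change is the smaller of the two in magnitude, so every
reported change is the absolute minimum of the two alleles.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .quant import molecules_from_tpm

__all__ = ["size_factors", "tpm", "nb_differential", "intersect_alleles",
           "translational_efficiency", "ks_compare", "mw_compare",
           "bh_adjust", "kruskal_omnibus"]

FDR_THRESHOLD = 0.01
MIN_TPM = 3.0
MIN_RFP_TPM = 10.0


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, the factor is the median over features of
    count / geometric-mean(feature), computed on features expressed in every
    sample.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no feature is nonzero in all samples; "
                         "consider a pseudocount")
    sub = counts.loc[positive].to_numpy(float)
    log_geo = np.mean(np.log(sub), axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geo[:, None], axis=0))
    return pd.Series(factors, index=counts.columns)


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million with effective length = annotated length."""
    rate = counts.div(lengths.reindex(counts.index), axis=0)
    return rate / rate.sum(axis=0) * 1e6


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def _trended_dispersion(mu: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu over genes and return the trend values."""
    ok = (mu > 0) & np.isfinite(alpha_mom)
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, alpha_mom[ok], rcond=None)
    a0, a1 = max(coef[0], 1e-6), max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        return np.where(mu > 0, a0 + a1 / mu, a0)


def nb_differential(counts: pd.DataFrame, design: pd.Series, *,
                    lengths: pd.Series | None = None,
                    min_tpm: float = MIN_TPM,
                    dispersion: float | None = None,
                    total_transcripts_per_cell: float = 3.4e6,
                    ) -> pd.DataFrame:
    """NB Wald test of mutant vs control per feature.

    ``design`` maps sample names to 'control' or 'mutant'.  Features whose
    control abundance is below ``min_tpm`` TPM (~10 molecules per cell at
    3.4e6 transcripts) are excluded before testing.  Gene-wise moment
    dispersions are shrunk 70% toward the fitted mean-dispersion trend
    unless a known ``dispersion`` is supplied.
    """
    groups = design.reindex(counts.columns)
    ctl = counts.columns[groups == "control"]
    mut = counts.columns[groups == "mutant"]
    if len(ctl) < 2 or len(mut) < 2:
        raise ValueError("need >= 2 replicates per group")
    sf = size_factors(counts)
    norm = counts / sf

    if lengths is None:
        lengths = pd.Series(1.0, index=counts.index)
    ctl_tpm = tpm(counts[ctl], lengths).mean(axis=1)
    keep = ctl_tpm >= min_tpm
    norm = norm.loc[keep]

    x1 = norm[mut].to_numpy(float)
    x0 = norm[ctl].to_numpy(float)
    n1, n0 = x1.shape[1], x0.shape[1]
    mu1, mu0 = x1.mean(axis=1), x0.mean(axis=1)
    mu = norm.mean(axis=1).to_numpy()

    if dispersion is None:
        # pooled within-group moments estimate, then trend shrinkage
        var_within = (x1.var(axis=1, ddof=1) * (n1 - 1)
                      + x0.var(axis=1, ddof=1) * (n0 - 1)) / (n1 + n0 - 2)
        mu_w = (mu1 * n1 + mu0 * n0) / (n1 + n0)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_mom = (var_within - mu_w) / np.maximum(mu_w, 1e-8) ** 2
        alpha_tr = _trended_dispersion(mu, alpha_mom)
        alpha = np.maximum(0.7 * alpha_tr + 0.3 * np.clip(alpha_mom, 0, None),
                           1e-6)
    else:
        alpha = np.full(len(mu), float(dispersion))

    eps = 0.5  # Haldane-style stabiliser for empty groups
    lfc = np.log2((mu1 + eps) / (mu0 + eps))
    var_log1 = 1.0 / np.maximum(mu1, eps) / n1 + alpha / n1
    var_log0 = 1.0 / np.maximum(mu0, eps) / n0 + alpha / n0
    se = np.sqrt(var_log1 + var_log0) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    out = pd.DataFrame({
        "base_mean": mu, "log2fc": lfc, "se": se, "p": p,
        "fdr": bh_adjust(p),
        "tpm_control": ctl_tpm.loc[keep].to_numpy(),
    }, index=norm.index)
    out["molecules_per_cell"] = molecules_from_tpm(
        out["tpm_control"], total_transcripts_per_cell)
    return out


def intersect_alleles(de_em1: pd.DataFrame, de_em2: pd.DataFrame, *,
                      fdr: float = FDR_THRESHOLD) -> pd.DataFrame:
    """Two-allele consensus: both significant, same sign, minimum magnitude.

    All shared features are returned with a consensus ``log2fc`` (the allele
    value of smaller magnitude) and a ``called`` flag.
    """
    common = de_em1.index.intersection(de_em2.index)
    a, b = de_em1.loc[common], de_em2.loc[common]
    same_sign = np.sign(a["log2fc"]) == np.sign(b["log2fc"])
    called = (a["fdr"] < fdr) & (b["fdr"] < fdr) & same_sign
    take_a = a["log2fc"].abs() <= b["log2fc"].abs()
    consensus = np.where(take_a, a["log2fc"], b["log2fc"])
    # when the alleles disagree in sign there is no meaningful consensus size
    consensus = np.where(same_sign, consensus, 0.0)
    out = pd.DataFrame({
        "log2fc": consensus,
        "log2fc_em1": a["log2fc"], "log2fc_em2": b["log2fc"],
        "fdr_em1": a["fdr"], "fdr_em2": b["fdr"],
        "fdr": np.maximum(a["fdr"], b["fdr"]),
        "called": called,
    }, index=common)
    return out


def translational_efficiency(rfp: pd.DataFrame, rna: pd.DataFrame,
                             design: pd.Series, *,
                             lengths: pd.Series | None = None,
                             min_rfp_tpm: float = MIN_RFP_TPM,
                             dispersion: float | None = None,
                             ) -> pd.DataFrame:
    """TE per feature and a differential-TE Wald test (ratio of ratios).

    TE = RFP TPM / RNA TPM.  The change in TE between mutant and control is
    tested as log2(TE_mut / TE_ctl) with the NB delta-method variance summed
    over the four count groups.  Features below ``min_rfp_tpm`` TPM of
    control ribosome occupancy, or without RNA signal, are excluded.
    """
    common = rfp.index.intersection(rna.index)
    rfp, rna = rfp.loc[common], rna.loc[common]
    if lengths is None:
        lengths = pd.Series(1.0, index=common)
    g_rfp = design.reindex(rfp.columns)
    g_rna = design.reindex(rna.columns)
    rfp_tpm = tpm(rfp, lengths)
    rna_tpm = tpm(rna, lengths)
    ctl_rfp_tpm = rfp_tpm.loc[:, g_rfp == "control"].mean(axis=1)
    rna_ok = (rna_tpm.loc[:, g_rna == "control"].mean(axis=1) > 0)
    keep = (ctl_rfp_tpm >= min_rfp_tpm) & rna_ok

    def _group(df, groups, which):
        sf = size_factors(df)
        return (df / sf).loc[keep, df.columns[groups == which]].to_numpy(float)

    arr = {("rfp", w): _group(rfp, g_rfp, w) for w in ("control", "mutant")}
    arr.update({("rna", w): _group(rna, g_rna, w) for w in ("control", "mutant")})

    means = {k: v.mean(axis=1) for k, v in arr.items()}
    te_ctl = means[("rfp", "control")] / np.maximum(means[("rna", "control")], 1e-9)
    te_mut = means[("rfp", "mutant")] / np.maximum(means[("rna", "mutant")], 1e-9)
    lfc = np.log2(np.maximum(te_mut, 1e-12) / np.maximum(te_ctl, 1e-12))

    if dispersion is None:
        dispersion_used = 0.05
        # moments across the four groups, pooled
        alphas = []
        for v in arr.values():
            m = v.mean(axis=1)
            s2 = v.var(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                alphas.append(np.clip((s2 - m) / np.maximum(m, 1e-8) ** 2, 0, None))
        dispersion_used = np.maximum(np.nanmedian(np.vstack(alphas), axis=0), 1e-6)
    else:
        dispersion_used = float(dispersion)
    var = sum((1.0 / np.maximum(means[k], 0.5) + dispersion_used) / arr[k].shape[1]
              for k in arr)
    se = np.sqrt(var) / np.log(2)
    z = lfc / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    return pd.DataFrame({
        "te_control": te_ctl, "te_mutant": te_mut,
        "log2fc_te": lfc, "se": se, "p": p, "fdr": bh_adjust(p),
        "rfp_tpm_control": ctl_rfp_tpm[keep].to_numpy(),
    }, index=common[keep])


def ks_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample, two-tailed Kolmogorov-Smirnov test -> (D, p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 observations")
    res = sps.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def mw_compare(group_a, group_b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U -> (U of group_a, p).

    Exact null distribution for small groups (both n <= 8, no ties), normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("groups must be nonempty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_omnibus(*groups) -> tuple[float, float]:
    """Kruskal-Wallis omnibus test across >= 2 groups -> (H, p)."""
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)
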