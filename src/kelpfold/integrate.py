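"""Compartment x epigenome integration: histone-mark enrichment, expression,
sex-biased-gene classification and their association with compartment
switching.

Group comparisons use the two-sample Wilcoxon rank-sum test (exact
enumeration for small untied samples, otherwise the normal approximation
with tie and continuity corrections); the switching association uses a
plain Pearson chi-square on the 2x2 gene table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .compartments import CompartmentTrack, SwitchTable

SBG_PADJ_MAX = 0.01
SBG_LFC_MIN = 1.0


def assign_to_compartment(features: pd.DataFrame, track: CompartmentTrack) -> pd.DataFrame:
    """Label features (peaks, genes) with the compartment of the bin holding
    their midpoint; features on masked bins are labeled 'masked'."""
    out = features.copy()
    labels = []
    for _, row in out.iterrows():
        mid = int((row["start"] + row["end"]) // 2)
        try:
            labels.append(track.label_at(row["chrom"], mid))
        except (KeyError, ValueError):
            labels.append("masked")
    out["compartment"] = labels
    return out


def rank_sum_test(x: np.ndarray, y: np.ndarray, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p) where W is the
    rank sum of the first sample.

    ``auto`` enumerates the exact permutation null when n1 + n2 <= 12 and
    there are no ties, and otherwise uses the normal approximation with tie
    and continuity corrections.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # fully tied: no evidence either way
        return float(n1 * (n1 + n2 + 1) / 2), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if method == "auto":
        method = "exact" if (n1 + n2 <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    w = float(res.statistic + n1 * (n1 + 1) / 2)  # U -> rank sum of x
    return w, float(res.pvalue)


def _compare_groups(values_a: np.ndarray, values_b: np.ndarray) -> dict:
    if len(values_a) < 3 or len(values_b) < 3:
        raise ValueError(
            f"empty or tiny group (A: {len(values_a)}, B: {len(values_b)}); need >= 3 each"
        )
    w, p = rank_sum_test(values_a, values_b)
    return {
        "A_values": values_a,
        "B_values": values_b,
        "n_A": len(values_a),
        "n_B": len(values_b),
        "W": w,
        "p": p,
        "median_A": float(np.median(values_a)),
        "median_B": float(np.median(values_b)),
    }


def mark_enrichment_by_compartment(peaks: pd.DataFrame, track: CompartmentTrack) -> dict[str, dict]:
    """Per histone mark, compare log2(fold_enrichment) of peaks in compartment
    A versus B (Wilcoxon rank-sum)."""
    labeled = assign_to_compartment(peaks, track)
    out = {}
    for mark, grp in labeled.groupby("mark"):
        a = np.log2(grp.loc[grp["compartment"] == "A", "fold_enrichment"].to_numpy(float))
        b = np.log2(grp.loc[grp["compartment"] == "B", "fold_enrichment"].to_numpy(float))
        out[str(mark)] = _compare_groups(a, b)
    return out


def expression_by_compartment(
    genes: pd.DataFrame, track: CompartmentTrack, tpm_column: str = "TPM"
) -> dict:
    """Compare gene expression, as log2(TPM + 1), between compartments A and B."""
    labeled = assign_to_compartment(genes, track)
    a = np.log2(labeled.loc[labeled["compartment"] == "A", tpm_column].to_numpy(float) + 1)
    b = np.log2(labeled.loc[labeled["compartment"] == "B", tpm_column].to_numpy(float) + 1)
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"empty group {'B' if len(b) == 0 else 'A'}")
    return _compare_groups(a, b)


def classify_sbg(
    genes: pd.DataFrame,
    padj_max: float = SBG_PADJ_MAX,
    lfc_min: float = SBG_LFC_MIN,
) -> pd.DataFrame:
    """Label genes as male-biased (MBG), female-biased (FBG) or unbiased (Unb)
    from differential-expression statistics.

    log2FC is oriented male-high: MBG when padj <= ``padj_max`` and
    log2FC >= ``lfc_min``; FBG with log2FC <= -``lfc_min``; Unb otherwise
    (including missing padj). Every gene receives exactly one label.
    """
    out = genes.copy()
    padj = out["padj"].to_numpy(float)
    lfc = out["log2FC"].to_numpy(float)
    sig = np.isfinite(padj) & (padj <= padj_max)
    label = np.where(sig & (lfc >= lfc_min), "MBG", np.where(sig & (lfc <= -lfc_min), "FBG", "Unb"))
    out["sbg_label"] = label
    return out


def chi2_2x2(table: np.ndarray, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table (df = 1), by default
    without continuity correction. Raises when any expected cell < 1."""
    t = np.asarray(table, float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    if (expected < 1).any():
        raise ValueError("chi-square invalid; use exact test")
    diff = np.abs(t - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0)
    chi2 = float((diff**2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class SbgSwitchResult:
    table: pd.DataFrame  # 2x2: {SBG, non-SBG} x {switching, conserved}
    chi2: float
    p: float


def sbg_switch_enrichment(
    genes: pd.DataFrame, switch: SwitchTable, yates: bool = False
) -> SbgSwitchResult:
    """Test whether sex-biased genes concentrate in compartment-switching
    regions (2x2 chi-square over genes, switching status by gene midpoint)."""
    if "sbg_label" not in genes.columns:
        raise ValueError("genes must carry sbg_label; run classify_sbg first")
    counts = np.zeros((2, 2))
    for _, row in genes.iterrows():
        mid = int((row["start"] + row["end"]) // 2)
        sw = switch.is_switching_at(row["chrom"], mid)
        if sw is None:
            continue
        i = 0 if row["sbg_label"] in ("MBG", "FBG") else 1
        j = 0 if sw else 1
        counts[i, j] += 1
    chi2, p = chi2_2x2(counts, yates=yates)
    table = pd.DataFrame(
        counts,
        index=["SBG", "non-SBG"],
        columns=["switching", "conserved"],
    )
    return SbgSwitchResult(table=table, chi2=chi2, p=p)
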