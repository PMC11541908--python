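"""Aggregate Chromosomal Analysis (ACA) and chromosome-scale clustering scores.

Each chromosome is linearly rescaled so that its centromere sits at the
center of a fixed pseudo-length: the p arm maps onto the left half and the q
arm onto the right half, by area-weighted averaging of the O/E cells (a flat
map therefore stays exactly flat). Averaging the rescaled maps across
chromosomes (intra) or chromosome pairs (inter) exposes centromere-centromere
and telomere-telomere clustering, and a Rabl configuration shows up as an
enriched band along the equal-relative-arm-position diagonal of the inter
aggregate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ContactMatrix, observed_over_expected


@dataclass
class AggregateMap:
    """Mean O/E over chromosomes rescaled to a common pseudo-length."""

    values: np.ndarray  # n_pseudo x n_pseudo, NaN where undefined
    kind: str  # 'intra' | 'inter'
    n_averaged: int  # chromosomes (intra) or ordered pairs (inter)
    n_pseudo: int

    @property
    def centromere_index(self) -> int:
        return self.n_pseudo // 2


@dataclass
class ClusterScores:
    """Enrichment of the inter-chromosome aggregate over its background."""

    cc_score: float  # centromere-centromere (center window)
    tt_score: float  # telomere-telomere (corner windows)
    arm_alignment_score: float  # equal-relative-position diagonal band
    configuration_call: str | None = None


def _rescale_operator(nb: int, bin_size: int, chrom_len: int, cen_bp: float, n_pseudo: int) -> np.ndarray:
    """Row-stochastic (n_pseudo x nb) operator: area-weighted mean of source
    bins per pseudo-bin, p arm -> left half, q arm -> right half."""
    half = n_pseudo // 2
    rows = np.zeros((n_pseudo, nb))
    starts = np.arange(nb) * bin_size
    ends = np.minimum(starts + bin_size, chrom_len)
    for arm, (lo, hi, row0) in enumerate(
        [(0.0, cen_bp, 0), (cen_bp, float(chrom_len), half)]
    ):
        width = (hi - lo) / half
        for k in range(half):
            plo, phi = lo + k * width, lo + (k + 1) * width
            ov = np.minimum(ends, phi) - np.maximum(starts, plo)
            ov = np.clip(ov, 0, None).astype(float)
            if ov.sum() > 0:
                rows[row0 + k] = ov / ov.sum()
    return rows


def _rescale_block(r1: np.ndarray, block: np.ndarray, r2: np.ndarray) -> np.ndarray:
    finite = np.isfinite(block)
    num = r1 @ np.where(finite, block, 0.0) @ r2.T
    den = r1 @ finite.astype(float) @ r2.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def aca(
    m: ContactMatrix,
    centromeres: dict[str, float],
    n_pseudo: int = 100,
    oe: np.ndarray | None = None,
) -> tuple[AggregateMap, AggregateMap]:
    """Centromere-centered aggregate of intra- and inter-chromosomal O/E.

    ``centromeres`` maps each chromosome to its centromere midpoint in bp
    (strictly inside the chromosome). Chromosomes with an arm shorter than 2
    bins are excluded with a warning. ``n_pseudo`` must be even.
    """
    if n_pseudo % 2:
        raise ValueError("n_pseudo must be even")
    if oe is None:
        oe = observed_over_expected(m)
    g = m.genome
    ops: dict[str, np.ndarray] = {}
    for name in g.names:
        if name not in centromeres:
            continue
        cen = float(centromeres[name])
        length = g.lengths[name]
        if not (0 < cen < length):
            raise ValueError(f"centromere of {name} not strictly inside chromosome")
        nb = g.chrom_nbins(name)
        if min(cen, length - cen) < 2 * g.bin_size:
            warnings.warn(f"chromosome {name}: arm shorter than 2 bins, excluded from ACA")
            continue
        ops[name] = _rescale_operator(nb, g.bin_size, length, cen, n_pseudo)
    if not ops:
        raise ValueError("no chromosome usable for ACA")
    names = list(ops)
    intra_stack = [
        _rescale_block(ops[n], oe[g.chrom_slice(n), g.chrom_slice(n)], ops[n]) for n in names
    ]
    inter_stack = []
    for a in names:
        for b in names:
            if a == b:
                continue
            inter_stack.append(
                _rescale_block(ops[a], oe[g.chrom_slice(a), g.chrom_slice(b)], ops[b])
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        intra = np.nanmean(np.stack(intra_stack), axis=0)
        inter = (
            np.nanmean(np.stack(inter_stack), axis=0)
            if inter_stack
            else np.full((n_pseudo, n_pseudo), np.nan)
        )
    return (
        AggregateMap(intra, "intra", len(names), n_pseudo),
        AggregateMap(inter, "inter", len(inter_stack), n_pseudo),
    )


def _window_masks(n: int, w: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c = n // 2
    lo, hi = c - w // 2, c - w // 2 + w
    center = np.zeros((n, n), bool)
    center[lo:hi, lo:hi] = True
    corners = np.zeros((n, n), bool)
    for rs in (slice(0, w), slice(n - w, n)):
        for cs in (slice(0, w), slice(n - w, n)):
            corners[rs, cs] = True
    i, j = np.indices((n, n))
    diag = np.abs(i - j) <= w // 2
    return center, corners, diag


def cluster_scores(inter: AggregateMap, window: int = 5) -> ClusterScores:
    """Centromere (C-C), telomere (T-T) and arm-alignment enrichment scores.

    Each score is the mean O/E of its window divided by the background mean,
    the background being the aggregate with the centromere and telomere
    windows excluded.
    """
    a = inter.values
    n = inter.n_pseudo
    center, corners, diag = _window_masks(n, window)
    finite = np.isfinite(a)
    bg_mask = finite & ~center & ~corners
    if not bg_mask.any():
        raise ValueError("no background cells in aggregate")
    bg = float(a[bg_mask].mean())

    def _mean(mask: np.ndarray) -> float:
        mm = mask & finite
        return float(a[mm].mean()) if mm.any() else np.nan

    return ClusterScores(
        cc_score=_mean(center) / bg,
        tt_score=_mean(corners) / bg,
        arm_alignment_score=_mean(diag & ~center & ~corners) / bg,
    )


def classify_configuration(
    s: ClusterScores, tau_c: float = 1.5, tau_r: float = 1.5
) -> str:
    """Call the interphase configuration from the clustering scores.

    Rabl-like when the arm-alignment band is enriched; clustered-non-Rabl
    when centromeres and telomeres cluster without arm alignment; dispersed
    otherwise.
    """
    if s.arm_alignment_score >= tau_r:
        return "Rabl-like"
    if s.cc_score >= tau_c and s.tt_score >= tau_c:
        return "clustered-non-Rabl"
    return "dispersed"


def trans_enrichment_by_pair(m: ContactMatrix, oe: np.ndarray | None = None) -> pd.DataFrame:
    """Mean log2 trans O/E for every chromosome pair (symmetric table, NaN diagonal)."""
    if oe is None:
        oe = observed_over_expected(m)
    names = m.genome.names
    table = pd.DataFrame(np.nan, index=names, columns=names)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            blk = oe[m.genome.chrom_slice(names[a]), m.genome.chrom_slice(names[b])]
            ok = np.isfinite(blk) & (blk > 0)
            if ok.any():
                v = float(np.log2(blk[ok]).mean())
                table.iloc[a, b] = table.iloc[b, a] = v
    return table


def default_telomere_bins(m: ContactMatrix, n_terminal: int = 2) -> np.ndarray:
    """Global indices of the terminal bins of every chromosome end."""
    out = []
    for name in m.genome.names:
        s = m.genome.chrom_slice(name)
        k = min(n_terminal, (s.stop - s.start) // 2)
        out.extend(range(s.start, s.start + k))
        out.extend(range(s.stop - k, s.stop))
    return np.unique(out)


def region_to_telomere_contact(
    m: ContactMatrix,
    query_region: tuple[str, int, int],
    telomere_bins: np.ndarray | None = None,
    control_regions: list[tuple[str, int, int]] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    oe: np.ndarray | None = None,
) -> tuple[float, float]:
    """Test whether a region contacts telomeres of other chromosomes more than
    matched controls do.

    The score is the mean trans O/E between the query bins and telomere bins
    on other chromosomes. Controls are either supplied regions of matched
    length (e.g. other H3K79me2-covered domains) or, if absent, ``n_perm``
    random placements of matched bin-length. The empirical p-value uses the
    add-one rule, ``(1 + #{control >= score}) / (1 + n_controls)``, so it is
    never zero.
    """
    g = m.genome
    if oe is None:
        oe = observed_over_expected(m)
    if telomere_bins is None:
        telomere_bins = default_telomere_bins(m)
    telomere_bins = np.asarray(telomere_bins)
    chroms = g.bin_chroms()

    def _score(region: tuple[str, int, int]) -> float:
        chrom, start, end = region
        s = g.chrom_slice(chrom)
        b0 = s.start + start // g.bin_size
        b1 = s.start + -(-end // g.bin_size)
        qbins = np.arange(b0, min(b1, s.stop))
        tel = telomere_bins[chroms[telomere_bins] != chrom]
        if tel.size == 0:
            raise ValueError("no trans telomere bins available")
        blk = oe[np.ix_(qbins, tel)]
        ok = np.isfinite(blk)
        return float(blk[ok].mean()) if ok.any() else np.nan

    score = _score(query_region)
    rng = np.random.default_rng(seed)
    if control_regions is None:
        chrom_q, start_q, end_q = query_region
        width = end_q - start_q
        usable = [n for n, l in g.chromosomes if l > width]
        control_regions = []
        for _ in range(n_perm):
            name = usable[rng.integers(len(usable))]
            start = int(rng.integers(0, g.lengths[name] - width))
            control_regions.append((name, start, start + width))
    control_scores = np.array([_score(r) for r in control_regions])
    control_scores = control_scores[np.isfinite(control_scores)]
    k = int((control_scores >= score).sum())
    p = (1 + k) / (1 + control_scores.size)
    return score, p
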