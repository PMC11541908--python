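"""Contact probability versus genomic distance and Interaction Decay Exponents.

P(s) is the mean balanced contact over unmasked bin pairs whose separation
falls in a log-spaced distance band; the IDE is the ordinary-least-squares
slope of log10 P against log10 s over a stated fit range, reported signed
(negative for decaying contact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix import ContactMatrix


@dataclass
class DecayFit:
    """Fitted power-law decay of contact frequency with distance."""

    distances: np.ndarray  # band centers, bp
    ps: np.ndarray
    exponent: float  # IDE: slope of log10 P(s) vs log10 s
    intercept: float
    r2: float
    fit_range: tuple[float, float]  # (s_min, s_max) bp
    n_bands: int


def contact_probability_curve(
    m: ContactMatrix,
    chrom: str,
    start: int | None = None,
    end: int | None = None,
    log_bins_per_decade: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """P(s) curve for one chromosome (or a sub-region of it).

    Returns geometric band centers (bp) and the mean balanced contact per
    band; bands with no unmasked pair are dropped.
    """
    bs = m.genome.bin_size
    sl = m.genome.chrom_slice(chrom)
    lo = sl.start + (0 if start is None else start // bs)
    hi = sl.start + (sl.stop - sl.start if end is None else -(-end // bs))
    if hi - lo < 3:
        raise ValueError("region has fewer than 3 bins")
    bal = m.balanced()[lo:hi, lo:hi]
    valid = m.valid[lo:hi]
    if valid.sum() < 3:
        raise ValueError("region has fewer than 3 unmasked bins")
    nb = hi - lo
    max_s = (nb - 1) * bs
    edges = [bs]
    while edges[-1] < max_s:
        edges.append(edges[-1] * 10 ** (1.0 / log_bins_per_decade))
    edges = np.array(edges)
    if len(edges) < 2:
        raise ValueError("region smaller than one distance band")
    centers, ps = [], []
    # distance of bin pair (i, j) taken as |i-j| * bin_size
    i, j = np.triu_indices(nb, k=1)
    s = (j - i) * bs
    vals = bal[i, j]
    ok = ~np.isnan(vals)
    for lo_e, hi_e in zip(edges[:-1], edges[1:]):
        band = ok & (s >= lo_e) & (s < hi_e)
        if band.sum() == 0:
            continue
        centers.append(s[band].mean())  # mean pair distance, not edge midpoint
        ps.append(vals[band].mean())
    return np.array(centers), np.array(ps)


def fit_ide(
    curve: tuple[np.ndarray, np.ndarray],
    s_min: float = 10_000,
    s_max: float = 500_000,
) -> DecayFit:
    """Fit the interaction decay exponent over ``[s_min, s_max]`` by OLS in
    log-log space. Zero-valued bands are dropped, not imputed."""
    distances, ps = np.asarray(curve[0], float), np.asarray(curve[1], float)
    if s_min >= s_max:
        raise ValueError("s_min must be < s_max")
    use = (distances >= s_min) & (distances <= s_max) & (ps > 0)
    if use.sum() < 3:
        raise ValueError(
            f"fewer than 3 usable bands with P(s) > 0 in [{s_min}, {s_max}]"
        )
    x, y = np.log10(distances[use]), np.log10(ps[use])
    res = stats.linregress(x, y)
    return DecayFit(
        distances=distances[use],
        ps=ps[use],
        exponent=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        fit_range=(s_min, s_max),
        n_bands=int(use.sum()),
    )
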