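"""Contact-map core: binning read pairs, masking, iterative correction (ICE),
distance-expected profiles, observed/expected and correlation maps.

Counts are stored dense and symmetric (suitable below ~5000 bins, the regime
this package targets); balancing weights are divisors, so the balanced value
of a cell is ``counts[i, j] / (w[i] * w[j])``. Weights are scaled to a unit
mean balanced marginal over unmasked bins, which makes O/E scale-free.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import scipy.sparse as sp

from .genome import GenomeSpec

log = logging.getLogger(__name__)

DENSE_LIMIT = 5000


@dataclass
class ContactMatrix:
    """Symmetric binned Hi-C counts with balancing weights and a bin mask.

    ``masked[i]`` True means bin *i* is excluded from every downstream
    statistic; its weight is NaN (undefined).
    """

    genome: GenomeSpec
    counts: np.ndarray
    weights: np.ndarray | None = None
    masked: np.ndarray | None = None

    def __post_init__(self) -> None:
        if sp.issparse(self.counts):
            if self.genome.n_bins > DENSE_LIMIT:
                raise ValueError(f"dense conversion above {DENSE_LIMIT} bins not supported")
            self.counts = np.asarray(self.counts.todense(), dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.genome.n_bins
        if self.counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if self.masked is None:
            self.masked = np.zeros(n, dtype=bool)
        self.masked = np.asarray(self.masked, dtype=bool)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)

    @property
    def n_bins(self) -> int:
        return self.genome.n_bins

    @property
    def valid(self) -> np.ndarray:
        return ~self.masked

    @property
    def total_count(self) -> float:
        """Number of pairs represented (upper triangle including diagonal)."""
        return float(np.triu(self.counts).sum())

    def marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def balanced(self) -> np.ndarray:
        """Balanced matrix with NaN on masked rows/columns.

        Requires :func:`ice_balance` (or externally supplied weights).
        """
        if self.weights is None:
            raise ValueError("matrix has no balancing weights; run ice_balance first")
        w = np.where(self.masked, np.nan, self.weights)
        return self.counts / np.outer(w, w)


def bin_pairs(
    pairs_stream: Iterable[tuple[str, int, str, int]],
    genome: GenomeSpec,
    strict: bool = False,
) -> ContactMatrix:
    """Bin a stream of contacts ``(chrom1, pos1, chrom2, pos2)`` (1-based bp).

    Each pair increments exactly one unordered bin-pair cell, using the bin
    containing each mate's 5' position. Records naming an unknown chromosome
    or an out-of-range position are dropped and logged (raised when
    ``strict``).
    """
    n = genome.n_bins
    counts = np.zeros((n, n))
    n_bad = 0
    for rec in pairs_stream:
        chrom1, pos1, chrom2, pos2 = rec
        try:
            i = genome.bin_index(chrom1, int(pos1) - 1)
            j = genome.bin_index(chrom2, int(pos2) - 1)
        except (KeyError, ValueError) as exc:
            if strict:
                raise ValueError(f"invalid pair record {rec!r}: {exc}") from exc
            n_bad += 1
            continue
        if i == j:
            counts[i, i] += 1
        else:
            counts[i, j] += 1
            counts[j, i] += 1
    if n_bad:
        log.warning("dropped %d invalid pair records", n_bad)
    return ContactMatrix(genome, counts)


def mask_low_coverage(m: ContactMatrix, min_frac: float = 0.02) -> ContactMatrix:
    """Mask bins whose marginal count falls below ``min_frac`` of the median
    nonzero marginal (all-zero bins are always masked)."""
    marg = m.marginals()
    nonzero = marg[marg > 0]
    if nonzero.size == 0:
        raise ValueError("degenerate matrix: all marginals zero")
    thresh = min_frac * float(np.median(nonzero))
    masked = m.masked | (marg < thresh) | (marg == 0)
    if masked.all():
        raise ValueError("degenerate matrix: all bins masked")
    return replace(m, masked=masked)


def ice_balance(
    m: ContactMatrix, tol: float = 1e-5, max_iter: int = 200
) -> ContactMatrix:
    """Iterative correction: find per-bin weights equalizing balanced marginals.

    Over unmasked bins, the balanced marginals agree to relative tolerance
    ``tol`` and are scaled to unit mean. Raises on non-convergence, reporting
    the last residual.
    """
    v = m.valid
    if v.sum() < 2:
        raise ValueError("need at least 2 unmasked bins to balance")
    sub = m.counts[np.ix_(v, v)]
    if not (sub.sum(axis=0) > 0).all():
        raise ValueError("unmasked bin with zero marginal; apply mask_low_coverage first")
    b = np.ones(int(v.sum()))
    residual = np.inf
    for _ in range(max_iter):
        marg = (sub / np.outer(b, b)).sum(axis=0)
        scale = marg / marg.mean()
        residual = float(np.abs(scale - 1).max())
        if residual < tol:
            break
        b *= np.sqrt(scale)
    else:
        raise RuntimeError(
            f"ICE did not converge in {max_iter} iterations (residual {residual:.3g})"
        )
    # rescale to unit mean balanced marginal
    marg = (sub / np.outer(b, b)).sum(axis=0)
    b *= np.sqrt(marg.mean())
    weights = np.full(m.n_bins, np.nan)
    weights[v] = b
    return replace(m, weights=weights)


@dataclass
class ExpectedProfile:
    """Distance-expected balanced contact per chromosome, plus per-pair trans means.

    ``cis[chrom][s]`` is the mean balanced value over unmasked bin pairs at
    diagonal offset ``s`` (in bins, offset 0 present); ``trans[(c1, c2)]`` is
    the mean balanced value over unmasked trans cells of the pair.
    """

    cis: dict[str, np.ndarray]
    trans: dict[tuple[str, str], float]
    bin_size: int

    def trans_expected(self, c1: str, c2: str) -> float:
        return self.trans[(c1, c2)] if (c1, c2) in self.trans else self.trans[(c2, c1)]


def expected_profile(m: ContactMatrix) -> ExpectedProfile:
    """Per-chromosome diagonal means and per-pair trans means of the balanced map."""
    bal = m.balanced()
    names = m.genome.names
    cis: dict[str, np.ndarray] = {}
    for name in names:
        s = m.genome.chrom_slice(name)
        block = bal[s, s]
        nb = block.shape[0]
        if m.valid[s].sum() < 2:
            warnings.warn(f"chromosome {name}: fewer than 2 unmasked bins, profile undefined")
            cis[name] = np.full(nb, np.nan)
            continue
        prof = np.full(nb, np.nan)
        for d in range(nb):
            diag = np.diagonal(block, offset=d)
            ok = ~np.isnan(diag)
            if ok.any():
                prof[d] = diag[ok].mean()
        cis[name] = prof
    trans: dict[tuple[str, str], float] = {}
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            blk = bal[m.genome.chrom_slice(names[a]), m.genome.chrom_slice(names[b])]
            ok = ~np.isnan(blk)
            trans[(names[a], names[b])] = float(blk[ok].mean()) if ok.any() else np.nan
    return ExpectedProfile(cis=cis, trans=trans, bin_size=m.genome.bin_size)


def observed_over_expected(m: ContactMatrix, e: ExpectedProfile | None = None) -> np.ndarray:
    """O/E matrix: cis cells divided by the distance expectation, trans cells by
    the chromosome-pair mean. Masked or zero-expected cells are NaN, never 0."""
    if e is None:
        e = expected_profile(m)
    bal = m.balanced()
    oe = np.full_like(bal, np.nan)
    names = m.genome.names
    for name in names:
        s = m.genome.chrom_slice(name)
        nb = s.stop - s.start
        i, j = np.indices((nb, nb))
        exp = e.cis[name][np.abs(i - j)]
        with np.errstate(invalid="ignore", divide="ignore"):
            blk = bal[s, s] / exp
        blk[exp == 0] = np.nan
        oe[s, s] = blk
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            sa, sb = m.genome.chrom_slice(names[a]), m.genome.chrom_slice(names[b])
            te = e.trans_expected(names[a], names[b])
            with np.errstate(invalid="ignore", divide="ignore"):
                blk = bal[sa, sb] / te
            if te == 0 or np.isnan(te):
                blk = np.full_like(blk, np.nan)
            oe[sa, sb] = blk
            oe[sb, sa] = blk.T
    return oe


def correlation_map(oe_block: np.ndarray) -> np.ndarray:
    """Pearson correlation of O/E rows over columns valid in both rows.

    Input is one chromosome's cis O/E block (NaN = masked/undefined). Rows
    with zero variance come back NaN (masked). The diagonal is 1 for valid
    rows.
    """
    n = oe_block.shape[0]
    out = np.full((n, n), np.nan)
    finite = np.isfinite(oe_block)
    row_ok = finite.sum(axis=1) >= 2
    # fast path: NaNs confined to whole rows/columns (the usual mask pattern)
    col_ok = finite[row_ok].all(axis=0) if row_ok.any() else np.zeros(n, bool)
    if row_ok.any() and (finite == np.outer(row_ok, col_ok)).all() and col_ok.sum() >= 2:
        sub = oe_block[np.ix_(row_ok, col_ok)]
        sd = sub.std(axis=1)
        ok = np.flatnonzero(row_ok)[sd > 0]
        if ok.size:
            with np.errstate(invalid="ignore"):
                c = np.corrcoef(oe_block[np.ix_(ok, col_ok)])
            out[np.ix_(ok, ok)] = c
        return out
    for i in range(n):
        if not row_ok[i]:
            continue
        for j in range(i, n):
            if not row_ok[j]:
                continue
            ok = finite[i] & finite[j]
            if ok.sum() < 2:
                continue
            xi, xj = oe_block[i, ok], oe_block[j, ok]
            sx, sy = xi.std(), xj.std()
            if sx == 0 or sy == 0:
                continue
            r = float(np.corrcoef(xi, xj)[0, 1])
            out[i, j] = out[j, i] = r
    return out
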