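"""A/B compartment calling from the leading eigenvector (E1) of Hi-C maps.

Positive E1 bins are labeled A and negative bins B after orienting the
eigenvector so that it correlates positively with GC content (the raw sign
of an eigenvector is arbitrary). Two modes are offered: ``trans`` decomposes
the genome-wide trans O/E map (cis blocks zeroed after centering), ``cis``
decomposes each chromosome's O/E correlation map separately. Compartment
borders are the bin edges separating A from B runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .matrix import ContactMatrix, correlation_map, expected_profile, observed_over_expected

ORIENT_DEADBAND = 0.05  # |corr(E1, GC)| below this: fall back to gene density
E1_ZERO = 1e-12  # |E1| below this is treated as masked
EIG_TIE = 1e-9  # leading-eigenvalue tie tolerance


@dataclass
class CompartmentTrack:
    """Per-bin E1 loadings with A/B labels and compartment borders."""

    genome: GenomeSpec
    e1: np.ndarray  # NaN on masked bins
    labels: np.ndarray  # object array: 'A' | 'B' | 'masked'
    borders: list[tuple[str, int]]  # (chrom, bp edge) at A<->B sign changes
    mode: str  # 'cis' | 'trans'

    @property
    def valid(self) -> np.ndarray:
        return self.labels != "masked"

    def label_at(self, chrom: str, pos: int) -> str:
        return str(self.labels[self.genome.bin_index(chrom, pos)])


def _top_eigvecs(a: np.ndarray, k: int = 3) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(a)
    order = np.argsort(vals)[::-1][:k]
    vals, vecs = vals[order], vecs[:, order]
    if len(vals) > 1 and abs(vals[0] - vals[1]) < EIG_TIE and abs(vals[0]) > EIG_TIE:
        raise ValueError("ambiguous E1: degenerate leading eigenvalue")
    return vals, vecs


def _pick_by_phasing(vecs: np.ndarray, phasing: np.ndarray) -> tuple[np.ndarray, float]:
    """Choose the eigenvector best correlated (in magnitude) with the phasing
    track (GC); returns the vector and its correlation. The compartment
    signature is not always the top eigenvector — a strong insulated domain
    or the centromere can dominate it — so the phasing track both selects
    and orients, as in standard E1 practice."""
    best, best_r = vecs[:, 0], 0.0
    if np.std(phasing) == 0:
        return best, 0.0
    for k in range(vecs.shape[1]):
        v = vecs[:, k]
        if np.std(v) == 0:
            continue
        r = float(np.corrcoef(v, phasing)[0, 1])
        if abs(r) > abs(best_r):
            best, best_r = v, r
    return best, best_r


def _borders(genome: GenomeSpec, labels: np.ndarray) -> list[tuple[str, int]]:
    borders = []
    bins = genome.bins()
    for name in genome.names:
        s = genome.chrom_slice(name)
        idx = [i for i in range(s.start, s.stop) if labels[i] != "masked"]
        for a, b in zip(idx[:-1], idx[1:]):
            if labels[a] != labels[b]:
                borders.append((name, int(bins.loc[b, "start"])))
    return borders


def call_compartments(
    m: ContactMatrix,
    gc: np.ndarray | None = None,
    mode: str = "trans",
    gene_density: np.ndarray | None = None,
) -> CompartmentTrack:
    """Call A/B compartments from the leading eigenvector of the contact map.

    ``gc`` defaults to the genome's GC track and is required for sign
    orientation: E1 is flipped so corr(E1, GC) >= 0. When that correlation is
    inside the +/-``ORIENT_DEADBAND`` dead band, ``gene_density`` is used
    instead if given, else the sign is kept with a warning.
    """
    if gc is None:
        gc = m.genome.gc
    if gc is None:
        raise ValueError("GC track required for E1 sign orientation")
    gc = np.asarray(gc, float)
    oe = observed_over_expected(m)
    n = m.n_bins
    e1 = np.full(n, np.nan)

    def _fill(idx: np.ndarray, vecs: np.ndarray) -> None:
        """Select among top eigenvectors by phasing track, orient, store."""
        vec, r = _pick_by_phasing(vecs, gc[idx])
        if abs(r) <= ORIENT_DEADBAND:
            if gene_density is not None and np.std(gene_density[idx]) > 0:
                vec, r = _pick_by_phasing(vecs, gene_density[idx])
            if abs(r) <= ORIENT_DEADBAND:
                warnings.warn(
                    f"E1 selection/orientation ambiguous (corr with GC {r:.3f}); "
                    "keeping leading eigenvector sign"
                )
        e1[idx] = vec if r >= 0 else -vec

    if mode == "cis":
        for name in m.genome.names:
            s = m.genome.chrom_slice(name)
            corr = correlation_map(oe[s, s])
            ok = np.isfinite(np.diagonal(corr))
            if ok.sum() < 2:
                continue
            sub = corr[np.ix_(ok, ok)]
            sub = sub - sub.mean(axis=1, keepdims=True)
            _, vecs = _top_eigvecs(sub)
            _fill(np.flatnonzero(ok) + s.start, vecs)
    elif mode == "trans":
        a = np.where(np.isfinite(oe), oe, np.nan)
        cis = m.genome.cis_mask()
        a[cis] = np.nan
        center = np.nanmean(a)
        a = np.where(np.isnan(a), 0.0, a - center)
        ok = m.valid
        _, vecs = _top_eigvecs(a[np.ix_(ok, ok)])
        _fill(np.flatnonzero(ok), vecs)
    else:
        raise ValueError(f"mode must be 'cis' or 'trans', got {mode!r}")

    labels = np.array(
        ["masked" if (not np.isfinite(v) or abs(v) < E1_ZERO) else ("A" if v > 0 else "B") for v in e1],
        dtype=object,
    )
    return CompartmentTrack(m.genome, e1, labels, _borders(m.genome, labels), mode)


def subcompartment_pca(
    m: ContactMatrix,
    track: CompartmentTrack,
    which_label: str = "A",
    centromere_bins: np.ndarray | None = None,
    noise_floor: float = 1e-9,
) -> dict:
    """Split one compartment into two sub-compartments by a second
    eigendecomposition of its trans contacts.

    Returns per-bin sub-labels ('A1'/'A2' on the selected bins, None
    elsewhere) plus, if centromere bins are supplied, which sub-compartment
    holds them. Warns "no sub-structure" when the restricted map is
    homogeneous (leading eigenvalue at the noise floor).
    """
    sel = np.flatnonzero((track.labels == which_label) & m.valid)
    if sel.size < 4:
        raise ValueError(f"fewer than 4 unmasked bins labeled {which_label!r}")
    oe = observed_over_expected(m)
    a = oe[np.ix_(sel, sel)]
    cis = m.genome.cis_mask()[np.ix_(sel, sel)]
    a = np.where(cis | ~np.isfinite(a), np.nan, a)
    center = np.nanmean(a)
    a = np.where(np.isnan(a), 0.0, a - center)
    vals, vecs = np.linalg.eigh(a)
    lam, vec = float(vals[-1]), vecs[:, -1]
    frob = float(np.linalg.norm(a))
    if abs(lam) <= noise_floor * max(1.0, frob):
        warnings.warn("no sub-structure: leading eigenvalue at noise floor")
    sub = np.full(m.n_bins, None, dtype=object)
    sub[sel] = np.where(vec >= 0, which_label + "1", which_label + "2")
    out = {"sub_labels": sub, "leading_eigenvalue": lam}
    if centromere_bins is not None:
        cen = [sub[b] for b in centromere_bins if sub[b] is not None]
        out["centromere_subcompartment"] = (
            max(set(cen), key=cen.count) if cen else None
        )
    return out


@dataclass
class SwitchTable:
    """Male/female compartment agreement merged into maximal runs.

    ``fraction_switched`` is the bp fraction of unmasked genome whose A/B
    identity differs between the two tracks (A->B plus B->A).
    """

    regions: pd.DataFrame  # chrom, start, end, category, length
    category_bp: dict[str, int]
    fraction_switched: float
    genome: GenomeSpec = field(repr=False, default=None)
    joint: np.ndarray = field(repr=False, default=None)  # per-bin category or None

    CATEGORIES = ("A->A", "B->B", "A->B", "B->A")

    def is_switching_at(self, chrom: str, pos: int) -> bool | None:
        cat = self.joint[self.genome.bin_index(chrom, pos)]
        return None if cat is None else cat in ("A->B", "B->A")


def compare_compartments(track_m: CompartmentTrack, track_f: CompartmentTrack) -> SwitchTable:
    """Compare two compartment tracks on the same binning (e.g. male vs female)."""
    g = track_m.genome
    if not g.same_binning(track_f.genome):
        raise ValueError("mismatched binning between tracks")
    joint = np.full(g.n_bins, None, dtype=object)
    both = track_m.valid & track_f.valid
    for i in np.flatnonzero(both):
        joint[i] = f"{track_m.labels[i]}->{track_f.labels[i]}"
    bins = g.bins()
    widths = (bins["end"] - bins["start"]).to_numpy()
    rows = []
    for name in g.names:
        s = g.chrom_slice(name)
        run_start, run_cat = None, None
        for i in list(range(s.start, s.stop)) + [s.stop]:
            cat = joint[i] if i < s.stop else None
            if cat != run_cat:
                if run_cat is not None:
                    rows.append(
                        {
                            "chrom": name,
                            "start": int(bins.loc[run_start, "start"]),
                            "end": int(bins.loc[i - 1, "end"]),
                            "category": run_cat,
                        }
                    )
                run_start, run_cat = i, cat
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "category"])
    regions["length"] = regions["end"] - regions["start"]
    bp = {c: 0 for c in SwitchTable.CATEGORIES}
    for i in np.flatnonzero(both):
        bp[joint[i]] += int(widths[i])
    total = sum(bp.values())
    switched = bp["A->B"] + bp["B->A"]
    frac = switched / total if total else 0.0
    return SwitchTable(regions, bp, frac, genome=g, joint=joint)
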