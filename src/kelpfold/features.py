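"""Centromere and telomere annotation.

Centromeres are localized two ways and the methods cross-validate each
other: (i) from the Hi-C map, as the mutually-reinforcing set of bins whose
trans contacts with the other chromosomes' candidate centromeres are
maximal; (ii) from repeat annotations, as the span from the first to the
last copy of centromere-specific repeat families — families selected for
being nearly exclusive to the Hi-C candidate windows and present on every
chromosome. Telomeric tracts are tandem runs of the telomere motif
(TTAGGG by default) at chromosome ends.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ContactMatrix, observed_over_expected

REPEAT_CLASSES = ("interspersed", "tandem", "low_complexity")


@dataclass
class RepeatAnnotation:
    """Repeat intervals with family labels and a coarse class."""

    intervals: pd.DataFrame  # chrom, start, end, family, class

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "family", "class"}
        missing = req - set(self.intervals.columns)
        if missing:
            raise ValueError(f"repeat table missing columns {sorted(missing)}")
        if (self.intervals["family"].astype(str).str.len() == 0).any():
            raise ValueError("empty repeat family name")
        bad = ~self.intervals["class"].isin(REPEAT_CLASSES)
        if bad.any():
            raise ValueError(f"unknown repeat class values: {self.intervals.loc[bad, 'class'].unique()}")


@dataclass
class CentromereCall:
    chrom: str
    start: int
    end: int
    method: str  # 'hic' | 'repeat-span'
    families: list[str] = field(default_factory=list)
    composition: dict | None = None


def locate_centromeres_hic(
    m: ContactMatrix,
    oe: np.ndarray | None = None,
    max_rounds: int = 50,
    enrichment_floor: float = 1.2,
    exclude_terminal: int = 200_000,
    smooth_bins: int = 7,
    refine: bool = True,
) -> pd.DataFrame:
    """Per-chromosome centromere candidate bin from trans contact clustering.

    Iterates ``c_i <- argmax_b sum_{j != i} trans O/E(b, c_j)`` from an
    initial guess at each chromosome's maximal total-trans bin, to a fixed
    point (ties to the lowest bin index). Telomeres also cluster in trans
    and form a competing attractor, so the ``exclude_terminal`` bp at each
    chromosome end are excluded from the candidate set (centromeres are
    interior by definition). Because a single trans cell holds few counts,
    the O/E map is box-smoothed over ``smooth_bins`` before the argmax (set
    to 1 for the raw cellwise update). Returns a table with the candidate
    global bin,
    its bp midpoint, the mean O/E score against the other candidates, and a
    ``no_enrichment`` flag when that score is below ``enrichment_floor``
    times the background trans level.
    """
    g = m.genome
    names = g.names
    if len(names) < 2:
        raise ValueError("need at least 2 chromosomes")
    if oe is None:
        oe = observed_over_expected(m)
    t = np.where(g.cis_mask(), np.nan, oe)
    if not np.isfinite(t).any():
        raise ValueError("no trans contacts")
    t0 = np.where(np.isnan(t), 0.0, t)
    if smooth_bins > 1:
        from scipy.ndimage import uniform_filter

        t0 = uniform_filter(t0, size=smooth_bins, mode="constant")
    k_excl = exclude_terminal // g.bin_size
    cand_slices = {}
    for n in names:
        s = g.chrom_slice(n)
        lo, hi = s.start + k_excl, s.stop - k_excl
        if hi - lo < 1:  # short chromosome: fall back to full range
            lo, hi = s.start, s.stop
        cand_slices[n] = slice(lo, hi)
    # initialize at each chromosome's maximal total-trans candidate bin
    totals = t0.sum(axis=1)
    cand = {n: cand_slices[n].start + int(np.argmax(totals[cand_slices[n]])) for n in names}
    for _ in range(max_rounds):
        changed = False
        for n in names:
            others = [cand[o] for o in names if o != n]
            cs = cand_slices[n]
            scores = t0[cs, :][:, others].sum(axis=1)
            best = cs.start + int(np.argmax(scores))  # argmax ties -> lowest index
            if best != cand[n]:
                cand[n] = best
                changed = True
        if not changed:
            break
    background = float(np.nanmean(t))
    bins = g.bins()
    refined = dict(cand)
    if refine:
        # the enriched region is wider than one bin: move each call to the
        # enrichment-weighted centroid of its peak neighborhood (centroids are
        # all computed against the unrefined fixed point)
        for n in names:
            others = [cand[o] for o in names if o != n]
            cs = cand_slices[n]
            prof = t0[cs, :][:, others].mean(axis=1)
            peak = cand[n] - cs.start
            lo = max(0, peak - 3 * smooth_bins)
            hi = min(len(prof), peak + 3 * smooth_bins + 1)
            idx = np.arange(lo, hi)
            wts = np.maximum(prof[lo:hi] - background, 0.0)
            if wts.sum() > 0:
                refined[n] = cs.start + int(round(float((idx * wts).sum() / wts.sum())))
    cand = refined
    rows = []
    for n in names:
        others = [cand[o] for o in names if o != n]
        score = float(np.mean(t0[cand[n], others]))
        rows.append(
            {
                "chrom": n,
                "bin": cand[n],
                "midpoint": int((bins.loc[cand[n], "start"] + bins.loc[cand[n], "end"]) // 2),
                "score": score,
                "no_enrichment": bool(score < enrichment_floor * background),
            }
        )
    return pd.DataFrame(rows)


def scan_centromeric_families(
    r: RepeatAnnotation,
    candidate_windows: dict[str, tuple[int, int]],
    min_specificity: float = 0.9,
    min_chrom_fraction: float = 1.0,
) -> pd.DataFrame:
    """Rank repeat families enriched in candidate centromeric windows and
    common to (nearly) all chromosomes.

    Specificity is the fraction of a family's genome-wide copies falling
    inside the windows (by midpoint); ubiquity the fraction of windowed
    chromosomes carrying >= 1 copy in their window. Families passing both
    thresholds are returned ranked by specificity x copy count.
    """
    df = r.intervals.copy()
    df["mid"] = (df["start"] + df["end"]) // 2

    def _in_window(row) -> bool:
        w = candidate_windows.get(row["chrom"])
        return bool(w and w[0] <= row["mid"] < w[1])

    df["in_window"] = df.apply(_in_window, axis=1)
    out = []
    n_chroms = len(candidate_windows)
    for fam, grp in df.groupby("family"):
        total = len(grp)
        inside = int(grp["in_window"].sum())
        specificity = inside / total
        chroms_hit = grp.loc[grp["in_window"], "chrom"].nunique()
        ubiquity = chroms_hit / n_chroms
        out.append(
            {
                "family": fam,
                "copies": total,
                "copies_in_windows": inside,
                "specificity": specificity,
                "ubiquity": ubiquity,
                "passes": specificity >= min_specificity and ubiquity >= min_chrom_fraction,
                "rank_score": specificity * total,
            }
        )
    table = pd.DataFrame(out).sort_values("rank_score", ascending=False).reset_index(drop=True)
    return table[table["passes"]].reset_index(drop=True)


def define_centromere_spans(r: RepeatAnnotation, families: list[str]) -> list[CentromereCall]:
    """Centromere span per chromosome: first to last copy of the selected
    families (a single copy yields that copy's own interval)."""
    if not families:
        raise ValueError("empty family list")
    df = r.intervals[r.intervals["family"].isin(families)]
    calls = []
    for chrom, grp in df.groupby("chrom", sort=False):
        calls.append(
            CentromereCall(
                chrom=str(chrom),
                start=int(grp["start"].min()),
                end=int(grp["end"].max()),
                method="repeat-span",
                families=sorted(set(grp["family"])),
            )
        )
    return calls


def _coverage(intervals: list[tuple[int, int]], lo: int, hi: int) -> int:
    """Total covered bp of [lo, hi) by a set of intervals (overlaps merged)."""
    clipped = sorted(
        (max(s, lo), min(e, hi)) for s, e in intervals if min(e, hi) > max(s, lo)
    )
    covered, cur_s, cur_e = 0, None, None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def _gc_frac(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    return (seq.count("G") + seq.count("C")) / acgt if acgt else np.nan


def centromere_composition(
    calls: list[CentromereCall],
    r: RepeatAnnotation,
    sequences: dict[str, str] | None = None,
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Base composition of each centromere span, plus the cross-centromere mean.

    Per span: fraction of bases from each selected family, from other
    interspersed repeats, and from tandem repeats (selected families take
    precedence over tandem, tandem over other interspersed, so fractions sum
    to <= 1); GC of the span versus the rest of the genome when sequences are
    given; count of overlapping genes when a gene table is given.
    """
    rows = []
    df = r.intervals
    for call in calls:
        span = (call.chrom, call.start, call.end)
        width = call.end - call.start
        here = df[(df["chrom"] == call.chrom) & (df["end"] > call.start) & (df["start"] < call.end)]
        sel = here[here["family"].isin(call.families)]
        sel_iv = list(zip(sel["start"], sel["end"]))
        row: dict = {"chrom": call.chrom, "start": call.start, "end": call.end, "length": width}
        for fam in call.families:
            fam_iv = list(zip(*[sel.loc[sel["family"] == fam, c] for c in ("start", "end")])) if len(sel) else []
            row[f"frac_{fam}"] = _coverage(fam_iv, call.start, call.end) / width
        # precedence: selected families > tandem > other interspersed
        tandem = here[(here["class"] == "tandem") & ~here["family"].isin(call.families)]
        other = here[(here["class"] == "interspersed") & ~here["family"].isin(call.families)]
        sel_cov = _coverage(sel_iv, call.start, call.end)
        tan_cov = _coverage(sel_iv + list(zip(tandem["start"], tandem["end"])), call.start, call.end) - sel_cov
        oth_cov = (
            _coverage(
                sel_iv
                + list(zip(tandem["start"], tandem["end"]))
                + list(zip(other["start"], other["end"])),
                call.start,
                call.end,
            )
            - sel_cov
            - tan_cov
        )
        row["frac_tandem"] = tan_cov / width
        row["frac_other_interspersed"] = oth_cov / width
        if sequences is not None and call.chrom in sequences:
            seq = sequences[call.chrom]
            row["gc_span"] = _gc_frac(seq[call.start : call.end])
            row["gc_rest"] = _gc_frac(seq[: call.start] + seq[call.end :])
        if genes is not None:
            ov = genes[
                (genes["chrom"] == call.chrom)
                & (genes["end"] > call.start)
                & (genes["start"] < call.end)
            ]
            row["n_genes"] = len(ov)
        rows.append(row)
    table = pd.DataFrame(rows)
    mean_row = table.drop(columns=["chrom", "start", "end"]).mean(numeric_only=True)
    mean_row["chrom"] = "mean"
    table = pd.concat([table, mean_row.to_frame().T], ignore_index=True)
    return table


_RC = str.maketrans("ACGT", "TGCA")


def detect_telomeric_tracts(
    sequence: str,
    motif: str = "TTAGGG",
    min_copies: int = 5,
    max_offset: int = 2000,
) -> dict:
    """Detect tandem telomere-motif tracts near each end of a chromosome.

    The 5' end is scanned for the reverse complement of the motif (CCCTAA
    for TTAGGG), the 3' end for the motif itself; a tract is >= ``min_copies``
    exact tandem copies starting within ``max_offset`` bp of the end.
    Returns per-end tract coordinates (or None) and telomere-to-telomere
    status.
    """
    seq = sequence.upper()
    rc = motif.upper().translate(_RC)[::-1]
    out: dict = {"five_prime": None, "three_prime": None}
    pat5 = re.compile(f"(?:{rc}){{{min_copies},}}")
    for mt in pat5.finditer(seq[: max_offset + min_copies * len(motif) * 10]):
        if mt.start() <= max_offset:
            out["five_prime"] = {
                "start": mt.start(),
                "end": mt.end(),
                "n_copies": (mt.end() - mt.start()) // len(motif),
            }
            break
    tail_off = max(0, len(seq) - max_offset - min_copies * len(motif) * 10)
    best = None
    pat3 = re.compile(f"(?:{motif.upper()}){{{min_copies},}}")
    for mt in pat3.finditer(seq[tail_off:]):
        if len(seq) - (tail_off + mt.end()) <= max_offset:
            best = {
                "start": tail_off + mt.start(),
                "end": tail_off + mt.end(),
                "n_copies": (mt.end() - mt.start()) // len(motif),
            }
    out["three_prime"] = best
    out["t2t"] = out["five_prime"] is not None and out["three_prime"] is not None
    return out


def telomere_summary(
    sequences: dict[str, str],
    motif: str = "TTAGGG",
    min_copies: int = 5,
    max_offset: int = 2000,
) -> dict:
    """Genome-wide telomere resolution summary: per-chromosome end status,
    number of resolved telomeric regions, and telomere-to-telomere count.

    The "resolved" criterion (>= ``min_copies`` tandem copies within
    ``max_offset`` bp of the end) is explicit configuration.
    """
    per_chrom = {}
    n_resolved = n_t2t = 0
    for name, seq in sequences.items():
        res = detect_telomeric_tracts(seq, motif, min_copies, max_offset)
        per_chrom[name] = res
        n_resolved += int(res["five_prime"] is not None) + int(res["three_prime"] is not None)
        n_t2t += int(res["t2t"])
    return {
        "per_chromosome": per_chrom,
        "n_chromosomes": len(sequences),
        "n_ends": 2 * len(sequences),
        "n_resolved_ends": n_resolved,
        "n_t2t": n_t2t,
        "criterion": {"motif": motif, "min_copies": min_copies, "max_offset": max_offset},
    }
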