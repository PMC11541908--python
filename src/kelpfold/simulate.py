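"""Seeded synthetic Hi-C genome with planted 3D-architecture truth.

The generator emulates, at desk scale, the architectural signals this
package measures: a power-law cis contact decay with a chosen exponent,
alternating A/B compartment blocks with like-with-like contact preference,
trans clustering of centromeres and telomeres, an insulated domain with
optional elevated trans-telomere contact, an optional Rabl-style
equal-arm-position band, and matched feature tracks (GC, genes with
expression and differential-expression statistics, histone-mark peaks, a
centromere-confined repeat family, chromosome sequences with telomeric
tracts). Counts are independent Poisson draws around the planted intensity,
so every run is exactly reproducible from its seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .features import RepeatAnnotation
from .genome import GenomeSpec
from .matrix import ContactMatrix

ACTIVATION_MARKS = ("H3K4me3", "H3K9ac", "H3K27ac", "H3K36me3")
REPRESSIVE_MARKS = ("H3K79me2",)


@dataclass
class SyntheticTruth:
    """Planted parameters of a synthetic Hi-C experiment.

    Defaults give a 4 x 2 Mb genome at 10 kb bins with recoverable but
    non-trivial signals: decay exponent 0.9, compartment contact factors
    1.6 (within) / 0.7 (between), ~5% trans contacts, centromere and
    telomere clustering boosts 5 and 3 over 100 kb regions, and an insulated
    400 kb domain with cross-boundary attenuation 0.3.
    """

    n_chromosomes: int = 4
    chrom_length: int = 2_000_000
    bin_size: int = 10_000
    alpha: float = 0.9  # cis decay exponent (P(s) ~ s^-alpha)
    compartment_block: int = 200_000  # alternating A/B block size, bp
    f_aa: float = 1.6
    f_bb: float = 1.6
    f_ab: float = 0.7
    trans_fraction: float = 0.05  # share of contacts that are trans
    trans_compartment_factor: float = 1.0  # like-label trans boost (1 = off)
    centromere_fractions: tuple[float, ...] = (0.5, 0.45, 0.55, 0.5)
    centromere_width: int = 140_000  # boosted region, bp
    beta_c: float = 5.0  # centromere-centromere trans boost
    telomere_width: int = 120_000  # boosted region per end, bp
    beta_t: float = 3.0  # telomere-telomere trans boost
    # placed off the compartment-block grid so its boundaries are its own
    insulated_region: tuple[str, int, int] | None = ("chr4", 1_050_000, 1_450_000)
    tad_regions: tuple[tuple[str, int, int], ...] = ()  # extra delta-insulated domains
    delta: float = 0.3  # cross-boundary attenuation (1 = off)
    beta_q: float = 1.0  # insulated-region x telomere trans boost (1 = off)
    beta_r: float = 1.0  # Rabl equal-arm-position boost (1 = off)
    rabl_band: float = 0.05  # half-width of the Rabl band, relative coordinate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        for name, v in [("beta_c", self.beta_c), ("beta_t", self.beta_t),
                        ("beta_q", self.beta_q), ("beta_r", self.beta_r)]:
            if v < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.delta <= 1):
            raise ValueError("delta must be in (0, 1]")
        if len(self.centromere_fractions) != self.n_chromosomes:
            raise ValueError("need one centromere fraction per chromosome")
        if not (0 < self.trans_fraction < 1):
            raise ValueError("trans_fraction must be in (0, 1)")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def genome(self) -> GenomeSpec:
        return GenomeSpec(
            [(n, self.chrom_length) for n in self.chrom_names], self.bin_size
        )

    def centromeres(self) -> dict[str, int]:
        """Centromere midpoints, bp."""
        return {
            n: int(f * self.chrom_length)
            for n, f in zip(self.chrom_names, self.centromere_fractions)
        }

    def labels(self) -> np.ndarray:
        """Per-bin compartment label, alternating blocks; the phase rotates by
        chromosome so labels do not correlate with absolute position."""
        g = self.genome()
        out = np.empty(g.n_bins, dtype=object)
        for ci, name in enumerate(self.chrom_names):
            s = g.chrom_slice(name)
            starts = np.arange(s.stop - s.start) * self.bin_size
            block = starts // self.compartment_block + ci
            out[s] = np.where(block % 2 == 0, "A", "B")
        return out

    def centromere_bins(self) -> np.ndarray:
        g = self.genome()
        out = np.zeros(g.n_bins, bool)
        for name, mid in self.centromeres().items():
            s = g.chrom_slice(name)
            lo = max(0, (mid - self.centromere_width // 2) // self.bin_size)
            hi = -(-(mid + self.centromere_width // 2) // self.bin_size)
            out[s.start + lo : min(s.start + hi, s.stop)] = True
        return out

    def telomere_bins(self) -> np.ndarray:
        g = self.genome()
        out = np.zeros(g.n_bins, bool)
        k = self.telomere_width // self.bin_size
        for name in self.chrom_names:
            s = g.chrom_slice(name)
            out[s.start : s.start + k] = True
            out[s.stop - k : s.stop] = True
        return out

    def insulated_bins(self) -> np.ndarray:
        g = self.genome()
        out = np.zeros(g.n_bins, bool)
        if self.insulated_region is not None:
            chrom, start, end = self.insulated_region
            s = g.chrom_slice(chrom)
            out[s.start + start // self.bin_size : s.start + -(-end // self.bin_size)] = True
        return out

    def arm_positions(self) -> np.ndarray:
        """Per-bin relative position on a centromere-centered [0, 1] axis
        (centromere at 0.5), used for the Rabl band."""
        g = self.genome()
        u = np.zeros(g.n_bins)
        for name, cen in self.centromeres().items():
            s = g.chrom_slice(name)
            mids = np.arange(s.stop - s.start) * self.bin_size + self.bin_size / 2
            p = mids < cen
            u[s][: len(mids)] = np.where(
                p, 0.5 * mids / cen, 0.5 + 0.5 * (mids - cen) / (self.chrom_length - cen)
            )
        return u

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("insulated_region"):
            d["insulated_region"] = tuple(d["insulated_region"])
        d["centromere_fractions"] = tuple(d["centromere_fractions"])
        d["tad_regions"] = tuple(tuple(r) for r in d.get("tad_regions", ()))
        return cls(**d)


def null_truth(seed: int = 0, **overrides) -> SyntheticTruth:
    """A structureless truth: decay only (all factors 1, no insulation)."""
    return SyntheticTruth(
        f_aa=1.0, f_bb=1.0, f_ab=1.0, beta_c=1.0, beta_t=1.0,
        insulated_region=None, delta=1.0, beta_q=1.0, beta_r=1.0,
        seed=seed, **overrides,
    )


def planted_intensity(truth: SyntheticTruth) -> np.ndarray:
    """Expected contact intensity matrix (unnormalized), before depth scaling."""
    g = truth.genome()
    n = g.n_bins
    labels = truth.labels()
    is_a = labels == "A"
    lam = np.zeros((n, n))
    # cis: power-law decay x compartment factor x insulation attenuation
    n_a = np.add.outer(is_a.astype(int), is_a.astype(int))
    f = np.where(n_a == 2, truth.f_aa, np.where(n_a == 0, truth.f_bb, truth.f_ab))
    ins = truth.insulated_bins()
    region_masks = [ins] if ins.any() else []
    for chrom, start, end in truth.tad_regions:
        rm = np.zeros(n, bool)
        s = g.chrom_slice(chrom)
        rm[s.start + start // truth.bin_size : s.start + -(-end // truth.bin_size)] = True
        region_masks.append(rm)
    for name in g.names:
        s = g.chrom_slice(name)
        nb = s.stop - s.start
        i, j = np.indices((nb, nb))
        d = np.maximum(np.abs(i - j), 1).astype(float)
        mod = f[s, s].copy()
        for rm in region_masks:
            cross = np.logical_xor.outer(rm[s], rm[s])
            mod[cross] *= truth.delta
        block = d ** (-truth.alpha) * mod
        # compartment/insulation factors act in O/E space: renormalize each
        # diagonal so the planted decay law is preserved exactly
        for off in range(nb):
            diag = np.diagonal(block, offset=off)
            mean = diag.mean()
            if mean > 0:
                target = float(np.maximum(off, 1)) ** (-truth.alpha)
                idx = np.arange(nb - off)
                block[idx, idx + off] *= target / mean
                if off:
                    block[idx + off, idx] *= target / mean
        lam[s, s] = block
    # trans: flat base with clustering boosts
    cis = g.cis_mask()
    trans = ~cis
    t = np.ones((n, n))
    cen, tel = truth.centromere_bins(), truth.telomere_bins()
    t[np.ix_(cen, cen)] *= truth.beta_c
    t[np.ix_(tel, tel)] *= truth.beta_t
    if truth.trans_compartment_factor != 1.0:
        same = np.equal.outer(labels, labels)
        t[same] *= truth.trans_compartment_factor
    if truth.beta_q != 1.0:
        t[np.ix_(ins, tel)] *= truth.beta_q
        t[np.ix_(tel, ins)] *= truth.beta_q
    if truth.beta_r != 1.0:
        u = truth.arm_positions()
        band = np.abs(np.subtract.outer(u, u)) <= truth.rabl_band
        t[band] *= truth.beta_r
    t[cis] = 0.0
    # scale trans so the expected trans share of contacts matches
    cis_sum = np.triu(lam).sum()
    t_sum = np.triu(t).sum()
    if t_sum > 0:
        t *= truth.trans_fraction / (1 - truth.trans_fraction) * cis_sum / t_sum
    lam = lam + t
    return (lam + lam.T) / 2


def simulate_contact_map(
    truth: SyntheticTruth, depth: float = 1_000_000, seed: int | None = None
) -> ContactMatrix:
    """Draw a symmetric Poisson contact map with expected total ``depth``
    (counted as unordered bin pairs, diagonal included)."""
    if depth < 1e4:
        raise ValueError("depth must be >= 1e4")
    lam = planted_intensity(truth)
    scale = depth / np.triu(lam).sum()
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    upper = np.triu(rng.poisson(lam * scale))
    counts = upper + np.triu(upper, k=1).T
    return ContactMatrix(truth.genome(), counts.astype(float))


@dataclass
class SimulatedTracks:
    """Feature tracks matched to a :class:`SyntheticTruth`."""

    gc: np.ndarray  # per-bin GC fraction
    genes: pd.DataFrame  # id, chrom, start, end, TPM_male, TPM_female, log2FC, padj
    peaks: pd.DataFrame  # chrom, start, end, mark, fold_enrichment
    repeats: RepeatAnnotation
    sequences: dict[str, str]
    n_sbg_planted: int = 0
    centromere_family: str = "CenRT-1"


def simulate_feature_tracks(
    truth: SyntheticTruth,
    n_genes: int = 1000,
    n_peaks_per_mark: int = 300,
    sbg_fraction: float = 0.1,
    gc_mu_a: float = 0.55,
    gc_mu_b: float = 0.50,
    gc_sigma: float = 0.01,
    expression_shift: float = 1.5,  # A-minus-B difference of mean log2(TPM+1)
    mark_shift: float = 1.0,  # compartment shift of mean log2 fold_enrichment
    telomere_plan: dict[str, tuple[bool, bool]] | None = None,
    with_sequences: bool = True,
    seed: int | None = None,
) -> SimulatedTracks:
    """Generate GC, gene, peak, repeat and sequence tracks consistent with the
    planted compartments and centromeres.

    GC and expression are higher in A bins; activation-mark analogs are
    A-shifted and the repressive analog B-shifted. A planted retrotransposon
    family is confined to the centromere regions. Chromosome sequences carry
    (TTAGGG)n tracts at the ends named in ``telomere_plan`` (default: both
    ends of chr1/chr2, the 5' end of chr3, none on chr4).
    """
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    g = truth.genome()
    labels = truth.labels()
    is_a = labels == "A"
    gc = np.where(is_a, gc_mu_a, gc_mu_b) + rng.normal(0, gc_sigma, g.n_bins)
    gc = np.clip(gc, 0.0, 1.0)
    bins = g.bins()

    # genes: uniform placement, expression higher in A, a planted SBG fraction
    gene_len = 2000
    chroms = rng.choice(truth.chrom_names, n_genes)
    starts = rng.integers(0, truth.chrom_length - gene_len, n_genes)
    mids = starts + gene_len // 2
    gene_bins = np.array([g.bin_index(c, int(p)) for c, p in zip(chroms, mids)])
    base = np.where(is_a[gene_bins], 2.5 + expression_shift, 2.5)
    log_tpm_m = rng.normal(base, 1.0)
    log_tpm_f = rng.normal(base, 1.0)
    n_sbg = int(round(sbg_fraction * n_genes))
    sbg_idx = rng.choice(n_genes, n_sbg, replace=False)
    log2fc = rng.normal(0, 0.3, n_genes)
    padj = rng.uniform(0.02, 1.0, n_genes)
    half = n_sbg // 2
    log2fc[sbg_idx[:half]] = 1.0 + np.abs(rng.normal(1.0, 0.5, half))  # MBG
    log2fc[sbg_idx[half:]] = -(1.0 + np.abs(rng.normal(1.0, 0.5, n_sbg - half)))  # FBG
    padj[sbg_idx] = rng.uniform(1e-6, 0.009, n_sbg)
    genes = pd.DataFrame(
        {
            "id": [f"gene{i:05d}" for i in range(n_genes)],
            "chrom": chroms,
            "start": starts,
            "end": starts + gene_len,
            "TPM_male": np.maximum(2.0**log_tpm_m - 1, 0.0),
            "TPM_female": np.maximum(2.0**log_tpm_f - 1, 0.0),
            "log2FC": log2fc,
            "padj": padj,
        }
    )
    genes["TPM"] = genes["TPM_male"]

    # histone-mark peaks: activation analogs A-shifted, repressive B-shifted
    peak_rows = []
    for mark in ACTIVATION_MARKS + REPRESSIVE_MARKS:
        pc = rng.choice(truth.chrom_names, n_peaks_per_mark)
        ps = rng.integers(0, truth.chrom_length - 2000, n_peaks_per_mark)
        pb = np.array([g.bin_index(c, int(p + 1000)) for c, p in zip(pc, ps)])
        shift = mark_shift if mark in ACTIVATION_MARKS else -mark_shift
        mu = 1.5 + np.where(is_a[pb], shift / 2, -shift / 2)
        fe = 2.0 ** rng.normal(mu, 0.5)
        peak_rows.append(
            pd.DataFrame({"chrom": pc, "start": ps, "end": ps + 2000, "mark": mark, "fold_enrichment": fe})
        )
    peaks = pd.concat(peak_rows, ignore_index=True)

    repeats = _simulate_repeats(truth, rng)
    sequences = (
        _simulate_sequences(truth, gc, telomere_plan, rng) if with_sequences else {}
    )
    return SimulatedTracks(
        gc=gc, genes=genes, peaks=peaks, repeats=repeats,
        sequences=sequences, n_sbg_planted=n_sbg,
    )


def _simulate_repeats(truth: SyntheticTruth, rng: np.random.Generator) -> RepeatAnnotation:
    rows = []
    half = truth.centromere_width // 2
    for name, cen in truth.centromeres().items():
        lo = cen - half
        # primary centromeric family: full-length ~6.6 kb copies
        for _ in range(5):
            s = int(rng.integers(lo, cen + half - 6600))
            rows.append((name, s, s + 6600, "CenRT-1", "interspersed"))
        # degraded second family: ~1 kb fragments
        for _ in range(2):
            s = int(rng.integers(lo, cen + half - 1000))
            rows.append((name, s, s + 1000, "CenRT-2", "interspersed"))
    for fam, n_copies, width in [("LTR-X", 80, 4000), ("DNA-Y", 60, 1500)]:
        for _ in range(n_copies):
            c = str(rng.choice(truth.chrom_names))
            s = int(rng.integers(0, truth.chrom_length - width))
            rows.append((c, s, s + width, fam, "interspersed"))
    for fam, cls, n_copies, width in [
        ("SAT-98", "tandem", 40, 2000),
        ("lowcomp", "low_complexity", 40, 500),
    ]:
        for _ in range(n_copies):
            c = str(rng.choice(truth.chrom_names))
            s = int(rng.integers(0, truth.chrom_length - width))
            rows.append((c, s, s + width, fam, cls))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "family", "class"])
    return RepeatAnnotation(df.sort_values(["chrom", "start"]).reset_index(drop=True))


def _simulate_sequences(
    truth: SyntheticTruth,
    gc: np.ndarray,
    telomere_plan: dict[str, tuple[bool, bool]] | None,
    rng: np.random.Generator,
) -> dict[str, str]:
    if telomere_plan is None:
        telomere_plan = {"chr1": (True, True), "chr2": (True, True), "chr3": (True, False), "chr4": (False, False)}
    g = truth.genome()
    seqs = {}
    for name in truth.chrom_names:
        s = g.chrom_slice(name)
        per_base_gc = np.repeat(gc[s], truth.bin_size)[: truth.chrom_length]
        u = rng.random(truth.chrom_length)
        v = rng.random(truth.chrom_length)
        bases = np.where(
            u < per_base_gc, np.where(v < 0.5, "G", "C"), np.where(v < 0.5, "A", "T")
        )
        seq = "".join(bases)
        p5, p3 = telomere_plan.get(name, (False, False))
        if p5:
            seq = "CCCTAA" * 30 + seq[180:]
        if p3:
            seq = seq[:-180] + "TTAGGG" * 30
        seqs[name] = seq
    return seqs
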