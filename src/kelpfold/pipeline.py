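"""Config-driven end-to-end pipeline with provenance.

Stages run in dependency order (bin -> balance -> decay -> compartments ->
aggregate -> insulation -> centromeres/telomeres -> integration); each
output directory gets a JSON report stamped with the config hash and seed.
Inputs come either from files (pairs/COO + chrom sizes + tracks) or from
the synthetic generator when no contact input is configured.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import aggregate as agg
from . import compartments as comp
from . import decay, features, insulation, integrate, io
from .genome import GenomeSpec
from .matrix import bin_pairs, ice_balance, mask_low_coverage
from .simulate import SyntheticTruth, simulate_contact_map, simulate_feature_tracks

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline inputs and parameters, serializable to YAML."""

    out_dir: str = "kelpfold_run"
    seed: int = 0
    # inputs (all optional; with no contact input the synthetic generator runs)
    pairs: str | None = None
    coo: str | None = None
    chrom_sizes: str | None = None
    gc_bedgraph: str | None = None
    fasta: str | None = None
    repeats: str | None = None
    peaks: str | None = None
    genes: str | None = None
    # parameters
    bin_size: int = 10_000
    min_frac: float = 0.02
    balance_tol: float = 1e-5
    balance_max_iter: int = 200
    decay_range: tuple[int, int] = (10_000, 500_000)
    compartment_mode: str = "cis"
    n_pseudo: int = 100
    aca_window: int = 5
    insulation_window: int = 100_000
    boundary_min_strength: float = 0.5
    tad_strength_threshold: float = 1.0
    telomere_min_copies: int = 5
    telomere_max_offset: int = 2000
    # synthetic-mode depth
    depth: float = 1_000_000

    def hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "decay_range" in d and d["decay_range"] is not None:
            d["decay_range"] = tuple(d["decay_range"])
        return cls(**d)

    def validate(self) -> None:
        for name in ("pairs", "coo", "chrom_sizes", "gc_bedgraph", "fasta", "repeats", "peaks", "genes"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input {name} does not exist: {p}")
        if self.compartment_mode not in ("cis", "trans"):
            raise ValueError("compartment_mode must be 'cis' or 'trans'")
        if self.bin_size <= 0 or self.min_frac < 0 or self.n_pseudo % 2:
            raise ValueError("parameter out of range")


def _stage(report: dict, name: str, fn, *args, **kwargs):
    log.info("stage %s", name)
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        report["failed_stage"] = name
        report["error"] = str(exc)
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the summary report (also written
    to ``out_dir/report.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.hash(), "seed": config.seed, "stages": {}}
    config.to_yaml(out / "config.yaml")

    # --- input / simulate
    tracks = None
    sequences = None
    if config.pairs or config.coo:
        if not config.chrom_sizes:
            raise ValueError("chrom_sizes required with pairs/COO input")
        genome = GenomeSpec(io.read_chrom_sizes(config.chrom_sizes), config.bin_size)
        if config.pairs:
            m = _stage(report, "bin", bin_pairs, io.read_pairs(config.pairs), genome)
        else:
            m = _stage(report, "bin", io.read_coo, config.coo, genome)
        gc = None
        if config.gc_bedgraph:
            gc = io.read_bedgraph(config.gc_bedgraph, genome)
        elif config.fasta:
            sequences = io.read_fasta(config.fasta)
            gc = io.gc_track_from_fasta(sequences, genome)
        if gc is None and config.compartment_mode:
            raise ValueError(
                "missing GC input: compartment calling needs gc_bedgraph or fasta"
            )
        genome.gc = gc
        m.genome.gc = gc
    else:
        truth = SyntheticTruth(bin_size=config.bin_size, seed=config.seed)
        m = _stage(report, "simulate", simulate_contact_map, truth, config.depth, config.seed)
        tracks = simulate_feature_tracks(truth, seed=config.seed + 1)
        m.genome.gc = tracks.gc
        sequences = tracks.sequences
        report["stages"]["simulate"] = {"truth": "synthetic defaults", "depth": config.depth}
    genome = m.genome
    report["stages"]["bin"] = {"n_bins": genome.n_bins, "total_pairs": m.total_count}

    # --- mask + balance
    m = _stage(report, "mask", mask_low_coverage, m, config.min_frac)
    m = _stage(report, "balance", ice_balance, m, config.balance_tol, config.balance_max_iter)
    io.write_coo(out / "matrix.coo.tsv", m)
    report["stages"]["balance"] = {
        "n_masked": int(m.masked.sum()),
        "normalization": "iterative correction (unit mean marginal)",
    }

    # --- decay
    fits = {}
    for name in genome.names:
        curve = decay.contact_probability_curve(m, name)
        fit = decay.fit_ide(curve, *config.decay_range)
        fits[name] = {"exponent": fit.exponent, "intercept": fit.intercept, "r2": fit.r2, "n_bands": fit.n_bands}
    with open(out / "decay.json", "w") as fh:
        json.dump(fits, fh, indent=2)
    report["stages"]["decay"] = {"mean_exponent": float(np.mean([f["exponent"] for f in fits.values()]))}

    # --- compartments
    track = _stage(report, "compartments", comp.call_compartments, m, genome.gc, config.compartment_mode)
    io.write_bedgraph(out / "e1.bedgraph", genome, track.e1)
    report["stages"]["compartments"] = {
        "mode": track.mode,
        "n_A": int((track.labels == "A").sum()),
        "n_B": int((track.labels == "B").sum()),
        "n_borders": len(track.borders),
    }

    # --- aggregate (centromeres from Hi-C first)
    cen_table = _stage(report, "centromeres_hic", features.locate_centromeres_hic, m)
    centromeres = dict(zip(cen_table["chrom"], cen_table["midpoint"].astype(float)))
    intra, inter = _stage(report, "aca", agg.aca, m, centromeres, config.n_pseudo)
    scores = agg.cluster_scores(inter, config.aca_window)
    call = agg.classify_configuration(scores)
    np.savetxt(out / "aca_inter.tsv", inter.values, fmt="%.5g", delimiter="\t")
    pair_table = agg.trans_enrichment_by_pair(m)
    pair_table.to_csv(out / "trans_pairs.tsv", sep="\t")
    report["stages"]["aggregate"] = {
        "cc_score": scores.cc_score,
        "tt_score": scores.tt_score,
        "arm_alignment_score": scores.arm_alignment_score,
        "configuration": call,
    }

    # --- insulation
    t = _stage(report, "insulation", insulation.insulation_track, m, config.insulation_window)
    bounds = insulation.detect_boundaries(t, config.boundary_min_strength)
    tad = insulation.assess_tad_presence(
        bounds, genome, config.tad_strength_threshold, compartment_borders=track.borders
    )
    io.write_bedgraph(out / "insulation.bedgraph", genome, t.scores)
    report["stages"]["insulation"] = tad

    # --- repeat-based centromeres + composition
    repeats = tracks.repeats if tracks else (
        features.RepeatAnnotation(io.read_repeat_table(config.repeats)) if config.repeats else None
    )
    if repeats is not None:
        windows = {
            c: (max(0, int(mp) - 200_000), int(mp) + 200_000) for c, mp in centromeres.items()
        }
        fams = features.scan_centromeric_families(repeats, windows)
        if len(fams):
            calls = features.define_centromere_spans(repeats, list(fams["family"]))
            compo = features.centromere_composition(calls, repeats, sequences=sequences)
            compo.to_csv(out / "centromere_composition.tsv", sep="\t", index=False)
            report["stages"]["centromeres"] = {
                "families": list(fams["family"]),
                "n_calls": len(calls),
            }

    # --- telomeres
    if sequences is not None:
        tel = features.telomere_summary(
            sequences, min_copies=config.telomere_min_copies, max_offset=config.telomere_max_offset
        )
        report["stages"]["telomeres"] = {
            "n_resolved_ends": tel["n_resolved_ends"],
            "n_t2t": tel["n_t2t"],
        }

    # --- integration
    peaks = tracks.peaks if tracks else (io.read_peak_table(config.peaks) if config.peaks else None)
    genes = tracks.genes if tracks else (io.read_gene_table(config.genes) if config.genes else None)
    if peaks is not None:
        marks = integrate.mark_enrichment_by_compartment(peaks, track)
        report["stages"]["marks"] = {
            k: {"W": v["W"], "p": v["p"], "median_A": v["median_A"], "median_B": v["median_B"]}
            for k, v in marks.items()
        }
    if genes is not None:
        expr = integrate.expression_by_compartment(genes, track)
        labeled = integrate.classify_sbg(genes)
        report["stages"]["expression"] = {"W": expr["W"], "p": expr["p"]}
        report["stages"]["sbg"] = labeled["sbg_label"].value_counts().to_dict()

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
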