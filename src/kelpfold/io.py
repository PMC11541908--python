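"""Readers and writers for the text formats the pipeline consumes and emits.

Pairs files follow the 4DN convention (1-based positions, ``#`` header
lines, an optional ``#columns:`` line naming the fields); interval tracks
use BED / bedGraph (0-based half-open); matrices travel as COO triplets or
dense TSV; FASTA goes through Biopython.
"""

from __future__ import annotations

import gzip
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GenomeSpec
from .matrix import ContactMatrix


def _open(path, mode="rt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


DEFAULT_PAIRS_COLUMNS = ["readID", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]


def read_pairs(path) -> Iterator[tuple[str, int, str, int]]:
    """Iterate ``(chrom1, pos1, chrom2, pos2)`` from a 4DN pairs file
    (plain or gzip). A ``#columns:`` header line, if present, names the
    fields; positions stay 1-based here and are converted by the binner."""
    cols = list(DEFAULT_PAIRS_COLUMNS)
    with _open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#columns:"):
                    cols = line.split(":", 1)[1].split()
                continue
            parts = line.split("\t")
            rec = dict(zip(cols, parts))
            yield rec["chrom1"], int(rec["pos1"]), rec["chrom2"], int(rec["pos2"])


def write_pairs(path, pairs: Iterable[tuple[str, int, str, int]], genome: GenomeSpec) -> None:
    with _open(path, "wt") as fh:
        fh.write("## pairs format v1.0\n")
        for name, length in genome.chromosomes:
            fh.write(f"#chromsize: {name} {length}\n")
        fh.write("#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2\n")
        for k, (c1, p1, c2, p2) in enumerate(pairs):
            fh.write(f"read{k}\t{c1}\t{p1}\t{c2}\t{p2}\t+\t-\n")


def write_coo(path, m: ContactMatrix) -> None:
    """Upper-triangle COO triplets: bin_i, bin_j (global indices), count."""
    i, j = np.nonzero(np.triu(m.counts))
    with _open(path, "wt") as fh:
        fh.write("# bin_i\tbin_j\tcount\n")
        for a, b in zip(i, j):
            v = m.counts[a, b]
            fh.write(f"{a}\t{b}\t{v:g}\n")


def read_coo(path, genome: GenomeSpec) -> ContactMatrix:
    n = genome.n_bins
    counts = np.zeros((n, n))
    with _open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            a, b, v = line.split()
            a, b, v = int(a), int(b), float(v)
            counts[a, b] += v
            if a != b:
                counts[b, a] += v
    return ContactMatrix(genome, counts)


def write_dense(path, m: ContactMatrix) -> None:
    np.savetxt(path, m.counts, fmt="%g", delimiter="\t")


def read_chrom_sizes(path) -> list[tuple[str, int]]:
    out = []
    with _open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            name, length = line.split()[:2]
            out.append((name, int(length)))
    return out


def write_chrom_sizes(path, genome: GenomeSpec) -> None:
    with _open(path, "wt") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


def write_bedgraph(path, genome: GenomeSpec, values: np.ndarray, na_rep: str | None = None) -> None:
    """Per-bin track as bedGraph; NaN bins are skipped unless ``na_rep``."""
    bins = genome.bins()
    with _open(path, "wt") as fh:
        for (_, row), v in zip(bins.iterrows(), values):
            if np.isnan(v):
                if na_rep is None:
                    continue
                v = na_rep
                fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{v}\n")
                continue
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{v:.6g}\n")


def read_bedgraph(path, genome: GenomeSpec) -> np.ndarray:
    """Per-bin values from a bedGraph whose intervals align to the binning
    (values are averaged over the bins an interval covers)."""
    vals = np.full(genome.n_bins, np.nan)
    wsum = np.zeros(genome.n_bins)
    acc = np.zeros(genome.n_bins)
    bins = genome.bins()
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    with _open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track")) or not line.strip():
                continue
            chrom, start, end, v = line.split()[:4]
            start, end, v = int(start), int(end), float(v)
            b0 = genome.bin_index(chrom, start)
            b1 = genome.bin_index(chrom, end - 1)
            for b in range(b0, b1 + 1):
                lo = max(start, int(starts[b]))
                hi = min(end, int(ends[b]))
                acc[b] += v * (hi - lo)
                wsum[b] += hi - lo
    ok = wsum > 0
    vals[ok] = acc[ok] / wsum[ok]
    return vals


def write_bed(path, intervals: pd.DataFrame, score_col: str | None = None, name_col: str | None = None) -> None:
    with _open(path, "wt") as fh:
        for _, row in intervals.iterrows():
            name = str(row[name_col]) if name_col else "."
            score = f"{row[score_col]:.6g}" if score_col else "."
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{name}\t{score}\n")


def read_bed(path, names=("chrom", "start", "end", "name", "score")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df.columns = list(names)[: df.shape[1]]
    return df


def read_repeat_table(path) -> pd.DataFrame:
    """Repeat annotation TSV with columns chrom, start, end, family, class
    (RepeatMasker-out-derived tables with those columns are accepted)."""
    return pd.read_csv(path, sep="\t", comment="#")


def read_peak_table(path) -> pd.DataFrame:
    """Histone peak TSV: chrom, start, end, mark, fold_enrichment."""
    return pd.read_csv(path, sep="\t", comment="#")


def read_gene_table(path) -> pd.DataFrame:
    """Gene TSV: id, chrom, start, end, TPM columns, log2FC, padj."""
    return pd.read_csv(path, sep="\t", comment="#")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def gc_track_from_fasta(sequences: dict[str, str], genome: GenomeSpec) -> np.ndarray:
    """Per-bin GC fraction computed from sequence."""
    out = np.full(genome.n_bins, np.nan)
    bins = genome.bins()
    for _, row in bins.iterrows():
        seq = sequences.get(row["chrom"])
        if seq is None:
            continue
        sub = seq[row["start"] : row["end"]].upper()
        acgt = sum(sub.count(b) for b in "ACGT")
        if acgt:
            out[row["index"]] = (sub.count("G") + sub.count("C")) / acgt
    return out
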