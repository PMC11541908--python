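"""Genome binning model: chromosomes, fixed-size bins, per-bin tracks.

Coordinates are 0-based half-open (BED convention) throughout. Pairs files
use 1-based positions on disk and are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenomeSpec:
    """An ordered set of chromosomes tiled by fixed-size bins.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` tuples.
    bin_size
        Bin width in bp. The last bin of each chromosome may be short.
    gc
        Optional per-bin GC fraction in [0, 1], aligned to global bin order.
    """

    chromosomes: list[tuple[str, int]]
    bin_size: int
    gc: np.ndarray | None = None

    _offsets: dict[str, int] = field(init=False, repr=False, default_factory=dict)
    _nbins: dict[str, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        lengths = [l for _, l in self.chromosomes]
        if min(lengths) <= 0:
            raise ValueError("chromosome lengths must be positive")
        if not (0 < self.bin_size <= min(lengths)):
            raise ValueError(
                f"bin_size {self.bin_size} must be in (0, min chromosome length {min(lengths)}]"
            )
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        off = 0
        for name, length in self.chromosomes:
            nb = -(-length // self.bin_size)  # ceil
            self._offsets[name] = off
            self._nbins[name] = nb
            off += nb
        if self.gc is not None:
            self.gc = np.asarray(self.gc, dtype=float)
            if self.gc.shape != (off,):
                raise ValueError(f"gc track must have {off} entries, got {self.gc.shape}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def n_bins(self) -> int:
        return sum(self._nbins.values())

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def chrom_nbins(self, name: str) -> int:
        return self._nbins[name]

    def chrom_offset(self, name: str) -> int:
        return self._offsets[name]

    def chrom_slice(self, name: str) -> slice:
        """Global-bin slice covering one chromosome."""
        o = self._offsets[name]
        return slice(o, o + self._nbins[name])

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of a 0-based position."""
        if chrom not in self._offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        length = self.lengths[chrom]
        if not (0 <= pos < length):
            raise ValueError(f"position {pos} outside {chrom} [0, {length})")
        return self._offsets[chrom] + pos // self.bin_size

    def bin_chroms(self) -> np.ndarray:
        """Per-bin chromosome name (object array, global order)."""
        out = np.empty(self.n_bins, dtype=object)
        for name in self.names:
            out[self.chrom_slice(name)] = name
        return out

    def bins(self) -> pd.DataFrame:
        """Bin table: chrom, start, end, global index."""
        rows = []
        for name, length in self.chromosomes:
            starts = np.arange(0, length, self.bin_size)
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        table = pd.concat(rows, ignore_index=True)
        table["index"] = np.arange(len(table))
        return table

    def cis_mask(self) -> np.ndarray:
        """Boolean n_bins x n_bins matrix, True for same-chromosome cells."""
        n = self.n_bins
        out = np.zeros((n, n), dtype=bool)
        for name in self.names:
            s = self.chrom_slice(name)
            out[s, s] = True
        return out

    def same_binning(self, other: "GenomeSpec") -> bool:
        return self.chromosomes == other.chromosomes and self.bin_size == other.bin_size
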