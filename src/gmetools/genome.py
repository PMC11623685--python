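"""Genome coordinate system and fixed-width binning.

All coordinates in this package are 0-based, half-open (BED convention).
Bins are assigned contiguously chromosome by chromosome; the number of bins
on a chromosome is ``ceil(length / bin_size)``, so the last bin may be
shorter than ``bin_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: dm6 (BDGP Release 6) major sequence lengths, bp.
DM6_CHROM_LENGTHS = {
    "2L": 23_513_712,
    "2R": 25_286_936,
    "3L": 28_110_227,
    "3R": 32_079_331,
    "X": 23_542_271,
    "4": 1_348_131,
    "Y": 3_667_352,
}

DEFAULT_BIN_SIZE = 25_000


@dataclass(frozen=True)
class GenomeSpec:
    """Named chromosomes with lengths and a bin size defining a global bin index.

    Parameters
    ----------
    chrom_names
        Ordered chromosome labels.
    chrom_lengths
        Lengths in bp, parallel to ``chrom_names``; all positive.
    bin_size
        Bin width in bp (default 25 kb, the working resolution of the
        analyses in this package).
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int = DEFAULT_BIN_SIZE

    # derived, filled in __post_init__
    _offsets: tuple[int, ...] = field(init=False, repr=False, compare=False, default=())

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(self.chrom_names) == 0:
            raise ValueError("genome must have at least one chromosome")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        offsets = np.concatenate([[0], np.cumsum([self.chrom_nbins(c) for c in self.chrom_names])])
        object.__setattr__(self, "_offsets", tuple(int(x) for x in offsets))

    @classmethod
    def from_dict(cls, lengths: dict[str, int], bin_size: int = DEFAULT_BIN_SIZE) -> "GenomeSpec":
        return cls(tuple(lengths.keys()), tuple(int(v) for v in lengths.values()), bin_size)

    @classmethod
    def dm6(cls, bin_size: int = DEFAULT_BIN_SIZE) -> "GenomeSpec":
        """The seven major dm6 sequences at the given bin size."""
        return cls.from_dict(DM6_CHROM_LENGTHS, bin_size)

    # -- chromosome-level queries -------------------------------------------------

    def chrom_length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def chrom_nbins(self, chrom: str) -> int:
        length = self.chrom_length(chrom)
        return -(-length // self.bin_size)  # ceil division

    def chrom_offset(self, chrom: str) -> int:
        """Global bin id of the first bin of *chrom*."""
        return self._offsets[self.chrom_names.index(chrom)]

    @property
    def n_bins(self) -> int:
        """Total number of bins across the genome."""
        return self._offsets[-1]

    # -- bin id arithmetic --------------------------------------------------------

    def bin_id(self, chrom: str, pos: int) -> int:
        """Global bin id containing base position *pos* on *chrom*."""
        if not 0 <= pos < self.chrom_length(chrom):
            raise ValueError(f"position {pos} outside {chrom} (length {self.chrom_length(chrom)})")
        return self.chrom_offset(chrom) + pos // self.bin_size

    def bin_range(self, chrom: str, start: int, end: int) -> range:
        """Global bin ids overlapped by the half-open interval [start, end)."""
        if not (0 <= start < end <= self.chrom_length(chrom)):
            raise ValueError(f"[{start}, {end}) outside {chrom}")
        off = self.chrom_offset(chrom)
        return range(off + start // self.bin_size, off + (end - 1) // self.bin_size + 1)

    def bin_location(self, bin_id: int) -> tuple[str, int, int]:
        """(chrom, start, end) of a global bin id."""
        if not 0 <= bin_id < self.n_bins:
            raise ValueError(f"bin id {bin_id} out of range")
        ci = int(np.searchsorted(self._offsets, bin_id, side="right")) - 1
        chrom = self.chrom_names[ci]
        local = bin_id - self._offsets[ci]
        start = local * self.bin_size
        return chrom, start, min(start + self.bin_size, self.chrom_length(chrom))

    def bin_chrom_index(self, bin_ids: np.ndarray) -> np.ndarray:
        """Vectorised chromosome index for an array of global bin ids."""
        return np.searchsorted(self._offsets, np.asarray(bin_ids), side="right") - 1

    def chrom_slice(self, chrom: str) -> slice:
        ci = self.chrom_names.index(chrom)
        return slice(self._offsets[ci], self._offsets[ci + 1])
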