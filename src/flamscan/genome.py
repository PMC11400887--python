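"""Contig sets, fixed-size bin grids and NX assembly statistics.

The coordinate universe for the whole pipeline: contigs are read from a
FASTA, a ``.fai`` index or a two-column ``chrom.sizes`` file, tiled into
fixed-size bins (BED convention, 0-based half-open), and optionally
filtered by the NX assembly-quality metric (e.g. N90) before evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ContigSet",
    "BinGrid",
    "read_contig_lengths",
    "make_bins",
    "compute_nx",
    "filter_contigs_by_nx",
]


@dataclass(frozen=True)
class ContigSet:
    """Ordered set of named contigs with lengths in bp.

    Order is preserved from the input and is deterministic; names must be
    unique and lengths at least 1 bp.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        seen: set[str] = set()
        for name in self.names:
            if name in seen:
                raise ValueError(f"duplicate contig name: {name!r}")
            seen.add(name)
        for name, length in zip(self.names, self.lengths):
            if int(length) < 1:
                raise ValueError(f"contig {name!r} has non-positive length {length}")

    @classmethod
    def from_entries(cls, entries: Iterable[tuple[str, int]]) -> "ContigSet":
        entries = list(entries)
        return cls(
            names=tuple(name for name, _ in entries),
            lengths=tuple(int(length) for _, length in entries),
        )

    @property
    def entries(self) -> list[tuple[str, int]]:
        return list(zip(self.names, self.lengths))

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def length_of(self, name: str) -> int:
        try:
            return self.lengths[self.names.index(name)]
        except ValueError:
            raise KeyError(f"unknown contig: {name!r}") from None

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.entries)


@dataclass(frozen=True)
class BinGrid:
    """Fixed-size tiling of a :class:`ContigSet`, 0-based half-open.

    Within each contig, bins are consecutive and non-overlapping, start at
    0 and step by ``bin_size``; the trailing bin is truncated at the contig
    end (its true width is used later for coverage normalisation).

    Attributes
    ----------
    contigs : ContigSet
        The tiled contigs, in input order.
    bin_size : int
        Nominal bin width in bp.
    contig_index, starts, ends : np.ndarray
        Per-bin arrays; ``contig_index`` maps into ``contigs.names``.
    """

    contigs: ContigSet
    bin_size: int
    contig_index: np.ndarray = field(repr=False)
    starts: np.ndarray = field(repr=False)
    ends: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    def contig_slice(self, name: str) -> slice:
        """Slice of the bin arrays covering one contig."""
        idx = self.contigs.names.index(name)
        lo, hi = np.searchsorted(self.contig_index, [idx, idx + 1])
        return slice(int(lo), int(hi))

    def iter_contig_slices(self) -> Iterator[tuple[str, slice]]:
        for name in self.contigs.names:
            yield name, self.contig_slice(name)

    def segment_lengths(self) -> list[int]:
        """Number of bins per contig, in contig order."""
        return [sl.stop - sl.start for _, sl in self.iter_contig_slices()]

    def to_bed(self, path: str | Path) -> None:
        """Write the grid as BED3."""
        with open(path, "w") as fh:
            for ci, s, e in zip(self.contig_index, self.starts, self.ends):
                fh.write(f"{self.contigs.names[ci]}\t{s}\t{e}\n")


def _parse_sizes_table(path: Path, min_columns: int) -> ContigSet:
    entries: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < min_columns:
                raise ValueError(f"{path}, line {lineno}: expected at least "
                                 f"{min_columns} tab-separated columns")
            name = fields[0]
            if name in seen:
                raise ValueError(f"{path}, line {lineno}: duplicate contig name {name!r}")
            seen.add(name)
            try:
                length = int(fields[1])
            except ValueError:
                raise ValueError(
                    f"{path}, line {lineno}: non-integer length {fields[1]!r}"
                ) from None
            entries.append((name, length))
    return ContigSet.from_entries(entries)


def _read_fasta_lengths(path: Path) -> ContigSet:
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    entries: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            name = header.split()[0]
            if name in seen:
                raise ValueError(f"{path}: duplicate contig name {name!r}")
            seen.add(name)
            entries.append((name, len(seq)))
    return ContigSet.from_entries(entries)


def read_contig_lengths(path: str | Path, format: str | None = None) -> ContigSet:
    """Read contig names and lengths from ``fai``, ``chrom.sizes`` or ``fasta``.

    ``fai`` and ``chrom.sizes`` are tab-separated with name and length in the
    first two columns; FASTA files are scanned record by record. When
    ``format`` is None it is inferred from the file extension. No filtering
    is applied; input order is kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix == ".fai":
            format = "fai"
        elif suffix in {".fa", ".fasta", ".fna"}:
            format = "fasta"
        else:
            format = "chrom.sizes"
    if format == "fai":
        return _parse_sizes_table(path, min_columns=2)
    if format in {"chrom.sizes", "sizes"}:
        return _parse_sizes_table(path, min_columns=2)
    if format == "fasta":
        return _read_fasta_lengths(path)
    raise ValueError(f"unknown contig-length format: {format!r}")


def make_bins(contigs: ContigSet, bin_size: int) -> BinGrid:
    """Tile every contig into consecutive ``bin_size`` windows.

    Produces ``ceil(length / bin_size)`` bins per contig; the last bin is
    truncated at the contig end. Equivalent to ``bedtools makewindows``.
    """
    bin_size = int(bin_size)
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    contig_index: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    for idx, (name, length) in enumerate(contigs):
        n = -(-length // bin_size)  # ceil
        s = np.arange(n, dtype=np.int64) * bin_size
        e = np.minimum(s + bin_size, length)
        contig_index.append(np.full(n, idx, dtype=np.int64))
        starts.append(s)
        ends.append(e)
    return BinGrid(
        contigs=contigs,
        bin_size=bin_size,
        contig_index=np.concatenate(contig_index) if contig_index else np.empty(0, np.int64),
        starts=np.concatenate(starts) if starts else np.empty(0, np.int64),
        ends=np.concatenate(ends) if ends else np.empty(0, np.int64),
    )


def compute_nx(contigs: ContigSet, x: float) -> int:
    """NX assembly statistic (e.g. N50, N90).

    The length of the shortest contig such that contigs of that length or
    longer cover at least ``x`` percent of the total assembly length. Ties
    are resolved by including all contigs of equal length in the cumulative
    sum before testing the threshold.
    """
    if not 0 < x <= 100:
        raise ValueError(f"x must be in (0, 100], got {x}")
    if len(contigs) == 0:
        raise ValueError("cannot compute NX of an empty contig set")
    lengths = np.sort(np.asarray(contigs.lengths, dtype=np.int64))[::-1]
    total = lengths.sum()
    # tiny slack keeps integer cumulative sums that hit x% exactly from
    # failing on floating-point rounding of the target
    target = x * float(total) / 100.0 - 1e-6
    cum = 0
    i = 0
    n = len(lengths)
    while i < n:
        # consume the whole block of equal lengths before testing
        j = i
        while j < n and lengths[j] == lengths[i]:
            cum += lengths[j]
            j += 1
        if cum >= target:
            return int(lengths[i])
        i = j
    return int(lengths[-1])  # unreachable for x <= 100


def filter_contigs_by_nx(contigs: ContigSet, x: float) -> ContigSet:
    """Retain contigs whose length is at least ``compute_nx(contigs, x)``.

    ``x=100`` retains every contig (N100 is the minimum contig length).
    """
    threshold = compute_nx(contigs, x)
    kept = [(n, l) for n, l in contigs if l >= threshold]
    logger.debug("NX filter (x=%s): kept %d of %d contigs", x, len(kept), len(contigs))
    return ContigSet.from_entries(kept)
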