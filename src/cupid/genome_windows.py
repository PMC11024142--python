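"""Fixed-width genome tiling, CpG annotation, and over-represented window masking."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

GenomeLike = Union[str, Path, Mapping[str, Union[int, str]]]


@dataclass
class WindowSet:
    """Ordered, non-overlapping fixed-width genome tiles.

    Window ids are the row positions (0..n-1), contiguous and unique.
    Coordinates are 0-based half-open throughout.
    """

    chrom: np.ndarray  # per-window chromosome name
    start: np.ndarray
    end: np.ndarray
    cpg_count: np.ndarray
    window_size: int
    has_cpg_densities: bool = True
    masked: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.masked is None:
            self.masked = np.zeros(len(self.start), dtype=bool)
        self._validate()
        # chrom -> (first window id, chromosome length) for midpoint lookup
        self._chrom_offsets: dict[str, tuple[int, int]] = {}
        for name in pd.unique(self.chrom):
            idx = np.flatnonzero(self.chrom == name)
            self._chrom_offsets[str(name)] = (int(idx[0]), int(self.end[idx[-1]]))

    def _validate(self) -> None:
        n = len(self.start)
        if not (len(self.end) == len(self.chrom) == len(self.cpg_count) == n):
            raise ValueError("window arrays must have equal length")
        if np.any(self.end <= self.start):
            raise ValueError("windows must have end > start")
        if np.any(self.cpg_count < 0):
            raise ValueError("cpg_count must be non-negative")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def window_ids(self) -> np.ndarray:
        return np.arange(len(self), dtype=np.int64)

    @property
    def chroms(self) -> list[str]:
        return list(self._chrom_offsets)

    def locate(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Map genomic point coordinates to window ids (-1 for unknown chrom
        or out-of-range positions)."""
        out = np.full(len(pos), -1, dtype=np.int64)
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        for name, (offset, length) in self._chrom_offsets.items():
            sel = (chrom == name) & (pos >= 0) & (pos < length)
            out[sel] = offset + pos[sel] // self.window_size
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "window_id": self.window_ids,
                "cpg_count": self.cpg_count,
                "masked": self.masked,
            }
        )


@dataclass
class MaskReport:
    """Outcome of the over-represented window rule."""

    primary_masked: set[int]
    adjacent_masked: set[int]
    q999: float
    q99: float

    @property
    def all_masked(self) -> set[int]:
        return self.primary_masked | self.adjacent_masked


def count_cpgs(sequence: str) -> int:
    """Count CG dinucleotides on the forward strand, case-insensitively."""
    return sequence.upper().count("CG")


def _windows_for_length(length: int, window_size: int) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, length, window_size, dtype=np.int64)
    ends = np.minimum(starts + window_size, length)
    return starts, ends


def tile_genome(genome: GenomeLike, window_size: int = 300) -> WindowSet:
    """Tile a genome into non-overlapping ``window_size``-bp windows.

    Parameters
    ----------
    genome
        Either a FASTA path (CpG counts computed from sequence), a mapping
        of chromosome name to sequence string, or a mapping of chromosome
        name to integer length (CpG counts set to 0 and flagged absent).
    window_size
        Window width in bp; the final window on each chromosome may be
        shorter.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")

    sequences: dict[str, str] | None = None
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(genome), as_raw=True, sequence_always_upper=True)
        sequences = {name: str(fa[name][:]) for name in fa.keys()}
        lengths = {name: len(seq) for name, seq in sequences.items()}
    else:
        # mapping, or sequence of (name, length|sequence) pairs
        items = list(genome.items()) if hasattr(genome, "items") else list(genome)
        names = [k for k, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        first = items[0][1] if items else None
        if isinstance(first, str):
            sequences = {k: v for k, v in items}  # type: ignore[misc]
            lengths = {k: len(v) for k, v in sequences.items()}
        else:
            lengths = {k: int(v) for k, v in items}  # type: ignore[arg-type]

    if not lengths:
        raise ValueError("empty genome")
    for name, length in lengths.items():
        if length < 1:
            raise ValueError(f"chromosome {name!r} has length < 1")

    chroms, starts, ends, cpgs = [], [], [], []
    for name, length in lengths.items():
        s, e = _windows_for_length(length, window_size)
        chroms.extend([name] * len(s))
        starts.append(s)
        ends.append(e)
        if sequences is not None:
            seq = sequences[name]
            cpgs.append(
                np.array([count_cpgs(seq[a:b]) for a, b in zip(s, e)], dtype=np.int64)
            )
        else:
            cpgs.append(np.zeros(len(s), dtype=np.int64))

    return WindowSet(
        chrom=np.array(chroms, dtype=object),
        start=np.concatenate(starts),
        end=np.concatenate(ends),
        cpg_count=np.concatenate(cpgs),
        window_size=window_size,
        has_cpg_densities=sequences is not None,
    )


def find_overrepresented(
    counts: np.ndarray,
    windows: WindowSet,
    primary_quantile: float = 0.999,
    adjacent_quantile: float = 0.99,
) -> MaskReport:
    """Mask windows whose pooled control counts are extreme outliers.

    Windows at or above the ``primary_quantile`` empirical quantile are
    primary-masked; unmasked immediate neighbours (same chromosome) at or
    above the ``adjacent_quantile`` quantile are adjacent-masked. The rule
    targets outliers, so in the degenerate case where the primary threshold
    equals the median (near-uniform counts) nothing is masked.
    """
    counts = np.asarray(counts, dtype=float)
    if len(counts) != len(windows):
        raise ValueError("counts must align with the WindowSet")

    if np.all(counts == 0):
        warnings.warn("all pooled counts are zero; no windows masked", stacklevel=2)
        report = MaskReport(set(), set(), 0.0, 0.0)
        windows.masked[:] = False
        return report

    q999 = float(np.quantile(counts, primary_quantile))
    q99 = float(np.quantile(counts, adjacent_quantile))

    if q999 == float(np.median(counts)):
        report = MaskReport(set(), set(), q999, q99)
        windows.masked[:] = False
        return report

    primary = counts >= q999
    adjacent = np.zeros(len(counts), dtype=bool)
    same_chrom_next = windows.chrom[:-1] == windows.chrom[1:]
    # neighbour to the right of a primary window
    right = np.zeros(len(counts), dtype=bool)
    right[1:] = primary[:-1] & same_chrom_next
    left = np.zeros(len(counts), dtype=bool)
    left[:-1] = primary[1:] & same_chrom_next
    adjacent = (right | left) & ~primary & (counts >= q99)

    windows.masked[:] = primary | adjacent
    return MaskReport(
        primary_masked=set(np.flatnonzero(primary).tolist()),
        adjacent_masked=set(np.flatnonzero(adjacent).tolist()),
        q999=q999,
        q99=q99,
    )


def density_strata(windows: WindowSet, cap_quantile: float = 0.99) -> np.ndarray:
    """Per-window CpG-density stratum: raw CpG count capped at the
    ``cap_quantile`` quantile (pooling rare very dense windows)."""
    cap = int(np.quantile(windows.cpg_count, cap_quantile))
    return np.minimum(windows.cpg_count, cap).astype(np.int64)


def write_bed(windows: WindowSet, path: str | Path) -> None:
    """Write windows as BED6 (name=window_id, score=cpg_count)."""
    df = windows.to_frame()
    out = df[["chrom", "start", "end"]].copy()
    out["name"] = df["window_id"]
    out["score"] = df["cpg_count"]
    out["strand"] = "."
    out.to_csv(path, sep="\t", header=False, index=False)
    mask_path = Path(str(path) + ".mask.tsv")
    df[["window_id", "masked"]].to_csv(mask_path, sep="\t", index=False)


def read_bed(path: str | Path, window_size: int | None = None) -> WindowSet:
    """Read a WindowSet from BED6 written by :func:`write_bed`."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    if window_size is None:
        window_size = int((df["end"] - df["start"]).max())
    ws = WindowSet(
        chrom=df["chrom"].to_numpy(dtype=object),
        start=df["start"].to_numpy(np.int64),
        end=df["end"].to_numpy(np.int64),
        cpg_count=df["score"].to_numpy(np.int64),
        window_size=window_size,
    )
    mask_path = Path(str(path) + ".mask.tsv")
    if mask_path.exists():
        mask = pd.read_csv(mask_path, sep="\t")
        ws.masked[:] = mask["masked"].to_numpy(bool)
    return ws
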