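"""Enrichment QC: relative CpG enrichment (relH), hyperstable fraction, gating."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cupid.fragment_counts import BetaMatrix
from cupid.genome_windows import WindowSet


@dataclass
class GenomeCpGIndex:
    """Sorted CpG start positions per chromosome plus genome-wide totals.

    A CpG at position p occupies bases [p, p+2); it lies inside a fragment
    footprint [start, end) only when both bases do, i.e. p <= end - 2.
    """

    cpg_positions: dict[str, np.ndarray]
    total_length: int
    total_cpgs: int

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "GenomeCpGIndex":
        positions: dict[str, np.ndarray] = {}
        total_length = 0
        total_cpgs = 0
        for chrom, seq in sequences.items():
            s = seq.upper()
            total_length += len(s)
            pos = []
            i = s.find("CG")
            while i != -1:
                pos.append(i)
                i = s.find("CG", i + 1)
            arr = np.asarray(pos, dtype=np.int64)
            positions[chrom] = arr
            total_cpgs += len(arr)
        return cls(positions, total_length, total_cpgs)

    def count_in(self, chrom: str, start: int, end: int) -> int:
        pos = self.cpg_positions.get(chrom)
        if pos is None or end - start < 2:
            return 0
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end - 2, side="right")
        return int(hi - lo)


@dataclass
class QCResult:
    sample_id: str
    relh: float
    hyperstable_fraction: float
    n_valid_fragments: int
    passed: bool = False


@dataclass
class HyperstablePanel:
    """Window ids designated as consistently hypermethylated across tissues."""

    window_ids: np.ndarray

    def __post_init__(self) -> None:
        self.window_ids = np.asarray(self.window_ids, dtype=np.int64)
        if len(self.window_ids) == 0:
            raise ValueError("hyperstable panel must be non-empty")

    def validate(self, windows: WindowSet) -> None:
        if self.window_ids.min() < 0 or self.window_ids.max() >= len(windows):
            raise ValueError("panel window ids outside the WindowSet")


def relh(fragments: pd.DataFrame, genome: GenomeCpGIndex) -> float:
    """Relative CpG enrichment of fragment footprints.

    (CpGs inside fragment footprints / footprint bases) divided by the
    genome-wide CpG density. Overlapping fragments contribute
    independently, per fragment.
    """
    if genome.total_cpgs == 0 or genome.total_length == 0:
        raise ValueError("genome CpG index is empty")
    starts = fragments["start"].to_numpy(np.int64)
    ends = fragments["end"].to_numpy(np.int64)
    chroms = fragments["chrom"].to_numpy(object)
    footprint = int((ends - starts).sum())
    if footprint == 0:
        raise ValueError("zero footprint bases; cannot compute relH")
    n_cpg = 0
    for chrom in pd.unique(chroms):
        pos = genome.cpg_positions.get(str(chrom))
        if pos is None or len(pos) == 0:
            continue
        sel = chroms == chrom
        lo = np.searchsorted(pos, starts[sel], side="left")
        hi = np.searchsorted(pos, ends[sel] - 2, side="right")
        n_cpg += int(np.maximum(hi - lo, 0).sum())
    fragment_density = n_cpg / footprint
    genome_density = genome.total_cpgs / genome.total_length
    return fragment_density / genome_density


def hyperstable_fraction(
    beta_row: pd.Series,
    panel: HyperstablePanel,
    beta_min: float = 0.8,
) -> float:
    """Fraction of panel windows with beta >= ``beta_min``.

    Panel windows with missing beta count as below the threshold.
    """
    vals = beta_row.reindex(panel.window_ids)
    return float((vals >= beta_min).sum() / len(panel.window_ids))


def qc_sample(
    sample_id: str,
    fragments: pd.DataFrame,
    genome: GenomeCpGIndex,
    beta_row: pd.Series,
    panel: HyperstablePanel,
) -> QCResult:
    return QCResult(
        sample_id=sample_id,
        relh=relh(fragments, genome),
        hyperstable_fraction=hyperstable_fraction(beta_row, panel),
        n_valid_fragments=len(fragments),
    )


def gate_samples(
    qc: Sequence[QCResult],
    relh_min: float = 2.5,
    hf_min: float = 0.4,
) -> pd.DataFrame:
    """Partition samples into pass/fail.

    A sample passes iff relH >= ``relh_min`` AND hyperstable fraction >=
    ``hf_min`` — values exactly at a threshold pass (only values *below*
    are excluded).
    """
    rows = []
    for r in qc:
        r.passed = bool(r.relh >= relh_min and r.hyperstable_fraction >= hf_min)
        rows.append(
            {
                "sample_id": r.sample_id,
                "relH": r.relh,
                "hyperstable_fraction": r.hyperstable_fraction,
                "n_valid_fragments": r.n_valid_fragments,
                "pass": r.passed,
            }
        )
    return pd.DataFrame(rows)


def read_panel(path: str | Path) -> HyperstablePanel:
    """Read a hyperstable panel from BED (name column = window_id)."""
    df = pd.read_csv(path, sep="\t", header=None)
    return HyperstablePanel(window_ids=df[3].to_numpy(np.int64))


def write_panel(panel: HyperstablePanel, windows: WindowSet, path: str | Path) -> None:
    ids = panel.window_ids
    pd.DataFrame(
        {
            "chrom": windows.chrom[ids],
            "start": windows.start[ids],
            "end": windows.end[ids],
            "name": ids,
        }
    ).to_csv(path, sep="\t", header=False, index=False)
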