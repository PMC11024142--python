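"""Fragment filtering, midpoint window assignment, NRPM and calibrated beta views."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from cupid.genome_windows import WindowSet, density_strata

FRAGMENT_COLUMNS = ["chrom", "start", "end", "mapq1", "mapq2"]


@dataclass
class FilterTally:
    """Per-rule rejection bookkeeping from :func:`filter_fragments`."""

    n_input: int = 0
    n_retained: int = 0
    rejected_mapq: int = 0
    rejected_length: int = 0
    rejected_span: int = 0
    malformed: int = 0


@dataclass
class CountMatrix:
    """Samples x windows fragment counts on a shared WindowSet.

    ``valid_totals`` is the number of retained fragments per sample — it
    describes the library, so fragments landing in masked windows still
    count toward it even though masked windows are dropped from NRPM/beta
    views. ``cnv_factor`` is a per-sample per-window copy-ratio (1.0 means
    diploid/no correction).
    """

    sample_ids: list[str]
    counts: np.ndarray  # (n_samples, n_windows) int64
    valid_totals: np.ndarray  # (n_samples,)
    cnv_factor: np.ndarray | None = None  # (n_samples, n_windows) or None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.sample_ids):
            raise ValueError("counts must be (n_samples, n_windows)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.valid_totals = np.asarray(self.valid_totals, dtype=np.int64)
        if self.cnv_factor is not None:
            self.cnv_factor = np.asarray(self.cnv_factor, dtype=float)
            if np.any(self.cnv_factor <= 0):
                raise ValueError("cnv_factor must be positive")

    @property
    def n_windows(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts.T, columns=self.sample_ids)
        df.insert(0, "window_id", np.arange(self.n_windows))
        return df


@dataclass
class BetaMatrix:
    """Per-window methylation level in [0,1]; NaN marks missing."""

    sample_ids: list[str]
    window_ids: np.ndarray
    beta: np.ndarray  # (n_samples, n_windows)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.window_ids = np.asarray(self.window_ids, dtype=np.int64)
        finite = self.beta[np.isfinite(self.beta)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0,1]")

    def row(self, sample_id: str) -> pd.Series:
        i = self.sample_ids.index(sample_id)
        return pd.Series(self.beta[i], index=self.window_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.beta.T, columns=self.sample_ids)
        df.insert(0, "window_id", self.window_ids)
        return df


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Read a BED-like fragment table (chrom, start, end, mapq1, mapq2)."""
    return pd.read_csv(path, sep="\t", header=None, names=FRAGMENT_COLUMNS, comment="#")


def filter_fragments(
    fragments: pd.DataFrame,
    min_mapq: int = 10,
    len_range: tuple[int, int] = (90, 1000),
    min_span: int = 30,
) -> tuple[pd.DataFrame, FilterTally]:
    """Retain fragments where either mate maps with MAPQ >= ``min_mapq``,
    the reference span lies inside ``len_range`` (inclusive) and is at
    least ``min_span`` bp.

    Malformed rows (non-numeric coordinates, end <= start) are dropped and
    tallied rather than raised.
    """
    tally = FilterTally(n_input=len(fragments))
    df = fragments.copy()
    for col in ("start", "end", "mapq1", "mapq2"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    well_formed = df[["start", "end", "mapq1", "mapq2"]].notna().all(axis=1)
    well_formed &= df["end"] > df["start"]
    tally.malformed = int((~well_formed).sum())
    df = df[well_formed]

    length = df["end"] - df["start"]
    mapq_ok = np.maximum(df["mapq1"], df["mapq2"]) >= min_mapq
    length_ok = (length >= len_range[0]) & (length <= len_range[1])
    span_ok = length >= min_span

    tally.rejected_mapq = int((~mapq_ok).sum())
    tally.rejected_length = int((mapq_ok & ~length_ok).sum())
    tally.rejected_span = int((mapq_ok & length_ok & ~span_ok).sum())

    kept = df[mapq_ok & length_ok & span_ok]
    tally.n_retained = len(kept)
    out = kept.astype({"start": np.int64, "end": np.int64, "mapq1": np.int64, "mapq2": np.int64})
    return out, tally


def assign_counts(
    fragments_by_sample: Mapping[str, pd.DataFrame],
    windows: WindowSet,
) -> CountMatrix:
    """Count filtered fragments into windows by their midpoint.

    The midpoint is floor((start+end)/2); each fragment increments exactly
    one window. Fragments on chromosomes absent from the WindowSet are
    skipped with a warning tally.
    """
    n_w = len(windows)
    sample_ids = list(fragments_by_sample)
    counts = np.zeros((len(sample_ids), n_w), dtype=np.int64)
    totals = np.zeros(len(sample_ids), dtype=np.int64)
    skipped = 0
    for i, sid in enumerate(sample_ids):
        df = fragments_by_sample[sid]
        totals[i] = len(df)
        if len(df) == 0:
            continue
        mid = (df["start"].to_numpy(np.int64) + df["end"].to_numpy(np.int64)) // 2
        wid = windows.locate(df["chrom"].to_numpy(object), mid)
        hit = wid >= 0
        skipped += int((~hit).sum())
        np.add.at(counts[i], wid[hit], 1)
        totals[i] = int(hit.sum())
    if skipped:
        warnings.warn(f"{skipped} fragments on chromosomes absent from the WindowSet", stacklevel=2)
    return CountMatrix(sample_ids=sample_ids, counts=counts, valid_totals=totals)


def nrpm(cm: CountMatrix, windows: WindowSet | None = None) -> np.ndarray:
    """Normalised reads per million: counts / valid_total * 1e6 / cnv_factor.

    Masked windows (when a WindowSet is given) are emitted as NaN.
    """
    zero = cm.valid_totals == 0
    if np.any(zero):
        bad = [cm.sample_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"samples with zero valid fragments: {bad}")
    out = cm.counts / cm.valid_totals[:, None] * 1e6
    if cm.cnv_factor is not None:
        out = out / cm.cnv_factor
    if windows is not None and np.any(windows.masked):
        out[:, windows.masked] = np.nan
    return out


def _stratum_saturation(
    values: np.ndarray,
    strata: np.ndarray,
    saturation_quantile: float,
    min_support: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-stratum high quantile of NRPM, isotonic-smoothed in density.

    Returns (stratum levels, saturation per level). Strata with fewer than
    ``min_support`` windows are filled by interpolation from neighbours.
    """
    levels = np.unique(strata)
    raw = np.full(len(levels), np.nan)
    for k, d in enumerate(levels):
        vals = values[(strata == d) & np.isfinite(values)]
        if len(vals) >= min_support:
            raw[k] = np.quantile(vals, saturation_quantile)
    known = np.isfinite(raw)
    if not known.any():
        raise ValueError("no density stratum has enough windows for calibration")
    raw = np.interp(levels.astype(float), levels[known].astype(float), raw[known])
    iso = IsotonicRegression(increasing=True)
    smooth = iso.fit_transform(levels.astype(float), raw)
    return levels, smooth


def calibrate_beta(
    nrpm_matrix: np.ndarray,
    windows: WindowSet,
    sample_ids: list[str] | None = None,
    saturation_quantile: float = 0.9,
    min_stratum_support: int = 10,
) -> BetaMatrix:
    """Blind-calibrate NRPM into per-window beta values.

    Per sample, a background level B is the median NRPM of CpG-free
    windows and a saturation level M_d per CpG-density stratum d is a high
    quantile of NRPM within the stratum (windows presumed fully
    methylated), smoothed to be non-decreasing in d. Then
    beta = clip((nrpm - B) / (M_d - B), 0, 1). Windows with no CpGs, with
    M_d <= B, or masked are missing (NaN).
    """
    if not windows.has_cpg_densities:
        raise ValueError("calibration requires CpG densities on the WindowSet")
    X = np.atleast_2d(np.asarray(nrpm_matrix, dtype=float))
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(X.shape[0])]
    strata = density_strata(windows)
    cpg_free = (windows.cpg_count == 0) & ~windows.masked
    usable = ~windows.masked

    beta = np.full_like(X, np.nan)
    for i in range(X.shape[0]):
        row = X[i]
        if cpg_free.any():
            bg_vals = row[cpg_free & np.isfinite(row)]
            B = float(np.median(bg_vals)) if bg_vals.size else 0.0
        else:
            warnings.warn("no CpG-free windows; background set to 0", stacklevel=2)
            B = 0.0
        sel = usable & (windows.cpg_count > 0) & np.isfinite(row)
        levels, sat = _stratum_saturation(
            row[sel], strata[sel], saturation_quantile, min_stratum_support
        )
        m_d = np.interp(strata.astype(float), levels.astype(float), sat)
        denom = m_d - B
        ok = sel & (denom > 0)
        beta[i, ok] = np.clip((row[ok] - B) / denom[ok], 0.0, 1.0)
    return BetaMatrix(sample_ids=sample_ids, window_ids=windows.window_ids, beta=beta)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index=False)
    totals = pd.DataFrame({"sample_id": cm.sample_ids, "valid_total": cm.valid_totals})
    totals.to_csv(Path(str(path) + ".totals.tsv"), sep="\t", index=False)


def read_count_matrix(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t")
    sample_ids = [c for c in df.columns if c != "window_id"]
    counts = df[sample_ids].to_numpy(np.int64).T
    totals_path = Path(str(path) + ".totals.tsv")
    if totals_path.exists():
        totals = pd.read_csv(totals_path, sep="\t").set_index("sample_id")
        valid_totals = totals.loc[sample_ids, "valid_total"].to_numpy(np.int64)
    else:
        valid_totals = counts.sum(axis=1)
    return CountMatrix(sample_ids=sample_ids, counts=counts, valid_totals=valid_totals)
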