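"""Class regrouping of methylation arrays and beta -> pseudo-count conversion.

Array probes carry point beta-values; converting them into enrichment-seq
style counts requires a lookup of the expected NRPM for a given
(CpG-density stratum, beta) combination, learned from pooled non-cancer
control (NCC) enrichment profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from cupid.fragment_counts import BetaMatrix, CountMatrix, nrpm
from cupid.genome_windows import WindowSet, density_strata

logger = logging.getLogger(__name__)

BETA_GRID_STEP = 0.01


@dataclass
class ClassMap:
    """Mapping from source cohort/histology labels to classifier classes."""

    table: pd.DataFrame  # columns: source_label, cupid_class, excluded, reason

    def __post_init__(self) -> None:
        required = {"source_label", "cupid_class", "excluded"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"class map needs columns {sorted(required)}")
        if "reason" not in self.table.columns:
            self.table = self.table.assign(reason="")

    @classmethod
    def default(cls) -> "ClassMap":
        """The shipped 30-class regrouping configuration."""
        with resources.files("cupid.config").joinpath("class_map.tsv").open() as fh:
            return cls(pd.read_csv(fh, sep="\t").fillna(""))

    @classmethod
    def read(cls, path: str | Path) -> "ClassMap":
        return cls(pd.read_csv(path, sep="\t").fillna(""))

    @property
    def classes(self) -> list[str]:
        keep = self.table[self.table["excluded"].astype(int) == 0]
        return sorted(keep["cupid_class"].unique())

    def lookup(self, source_label: str) -> tuple[str | None, str]:
        row = self.table[self.table["source_label"] == source_label]
        if row.empty:
            raise KeyError(source_label)
        row = row.iloc[0]
        if int(row["excluded"]):
            return None, str(row.get("reason", ""))
        return str(row["cupid_class"]), ""


@dataclass
class ArrayBetaSet:
    """Methylation-array betas: probes (point coordinates) x samples."""

    sample_ids: list[str]
    labels: list[str]  # source label or classifier class per sample
    probe_chrom: np.ndarray
    probe_pos: np.ndarray
    beta: np.ndarray  # (n_probes, n_samples)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.probe_pos), len(self.sample_ids)):
            raise ValueError("beta must be (n_probes, n_samples)")
        finite = self.beta[np.isfinite(self.beta)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("array betas must lie in [0,1]")

    def subset_samples(self, keep: np.ndarray, labels: list[str]) -> "ArrayBetaSet":
        return ArrayBetaSet(
            sample_ids=[self.sample_ids[i] for i in np.flatnonzero(keep)],
            labels=labels,
            probe_chrom=self.probe_chrom,
            probe_pos=self.probe_pos,
            beta=self.beta[:, keep],
        )


@dataclass
class CalibrationTable:
    """Expected NRPM per (CpG-density stratum, beta) cell.

    ``expected_nrpm[k, j]`` is the expected NRPM for stratum
    ``strata[k]`` at beta ``beta_grid[j]``; non-decreasing in beta within
    each stratum.
    """

    strata: np.ndarray  # sorted unique density levels
    beta_grid: np.ndarray  # 0, 0.01, ..., 1
    expected_nrpm: np.ndarray  # (n_strata, n_beta)

    def __post_init__(self) -> None:
        if self.expected_nrpm.shape != (len(self.strata), len(self.beta_grid)):
            raise ValueError("expected_nrpm shape mismatch")
        if np.any(self.expected_nrpm < 0):
            raise ValueError("expected_nrpm must be non-negative")

    def rate(self, stratum: np.ndarray, beta: np.ndarray) -> np.ndarray:
        """Expected NRPM for vectors of window strata and betas."""
        k = np.searchsorted(self.strata, np.minimum(stratum, self.strata[-1]))
        k = np.clip(k, 0, len(self.strata) - 1)
        j = np.clip(np.round(np.asarray(beta) / BETA_GRID_STEP).astype(int), 0, len(self.beta_grid) - 1)
        return self.expected_nrpm[k, j]

    def to_frame(self) -> pd.DataFrame:
        d, b = np.meshgrid(self.strata, self.beta_grid, indexing="ij")
        return pd.DataFrame(
            {"cpg_stratum": d.ravel(), "beta": b.ravel(), "expected_nrpm": self.expected_nrpm.ravel()}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "CalibrationTable":
        df = pd.read_csv(path, sep="\t")
        strata = np.sort(df["cpg_stratum"].unique())
        grid = np.sort(df["beta"].unique())
        mat = (
            df.pivot(index="cpg_stratum", columns="beta", values="expected_nrpm")
            .loc[strata, grid]
            .to_numpy()
        )
        return cls(strata=strata, beta_grid=grid, expected_nrpm=mat)


def apply_class_map(arrays: ArrayBetaSet, class_map: ClassMap) -> ArrayBetaSet:
    """Relabel array samples into classifier classes, dropping exclusions.

    Raises if any source label is absent from the map (all offenders
    listed); logs each excluded sample with its reason.
    """
    unmapped = sorted(
        {lab for lab in arrays.labels if lab not in set(class_map.table["source_label"])}
    )
    if unmapped:
        raise ValueError(f"unmapped source labels: {unmapped}")
    keep = np.zeros(len(arrays.sample_ids), dtype=bool)
    new_labels: list[str] = []
    for i, lab in enumerate(arrays.labels):
        cls, reason = class_map.lookup(lab)
        if cls is None:
            logger.info("excluding sample %s (%s): %s", arrays.sample_ids[i], lab, reason)
            continue
        keep[i] = True
        new_labels.append(cls)
    return arrays.subset_samples(keep, new_labels)


def probe_to_window_beta(arrays: ArrayBetaSet, windows: WindowSet) -> BetaMatrix:
    """Collapse probe betas onto windows; max beta where several probes
    share a window. Only windows overlapping at least one probe appear."""
    wid = windows.locate(arrays.probe_chrom, arrays.probe_pos)
    outside = wid < 0
    if outside.any():
        logger.info("%d probes fall outside all windows; skipped", int(outside.sum()))
    wid = wid[~outside]
    beta = arrays.beta[~outside]
    order = np.argsort(wid, kind="stable")
    wid = wid[order]
    beta = beta[order]
    uniq, starts = np.unique(wid, return_index=True)
    out = np.full((len(uniq), beta.shape[1]), np.nan)
    bounds = np.append(starts, len(wid))
    for k in range(len(uniq)):
        chunk = beta[bounds[k] : bounds[k + 1]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            out[k] = np.nanmax(chunk, axis=0)
    return BetaMatrix(sample_ids=list(arrays.sample_ids), window_ids=uniq, beta=out.T)


def build_calibration(
    ncc_counts: CountMatrix,
    ncc_beta: BetaMatrix,
    windows: WindowSet,
) -> CalibrationTable:
    """Learn the (density, beta) -> expected NRPM lookup from pooled NCCs.

    Pooled NRPM values are averaged within (stratum, beta-bin) cells,
    empty cells filled by linear interpolation along beta then across
    density, and each stratum projected to be non-decreasing in beta.
    """
    strata = density_strata(windows)
    levels = np.unique(strata)
    if len(levels) == 1:
        warnings.warn("only one density stratum present; table still built", stacklevel=2)
    grid = np.round(np.arange(0, 1 + BETA_GRID_STEP / 2, BETA_GRID_STEP), 2)

    X = nrpm(ncc_counts, windows)  # masked windows NaN
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        pooled_nrpm = np.nanmean(X, axis=0)
    if ncc_beta.beta.shape[1] != len(windows):
        raise ValueError("ncc_beta must cover the full WindowSet")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        pooled_beta = np.nanmean(ncc_beta.beta, axis=0)
    # zero-CpG windows carry no methylation: anchor them at beta 0 so the
    # stratum-0 row reflects pure background rather than denser strata
    pooled_beta = np.where(windows.cpg_count == 0, 0.0, pooled_beta)

    ok = np.isfinite(pooled_nrpm) & np.isfinite(pooled_beta) & ~windows.masked
    bin_idx = np.clip(np.round(pooled_beta[ok] / BETA_GRID_STEP).astype(int), 0, len(grid) - 1)
    stratum_of = strata[ok]
    values = pooled_nrpm[ok]

    table = np.full((len(levels), len(grid)), np.nan)
    for k, d in enumerate(levels):
        sel = stratum_of == d
        if not sel.any():
            continue
        sums = np.bincount(bin_idx[sel], weights=values[sel], minlength=len(grid))
        ns = np.bincount(bin_idx[sel], minlength=len(grid))
        filled = ns > 0
        table[k, filled] = sums[filled] / ns[filled]

    # fill along beta within stratum, then across strata, then isotonic in beta
    for k in range(len(levels)):
        row = table[k]
        known = np.isfinite(row)
        if known.any():
            table[k] = np.interp(grid, grid[known], row[known])
    for j in range(len(grid)):
        col = table[:, j]
        known = np.isfinite(col)
        if not known.any():
            table[:, j] = 0.0
        elif not known.all():
            table[:, j] = np.interp(levels.astype(float), levels[known].astype(float), col[known])
    iso = IsotonicRegression(increasing=True)
    for k in range(len(levels)):
        table[k] = iso.fit_transform(grid, table[k])

    return CalibrationTable(strata=levels, beta_grid=grid, expected_nrpm=np.maximum(table, 0.0))


def convert_array(
    window_betas: pd.Series,
    table: CalibrationTable,
    windows: WindowSet,
    library_size: int,
    seed: int | np.random.Generator,
) -> pd.Series:
    """Draw a pseudo enrichment-seq count row from window betas.

    Expected counts are proportional to the calibration-table NRPM for
    each window's (density, beta) cell, rescaled to sum to
    ``library_size``; integer counts are drawn multinomially. Output is
    restricted to the windows carried by ``window_betas`` (the
    probe-overlap universe).
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    wid = window_betas.index.to_numpy(np.int64)
    beta = window_betas.to_numpy(float)
    ok = np.isfinite(beta)
    wid, beta = wid[ok], beta[ok]
    strata = density_strata(windows)[wid]
    rates = table.rate(strata, beta)
    total = rates.sum()
    if total <= 0:
        raise ValueError("all expected rates are zero; cannot convert")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    counts = rng.multinomial(int(library_size), rates / total)
    return pd.Series(counts, index=wid)


def convert_array_set(
    window_beta: BetaMatrix,
    table: CalibrationTable,
    windows: WindowSet,
    library_size: int,
    seed: int,
) -> CountMatrix:
    """Convert every sample of a window-level BetaMatrix to pseudo counts
    on the probe-overlap window universe (full-length rows, zeros outside)."""
    rng = np.random.default_rng(seed)
    counts = np.zeros((len(window_beta.sample_ids), len(windows)), dtype=np.int64)
    for i, sid in enumerate(window_beta.sample_ids):
        row = pd.Series(window_beta.beta[i], index=window_beta.window_ids)
        drawn = convert_array(row, table, windows, library_size, rng)
        counts[i, drawn.index.to_numpy()] = drawn.to_numpy()
    return CountMatrix(
        sample_ids=list(window_beta.sample_ids),
        counts=counts,
        valid_totals=counts.sum(axis=1),
    )
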