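"""Self-contained toy data with the statistical structure the pipeline assumes.

Generates a small genome with heterogeneous CpG density, class-specific
methylation signatures (marker windows elevated for one class, low
elsewhere), array-style beta profiles, and non-cancer control (NCC)
enrichment count profiles following a logistic density-dependent
enrichment curve. Everything is deterministic per seed and emitted in the
same shapes and formats the real pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from cupid.array_conversion import ArrayBetaSet
from cupid.fragment_counts import CountMatrix
from cupid.genome_windows import WindowSet, tile_genome
from cupid.mixture_simulator import NCC_CLASS
from cupid.qc_metrics import HyperstablePanel


@dataclass
class SyntheticConfig:
    # genome
    n_chroms: int = 2
    chrom_length: int = 300_000
    window_size: int = 300
    # CpG-density strata (count per window) and their sampling weights
    density_levels: tuple[int, ...] = (0, 2, 5, 10, 20, 40)
    density_weights: tuple[float, ...] = (0.40, 0.15, 0.15, 0.15, 0.10, 0.05)
    # cohort
    n_classes: int = 4
    arrays_per_class: int = 10
    n_normal_arrays: int = 2  # baseline-profile arrays labelled NCC
    n_ncc: int = 6
    # methylation signatures
    markers_per_class: int = 30
    marker_min_cpg: int = 10
    beta_high: float = 0.95
    beta_low: float = 0.05
    baseline_high: float = 0.92
    baseline_low: float = 0.06
    p_baseline_high: float = 0.5
    beta_noise_sd: float = 0.03
    # enrichment curve: expected NRPM = background + amplitude(d) * beta
    enrich_background: float = 10.0
    enrich_max: float = 2000.0
    enrich_k: float = 0.25
    enrich_mid: float = 10.0
    # NCC libraries
    ncc_depth: int = 50_000
    panel_size: int = 100

    def __post_init__(self) -> None:
        if len(self.density_levels) != len(self.density_weights):
            raise ValueError("density levels and weights must align")
        if self.window_size > self.chrom_length:
            raise ValueError("window_size larger than chromosome length")
        if min(self.n_chroms, self.n_classes, self.arrays_per_class, self.n_ncc) < 1:
            raise ValueError("counts must be positive")
        for b in (self.beta_high, self.beta_low, self.baseline_high, self.baseline_low):
            if not 0.0 <= b <= 1.0:
                raise ValueError("beta means must lie in [0,1]")


@dataclass
class GroundTruth:
    sample_class: dict[str, str]
    class_beta: dict[str, np.ndarray]  # true per-window beta per class
    marker_windows: dict[str, np.ndarray]
    baseline_beta: np.ndarray = field(default=None)  # type: ignore[assignment]


def enrichment_nrpm(cpg_count: np.ndarray, beta: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Expected NRPM: background plus a logistic-in-density amplitude
    scaled by methylation level; zero-CpG windows sit at background."""
    d = np.asarray(cpg_count, dtype=float)
    lo = 1.0 / (1.0 + np.exp(cfg.enrich_k * cfg.enrich_mid))
    amp = cfg.enrich_max * (1.0 / (1.0 + np.exp(-cfg.enrich_k * (d - cfg.enrich_mid))) - lo) / (1.0 - lo)
    return cfg.enrich_background + amp * np.asarray(beta, dtype=float)


def make_reference(cfg: SyntheticConfig, seed: int = 0) -> tuple[dict[str, str], WindowSet]:
    """Generate chromosome sequences whose windows carry exactly the
    sampled per-window CpG counts (filler bases are A/T so no accidental
    CpGs form), then tile them."""
    rng = np.random.default_rng(seed)
    w = cfg.window_size
    sequences: dict[str, str] = {}
    weights = np.asarray(cfg.density_weights, dtype=float)
    weights = weights / weights.sum()
    for c in range(cfg.n_chroms):
        n_windows = -(-cfg.chrom_length // w)  # ceil
        parts: list[str] = []
        for i in range(n_windows):
            length = min(w, cfg.chrom_length - i * w)
            k = int(rng.choice(cfg.density_levels, p=weights))
            block = rng.choice(np.array(["A", "T"]), size=length)
            slots = np.arange(0, length - 1, 2)
            k = min(k, len(slots))
            if k > 0:
                pos = rng.choice(slots, size=k, replace=False)
                block[pos] = "C"
                block[pos + 1] = "G"
            parts.append("".join(block))
        sequences[f"chr{c + 1}"] = "".join(parts)
    windows = tile_genome(sequences, window_size=w)
    return sequences, windows


def _baseline_beta(cfg: SyntheticConfig, windows: WindowSet, rng: np.random.Generator) -> np.ndarray:
    """Shared bimodal methylation background; CpG-free windows get a flat
    mid value (arrays have no signal there, enrichment only background)."""
    n = len(windows)
    beta = np.full(n, 0.5)
    has_cpg = windows.cpg_count > 0
    high = rng.random(n) < cfg.p_baseline_high
    beta[has_cpg & high] = cfg.baseline_high
    beta[has_cpg & ~high] = cfg.baseline_low
    return beta


def _assign_markers(
    cfg: SyntheticConfig, windows: WindowSet, rng: np.random.Generator, class_names: list[str]
) -> dict[str, np.ndarray]:
    eligible = np.flatnonzero((windows.cpg_count >= cfg.marker_min_cpg) & ~windows.masked)
    need = cfg.markers_per_class * len(class_names)
    if len(eligible) < need:
        raise ValueError(
            f"not enough CpG-dense windows for markers: need {need}, have {len(eligible)}"
        )
    chosen = rng.choice(eligible, size=need, replace=False)
    return {
        cls: np.sort(chosen[i * cfg.markers_per_class : (i + 1) * cfg.markers_per_class])
        for i, cls in enumerate(class_names)
    }


def make_class_arrays(
    cfg: SyntheticConfig, windows: WindowSet, seed: int = 0
) -> tuple[ArrayBetaSet, GroundTruth]:
    """Array-style beta profiles: one probe per window midpoint; class-c
    samples sit at ``beta_high`` on class-c marker windows, ``beta_low``
    on every other class's markers, and at the shared baseline elsewhere.
    Arrays labelled NCC carry the pure baseline (normal-tissue analogue).
    """
    rng = np.random.default_rng(seed)
    class_names = [f"C{i + 1}" for i in range(cfg.n_classes)]
    baseline = _baseline_beta(cfg, windows, rng)
    markers = _assign_markers(cfg, windows, rng, class_names)
    all_markers = np.concatenate(list(markers.values()))
    if len(np.unique(all_markers)) != len(all_markers):
        raise ValueError("overlapping marker assignments")

    class_beta: dict[str, np.ndarray] = {}
    for cls in class_names:
        b = baseline.copy()
        b[all_markers] = cfg.beta_low
        b[markers[cls]] = cfg.beta_high
        class_beta[cls] = b
    class_beta[NCC_CLASS] = baseline.copy()

    sample_ids: list[str] = []
    labels: list[str] = []
    columns: list[np.ndarray] = []
    truth_class: dict[str, str] = {}
    for cls in class_names:
        for r in range(cfg.arrays_per_class):
            sid = f"{cls}_arr{r}"
            noisy = np.clip(class_beta[cls] + rng.normal(0, cfg.beta_noise_sd, len(windows)), 0, 1)
            sample_ids.append(sid)
            labels.append(cls)
            columns.append(noisy)
            truth_class[sid] = cls
    for r in range(cfg.n_normal_arrays):
        sid = f"normal_arr{r}"
        noisy = np.clip(class_beta[NCC_CLASS] + rng.normal(0, cfg.beta_noise_sd, len(windows)), 0, 1)
        sample_ids.append(sid)
        labels.append(NCC_CLASS)
        columns.append(noisy)
        truth_class[sid] = NCC_CLASS

    mid = (windows.start + windows.end) // 2
    arrays = ArrayBetaSet(
        sample_ids=sample_ids,
        labels=labels,
        probe_chrom=windows.chrom.copy(),
        probe_pos=mid.astype(np.int64),
        beta=np.column_stack(columns),
    )
    truth = GroundTruth(
        sample_class=truth_class,
        class_beta=class_beta,
        marker_windows=markers,
        baseline_beta=baseline,
    )
    return arrays, truth


def make_ncc_counts(
    cfg: SyntheticConfig, windows: WindowSet, seed: int = 0
) -> tuple[CountMatrix, HyperstablePanel]:
    """Poisson NCC count profiles along the enrichment curve at the
    baseline methylation state, plus a hyperstable panel of designated
    always-methylated CpG-dense windows."""
    if cfg.ncc_depth <= 0:
        raise ValueError("ncc_depth must be positive")
    rng = np.random.default_rng(seed)
    baseline = _baseline_beta(cfg, windows, rng)
    # CpG-free windows have no methylation signal in enrichment space
    beta = np.where(windows.cpg_count > 0, baseline, 0.0)
    expected = enrichment_nrpm(windows.cpg_count, beta, cfg)
    rates = expected / expected.sum()
    counts = rng.poisson(rates[None, :] * cfg.ncc_depth, size=(cfg.n_ncc, len(windows)))
    cm = CountMatrix(
        sample_ids=[f"ncc{i}" for i in range(cfg.n_ncc)],
        counts=counts.astype(np.int64),
        valid_totals=counts.sum(axis=1),
    )
    stable = np.flatnonzero(
        (baseline == cfg.baseline_high) & (windows.cpg_count >= cfg.marker_min_cpg) & ~windows.masked
    )
    if len(stable) == 0:
        raise ValueError("no hyperstable candidate windows; densify the config")
    panel = HyperstablePanel(window_ids=stable[: cfg.panel_size])
    return cm, panel


def make_ncc_fragments(
    cfg: SyntheticConfig,
    windows: WindowSet,
    seed: int = 0,
    n_fragments: int = 20_000,
    frag_len: tuple[int, int] = (120, 220),
) -> pd.DataFrame:
    """Fragment-level NCC sample: fragments land in windows proportionally
    to the enrichment curve, positioned uniformly inside the window."""
    rng = np.random.default_rng(seed)
    baseline = _baseline_beta(cfg, windows, rng)
    beta = np.where(windows.cpg_count > 0, baseline, 0.0)
    expected = enrichment_nrpm(windows.cpg_count, beta, cfg)
    probs = expected / expected.sum()
    wid = rng.choice(len(windows), size=n_fragments, p=probs)
    lengths = rng.integers(frag_len[0], frag_len[1] + 1, size=n_fragments)
    w_start = windows.start[wid]
    w_end = windows.end[wid]
    span = np.maximum(w_end - w_start - lengths, 1)
    starts = w_start + rng.integers(0, span)
    ends = starts + lengths
    return pd.DataFrame(
        {
            "chrom": windows.chrom[wid],
            "start": starts,
            "end": ends,
            "mapq1": 60,
            "mapq2": 60,
        }
    )


def pooled_control_counts(
    cfg: SyntheticConfig,
    windows: WindowSet,
    seed: int = 0,
    n_hot_windows: int = 3,
    hot_factor: float = 200.0,
) -> np.ndarray:
    """Pooled non-enriched control counts with a few artefactual hot
    windows, for exercising the over-represented window mask."""
    rng = np.random.default_rng(seed)
    base = rng.poisson(50.0, size=len(windows)).astype(float)
    hot = rng.choice(len(windows), size=n_hot_windows, replace=False)
    base[hot] *= hot_factor
    return base
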