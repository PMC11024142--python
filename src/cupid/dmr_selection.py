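"""Pairwise differentially methylated window selection with FDR control."""

from __future__ import annotations

import warnings
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cupid.fragment_counts import BetaMatrix


def _welch_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test per column (NaN-aware); columns without at
    least two finite values per group get p = NaN."""
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-identical groups trigger scipy's catastrophic-cancellation
        # warning; those columns resolve to NaN p-values (no evidence)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=0, equal_var=False, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    # zero-variance, equal-mean columns yield NaN statistics: no evidence
    return p


def pairwise_dmrs(
    beta: BetaMatrix,
    classes: Sequence[str],
    fdr: float = 0.001,
    n_top: int = 250,
) -> pd.DataFrame:
    """Select discriminating windows for every unordered class pair.

    Per pair: Welch's t-test on per-window betas, Benjamini-Hochberg
    within the pair, then among q <= ``fdr`` windows keep the ``n_top``
    largest and ``n_top`` smallest mean-beta differences (delta_beta =
    mean_first - mean_second). Boundary ties break by smaller q, then
    lower window id, so output is deterministic.

    Returns the DMR catalog: window_id, class_a, class_b, delta_beta,
    q_value, direction.
    """
    labels = np.asarray(classes, dtype=object)
    if len(labels) != len(beta.sample_ids):
        raise ValueError("one class label per sample required")
    class_names = sorted(pd.unique(labels))
    for c in class_names:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")

    records: list[dict] = []
    for ca, cb in combinations(class_names, 2):
        A = beta.beta[labels == ca]
        B = beta.beta[labels == cb]
        # a window participates only if both classes have >=2 finite betas
        n_a = np.isfinite(A).sum(axis=0)
        n_b = np.isfinite(B).sum(axis=0)
        usable = (n_a >= 2) & (n_b >= 2)
        if not usable.any():
            continue
        p = _welch_pvalues(A[:, usable], B[:, usable])
        delta = np.nanmean(A[:, usable], axis=0) - np.nanmean(B[:, usable], axis=0)
        wids = beta.window_ids[usable]
        tested = np.isfinite(p)
        if not tested.any():
            continue
        q = np.full(len(p), np.nan)
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
        sig = tested & (q <= fdr)
        if not sig.any():
            continue
        sig_idx = np.flatnonzero(sig)
        sig_df = pd.DataFrame(
            {"window_id": wids[sig_idx], "delta_beta": delta[sig_idx], "q_value": q[sig_idx]}
        )
        top = (
            sig_df[sig_df["delta_beta"] > 0]
            .sort_values(["delta_beta", "q_value", "window_id"], ascending=[False, True, True])
            .head(n_top)
        )
        bottom = (
            sig_df[sig_df["delta_beta"] < 0]
            .sort_values(["delta_beta", "q_value", "window_id"], ascending=[True, True, True])
            .head(n_top)
        )
        for direction, part in (("top", top), ("bottom", bottom)):
            for r in part.itertuples():
                records.append(
                    {
                        "window_id": int(r.window_id),
                        "class_a": ca,
                        "class_b": cb,
                        "delta_beta": float(r.delta_beta),
                        "q_value": float(r.q_value),
                        "direction": direction,
                    }
                )
    catalog = pd.DataFrame(
        records, columns=["window_id", "class_a", "class_b", "delta_beta", "q_value", "direction"]
    )
    return catalog


def dedupe_regions(catalog: pd.DataFrame) -> np.ndarray:
    """Sorted union of window ids across all pairwise selections."""
    if catalog.empty:
        return np.array([], dtype=np.int64)
    return np.sort(catalog["window_id"].unique()).astype(np.int64)


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
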