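"""Shared fixtures: a deterministic toy dataset and an end-to-end run.

Everything is generated programmatically at test time — no data files.
The expensive end-to-end artifacts are session-scoped so acceptance and
unit tests share one build.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from cupid.array_conversion import build_calibration, convert_array_set, probe_to_window_beta
from cupid.dmr_selection import dedupe_regions, pairwise_dmrs
from cupid.ensemble import TrainParams, train_ensemble
from cupid.fragment_counts import calibrate_beta, nrpm
from cupid.mixture_simulator import mix_all, plan_mixtures
from cupid.synthetic_data import (
    SyntheticConfig,
    make_class_arrays,
    make_ncc_counts,
    make_reference,
)


@pytest.fixture(scope="session")
def toy_cfg() -> SyntheticConfig:
    return SyntheticConfig()


@pytest.fixture(scope="session")
def toy_reference(toy_cfg):
    sequences, windows = make_reference(toy_cfg, seed=1)
    return SimpleNamespace(sequences=sequences, windows=windows)


@pytest.fixture(scope="session")
def toy_ncc(toy_cfg, toy_reference):
    counts, panel = make_ncc_counts(toy_cfg, toy_reference.windows, seed=3)
    beta = calibrate_beta(
        nrpm(counts, toy_reference.windows),
        toy_reference.windows,
        sample_ids=counts.sample_ids,
    )
    return SimpleNamespace(counts=counts, panel=panel, beta=beta)


@pytest.fixture(scope="session")
def toy_arrays(toy_cfg, toy_reference):
    arrays, truth = make_class_arrays(toy_cfg, toy_reference.windows, seed=4)
    window_beta = probe_to_window_beta(arrays, toy_reference.windows)
    return SimpleNamespace(arrays=arrays, truth=truth, window_beta=window_beta)


@pytest.fixture(scope="session")
def toy_calibration(toy_reference, toy_ncc):
    return build_calibration(toy_ncc.counts, toy_ncc.beta, toy_reference.windows)


@pytest.fixture(scope="session")
def toy_converted(toy_reference, toy_arrays, toy_calibration):
    return convert_array_set(
        toy_arrays.window_beta, toy_calibration, toy_reference.windows, library_size=100_000, seed=7
    )


@pytest.fixture(scope="session")
def toy_mixtures(toy_arrays, toy_ncc, toy_converted):
    array_labels = dict(zip(toy_arrays.arrays.sample_ids, toy_arrays.arrays.labels))
    plans = plan_mixtures(
        array_labels,
        toy_ncc.counts.sample_ids,
        seed=11,
        depth_range=(50_000, 150_000),
    )
    components = {
        sid: toy_converted.counts[i] for i, sid in enumerate(toy_converted.sample_ids)
    }
    components.update(
        {sid: toy_ncc.counts.counts[i] for i, sid in enumerate(toy_ncc.counts.sample_ids)}
    )
    return mix_all(plans, components)


@pytest.fixture(scope="session")
def toy_dmrs(toy_arrays):
    catalog = pairwise_dmrs(toy_arrays.window_beta, toy_arrays.arrays.labels, fdr=0.001, n_top=250)
    return SimpleNamespace(catalog=catalog, windows=dedupe_regions(catalog))


@pytest.fixture(scope="session")
def toy_model(toy_mixtures, toy_dmrs):
    params = TrainParams(n_members=10, trees=200, ncc_frac=0.5)
    return train_ensemble(toy_mixtures, toy_dmrs.windows, params, seed=21)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
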