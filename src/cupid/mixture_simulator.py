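"""In-silico cfDNA mixtures: spike converted tumour counts into NCC profiles."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cupid.fragment_counts import CountMatrix

NCC_CLASS = "NCC"


@dataclass
class MixtureSpec:
    """One planned synthetic sample.

    ``component_a`` is the spiked-in component (a converted array, or the
    first NCC of an NCC-NCC pair); ``component_b`` is always an NCC.
    """

    component_a_id: str
    component_b_id: str
    proportion_a: float
    n_fragments: int
    class_label: str
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion_a <= 1.0:
            raise ValueError("proportion_a must lie in [0,1]")
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be positive")


@dataclass
class MixtureSet:
    specs: list[MixtureSpec]
    counts: CountMatrix
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.specs) != len(self.counts.sample_ids):
            raise ValueError("one count row per spec required")
        if not self.labels:
            self.labels = [s.class_label for s in self.specs]

    def __len__(self) -> int:
        return len(self.specs)


def plan_mixtures(
    array_labels: Mapping[str, str],
    ncc_ids: Sequence[str],
    seed: int,
    per_class_cap: int = 10_000,
    tumour_proportions: tuple[float, float] = (0.005, 0.10),
    ncc_proportions: tuple[float, float] = (0.15, 0.50),
    depth_range: tuple[int, int] = (1_000_000, 10_000_000),
) -> list[MixtureSpec]:
    """Plan every (component, NCC) pairing once with random proportion/depth.

    Tumour arrays pair with every NCC at a tumour-fraction proportion;
    arrays labelled NCC (e.g. adjacent-normal tissue) do the same but keep
    the NCC label. NCC-NCC plans are ordered pairs (each NCC spiked once
    into each other NCC) at the wider NCC proportion range. Each class is
    then subsampled down to ``per_class_cap`` plans.
    """
    if per_class_cap < 1:
        raise ValueError("per_class_cap must be >= 1")
    if len(ncc_ids) < 2:
        raise ValueError("need at least 2 NCC samples")
    rng = np.random.default_rng(seed)

    plans: list[MixtureSpec] = []

    def draw_spec(a: str, b: str, prop_range: tuple[float, float], label: str) -> MixtureSpec:
        p = float(rng.uniform(*prop_range))
        n = int(rng.integers(depth_range[0], depth_range[1] + 1))
        return MixtureSpec(a, b, p, n, label, seed=int(rng.integers(0, 2**31 - 1)))

    for array_id, label in array_labels.items():
        for ncc in ncc_ids:
            plans.append(draw_spec(array_id, ncc, tumour_proportions, label))
    for a in ncc_ids:
        for b in ncc_ids:
            if a != b:
                plans.append(draw_spec(a, b, ncc_proportions, NCC_CLASS))

    # per-class cap, preserving plan order within the subsample
    by_class: dict[str, list[int]] = {}
    for i, spec in enumerate(plans):
        by_class.setdefault(spec.class_label, []).append(i)
    keep: list[int] = []
    for label in by_class:
        idx = by_class[label]
        if len(idx) > per_class_cap:
            idx = sorted(rng.choice(idx, size=per_class_cap, replace=False).tolist())
        keep.extend(idx)
    keep.sort()
    return [plans[i] for i in keep]


def mix(spec: MixtureSpec, a_counts: np.ndarray, b_counts: np.ndarray) -> np.ndarray:
    """Draw one mixture count row.

    Window rates are p * a/sum(a) + (1-p) * b/sum(b); counts are a single
    multinomial draw of ``spec.n_fragments`` seeded by ``spec.seed``.
    """
    a = np.asarray(a_counts, dtype=float)
    b = np.asarray(b_counts, dtype=float)
    if a.shape != b.shape:
        raise ValueError("components must share a window universe")
    sa, sb = a.sum(), b.sum()
    if sa == 0 or sb == 0:
        raise ValueError("component with zero total counts")
    rate = spec.proportion_a * a / sa + (1.0 - spec.proportion_a) * b / sb
    rng = np.random.default_rng(spec.seed)
    return rng.multinomial(spec.n_fragments, rate / rate.sum())


def mix_all(
    specs: Sequence[MixtureSpec],
    component_counts: Mapping[str, np.ndarray],
) -> MixtureSet:
    """Materialise a planned mixture list into a MixtureSet."""
    n_windows = len(next(iter(component_counts.values())))
    counts = np.zeros((len(specs), n_windows), dtype=np.int64)
    for i, spec in enumerate(specs):
        counts[i] = mix(spec, component_counts[spec.component_a_id], component_counts[spec.component_b_id])
    cm = CountMatrix(
        sample_ids=[f"mix{i}" for i in range(len(specs))],
        counts=counts,
        valid_totals=counts.sum(axis=1),
    )
    return MixtureSet(specs=list(specs), counts=cm)


def specs_to_frame(specs: Sequence[MixtureSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "component_a_id": [s.component_a_id for s in specs],
            "component_b_id": [s.component_b_id for s in specs],
            "proportion_a": [s.proportion_a for s in specs],
            "n_fragments": [s.n_fragments for s in specs],
            "class_label": [s.class_label for s in specs],
            "seed": [s.seed for s in specs],
        }
    )


def write_specs(specs: Sequence[MixtureSpec], path: str | Path) -> None:
    specs_to_frame(specs).to_csv(path, sep="\t", index=False)


def read_specs(path: str | Path) -> list[MixtureSpec]:
    df = pd.read_csv(path, sep="\t")
    return [
        MixtureSpec(
            component_a_id=str(r.component_a_id),
            component_b_id=str(r.component_b_id),
            proportion_a=float(r.proportion_a),
            n_fragments=int(r.n_fragments),
            class_label=str(r.class_label),
            seed=int(r.seed),
        )
        for r in df.itertuples()
    ]
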