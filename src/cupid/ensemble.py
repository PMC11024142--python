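"""Bagged gradient-boosted multi-class ensemble, call rule, and evaluation.

Each of the (by default 100) sub-classifiers trains only on mixtures whose
components fall inside its own 80% array / 80% NCC subsets, so held-out
scoring can average over members that never saw either component of a
mixture. Ensemble scores are the arithmetic mean of member class
probabilities; a tumour class is called when its mean score exceeds 0.5
(so it beats all other classes combined), otherwise — or when the
non-cancer class wins — the sample is UNCLASSIFIED.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier

from cupid.fragment_counts import CountMatrix
from cupid.mixture_simulator import MixtureSet, NCC_CLASS

UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class TrainParams:
    n_members: int = 100
    array_frac: float = 0.8
    ncc_frac: float = 0.8
    trees: int = 200
    row_subsample: float = 0.5
    feature_subsample_frac: float = 0.10
    feature_subsample_count: int | None = None  # absolute override
    learning_rate: float = 0.1
    max_retries: int = 20

    def resolve_feature_count(self, n_features: int) -> int:
        if self.feature_subsample_count is not None:
            return min(self.feature_subsample_count, n_features)
        return max(1, round(self.feature_subsample_frac * n_features))


@dataclass
class SubClassifier:
    model: GradientBoostingClassifier
    train_array_ids: frozenset[str]
    train_ncc_ids: frozenset[str]
    seed: int

    def saw(self, component_id: str) -> bool:
        return component_id in self.train_array_ids or component_id in self.train_ncc_ids


@dataclass
class EnsembleModel:
    members: list[SubClassifier]
    feature_windows: np.ndarray  # window ids used as features
    classes: list[str]
    ncc_class: str = NCC_CLASS
    manifest: dict = field(default_factory=dict)

    def member_scores(self, X: np.ndarray) -> np.ndarray:
        """(n_members, n_samples, n_classes) probability tensor, columns
        aligned to ``self.classes`` (absent classes scored 0)."""
        out = np.zeros((len(self.members), X.shape[0], len(self.classes)))
        col = {c: j for j, c in enumerate(self.classes)}
        for m, sub in enumerate(self.members):
            proba = sub.model.predict_proba(X)
            for j, cls in enumerate(sub.model.classes_):
                out[m, :, col[cls]] = proba[:, j]
        return out

    def features_from(self, cm: CountMatrix) -> np.ndarray:
        """NRPM over the feature windows."""
        return (
            cm.counts[:, self.feature_windows] / cm.valid_totals[:, None] * 1e6
        )


@dataclass
class PredictionResult:
    sample_id: str
    scores: pd.Series  # index = classes, sums to 1
    call: str

    def __post_init__(self) -> None:
        if abs(float(self.scores.sum()) - 1.0) > 1e-6:
            raise ValueError("scores must sum to 1")


def _component_roles(mixtures: MixtureSet) -> tuple[dict[str, str], set[str]]:
    """Split component ids into arrays (with their class) and NCCs.

    Every NCC appears as a spike-target (component_b) somewhere; array
    components never do.
    """
    ncc_ids = {s.component_b_id for s in mixtures.specs}
    array_class: dict[str, str] = {}
    for s in mixtures.specs:
        if s.component_a_id not in ncc_ids:
            array_class[s.component_a_id] = s.class_label
    return array_class, ncc_ids


def _stratified_subset(
    ids_by_class: Mapping[str, list[str]], frac: float, rng: np.random.Generator
) -> frozenset[str]:
    chosen: list[str] = []
    for cls in sorted(ids_by_class):
        ids = sorted(ids_by_class[cls])
        k = max(1, round(frac * len(ids)))
        chosen.extend(rng.choice(ids, size=k, replace=False).tolist())
    return frozenset(chosen)


def train_ensemble(
    mixtures: MixtureSet,
    dmr_windows: np.ndarray,
    params: TrainParams | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Train the sub-classifier ensemble on mixture NRPM features.

    Array subsets are drawn stratified by class so no member loses a small
    class outright; NCC subsets are drawn unstratified. A member whose
    training mixtures still miss a class is redrawn (bounded retries).
    """
    params = params or TrainParams()
    dmr_windows = np.asarray(dmr_windows, dtype=np.int64)
    specs = mixtures.specs
    labels = np.asarray(mixtures.labels, dtype=object)
    classes = sorted(pd.unique(labels))
    array_class, ncc_ids = _component_roles(mixtures)
    arrays_by_class: dict[str, list[str]] = {}
    for aid, cls in array_class.items():
        arrays_by_class.setdefault(cls, []).append(aid)
    ncc_list = sorted(ncc_ids)

    X = mixtures.counts.counts[:, dmr_windows] / mixtures.counts.valid_totals[:, None] * 1e6
    feat_count = params.resolve_feature_count(len(dmr_windows))

    comp_a = np.asarray([s.component_a_id for s in specs], dtype=object)
    comp_b = np.asarray([s.component_b_id for s in specs], dtype=object)
    a_is_array = np.asarray([s.component_a_id in array_class for s in specs])

    rng = np.random.default_rng(seed)
    members: list[SubClassifier] = []
    member_manifests = []
    for m in range(params.n_members):
        for attempt in range(params.max_retries):
            member_seed = int(rng.integers(0, 2**31 - 1))
            sub_rng = np.random.default_rng(member_seed)
            array_subset = _stratified_subset(arrays_by_class, params.array_frac, sub_rng)
            k_ncc = max(1, round(params.ncc_frac * len(ncc_list)))
            ncc_subset = frozenset(sub_rng.choice(ncc_list, size=k_ncc, replace=False).tolist())

            in_a = np.array(
                [
                    (a in array_subset) if is_arr else (a in ncc_subset)
                    for a, is_arr in zip(comp_a, a_is_array)
                ]
            )
            in_b = np.isin(comp_b, sorted(ncc_subset))
            train_mask = in_a & in_b
            train_labels = labels[train_mask]
            if set(classes) <= set(train_labels):
                break
        else:
            missing = sorted(set(classes) - set(train_labels))
            raise RuntimeError(
                f"member {m}: classes {missing} absent from training mixtures "
                f"after {params.max_retries} redraws"
            )

        model = GradientBoostingClassifier(
            n_estimators=params.trees,
            subsample=params.row_subsample,
            max_features=feat_count,
            learning_rate=params.learning_rate,
            random_state=member_seed,
        )
        model.fit(X[train_mask], train_labels.astype(str))
        members.append(
            SubClassifier(
                model=model,
                train_array_ids=array_subset,
                train_ncc_ids=ncc_subset,
                seed=member_seed,
            )
        )
        member_manifests.append(
            {
                "member": m,
                "seed": member_seed,
                "train_array_ids": sorted(array_subset),
                "train_ncc_ids": sorted(ncc_subset),
                "n_train_mixtures": int(train_mask.sum()),
            }
        )

    manifest = {
        "seed": seed,
        "params": {
            "n_members": params.n_members,
            "array_frac": params.array_frac,
            "ncc_frac": params.ncc_frac,
            "trees": params.trees,
            "row_subsample": params.row_subsample,
            "feature_subsample_count": feat_count,
            "learning_rate": params.learning_rate,
        },
        "classes": classes,
        "n_features": len(dmr_windows),
        "n_mixtures": len(mixtures),
        "members": member_manifests,
    }
    return EnsembleModel(
        members=members,
        feature_windows=dmr_windows,
        classes=classes,
        manifest=manifest,
    )


def call_from_scores(scores: pd.Series, ncc_class: str = NCC_CLASS) -> str:
    """Apply the call rule: the argmax class is called iff its mean score
    exceeds 0.5 (it then outscores all other classes combined) and it is
    not the non-cancer class; otherwise UNCLASSIFIED."""
    best = scores.idxmax()
    if scores[best] > 0.5 and best != ncc_class:
        return str(best)
    return UNCLASSIFIED


def predict(
    model: EnsembleModel,
    counts: CountMatrix,
    member_filter: Sequence[int] | None = None,
) -> list[PredictionResult]:
    """Score samples with the (optionally filtered) member mean and call."""
    if member_filter is not None:
        member_filter = list(member_filter)
        if len(member_filter) == 0:
            raise ValueError("member_filter must not be empty")
    X = model.features_from(counts)
    tensor = model.member_scores(X)
    if member_filter is not None:
        tensor = tensor[member_filter]
    mean_scores = tensor.mean(axis=0)
    results = []
    for i, sid in enumerate(counts.sample_ids):
        s = pd.Series(mean_scores[i], index=model.classes)
        results.append(PredictionResult(sample_id=sid, scores=s, call=call_from_scores(s, model.ncc_class)))
    return results


def heldout_scores(
    model: EnsembleModel,
    mixtures: MixtureSet,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean scores per mixture over members that saw neither component.

    Returns (scores (n_mixtures, n_classes) with NaN rows where no member
    is eligible, eligible-member counts).
    """
    X = model.features_from(mixtures.counts)
    tensor = model.member_scores(X)
    n = len(mixtures)
    scores = np.full((n, len(model.classes)), np.nan)
    n_eligible = np.zeros(n, dtype=np.int64)
    eligibility = np.zeros((len(model.members), n), dtype=bool)
    for m, sub in enumerate(model.members):
        for i, spec in enumerate(mixtures.specs):
            eligibility[m, i] = not (sub.saw(spec.component_a_id) or sub.saw(spec.component_b_id))
    for i in range(n):
        elig = eligibility[:, i]
        n_eligible[i] = elig.sum()
        if n_eligible[i]:
            scores[i] = tensor[elig, i, :].mean(axis=0)
    return scores, n_eligible


def hand_till_auroc(
    scores: np.ndarray,
    labels: Sequence[str],
    classes: Sequence[str] | None = None,
) -> float:
    """Multi-class AUROC: mean over class pairs of the symmetrised
    probability that a random member of one class outscores a random
    member of the other on the first class's score (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if classes is None:
        classes = sorted(pd.unique(labels))
    classes = list(classes)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    idx = {c: j for j, c in enumerate(classes)}
    for c in classes:
        if (labels == c).sum() == 0:
            raise ValueError(f"class {c!r} has no samples")

    def a_given(i: str, j: str) -> float:
        """P(score_i of a class-i sample > that of a class-j sample)."""
        si = scores[labels == i, idx[i]]
        sj = scores[labels == j, idx[i]]
        ranks = rankdata(np.concatenate([si, sj]))
        ni, nj = len(si), len(sj)
        return (ranks[:ni].sum() - ni * (ni + 1) / 2) / (ni * nj)

    total = 0.0
    pairs = list(combinations(classes, 2))
    for i, j in pairs:
        total += (a_given(i, j) + a_given(j, i)) / 2
    return total / len(pairs)


@dataclass
class EvaluationSummary:
    """Outcome tally over samples with a tumour truth label, plus
    non-cancer specificity."""

    n_correct: int
    n_unclassified: int
    n_incorrect: int
    ncc_total: int = 0
    ncc_unclassified: int = 0

    @property
    def n_total(self) -> int:
        return self.n_correct + self.n_unclassified + self.n_incorrect

    @property
    def sensitivity(self) -> float:
        return self.n_correct / self.n_total

    @property
    def too_accuracy(self) -> float:
        """Correct calls among samples that received any tumour call."""
        return self.n_correct / (self.n_correct + self.n_incorrect)

    @property
    def unclassified_rate(self) -> float:
        return self.n_unclassified / self.n_total

    @property
    def incorrect_rate(self) -> float:
        return self.n_incorrect / self.n_total

    @property
    def ncc_specificity(self) -> float:
        return self.ncc_unclassified / self.ncc_total


def evaluate(
    predictions: Sequence[PredictionResult],
    truth: Mapping[str, str],
    ncc_class: str = NCC_CLASS,
) -> EvaluationSummary:
    """Tally calls against truth labels.

    Tumour-truth samples are correct when the call equals the label,
    unclassified on an UNCLASSIFIED call, incorrect otherwise; a truth
    label outside the model's class list can therefore only be
    unclassified or incorrect. Non-cancer-truth samples feed specificity:
    the fraction left UNCLASSIFIED.
    """
    n_correct = n_unclassified = n_incorrect = 0
    ncc_total = ncc_unclassified = 0
    for pred in predictions:
        label = truth[pred.sample_id]
        if label == ncc_class:
            ncc_total += 1
            ncc_unclassified += pred.call == UNCLASSIFIED
        elif pred.call == UNCLASSIFIED:
            n_unclassified += 1
        elif pred.call == label:
            n_correct += 1
        else:
            n_incorrect += 1
    return EvaluationSummary(
        n_correct=n_correct,
        n_unclassified=n_unclassified,
        n_incorrect=n_incorrect,
        ncc_total=ncc_total,
        ncc_unclassified=ncc_unclassified,
    )


@dataclass
class CohortCallSummary:
    """Call-rate bookkeeping for a cohort without per-sample truth (e.g. a
    cancers-of-unknown-primary cohort), plus optional consistency and
    broad-category annotations."""

    n_total: int
    n_called: int
    n_consistent: int | None = None
    n_evaluable_called: int | None = None
    n_in_broad_category: int | None = None

    def __post_init__(self) -> None:
        if self.n_called > self.n_total:
            raise ValueError("n_called cannot exceed n_total")

    @classmethod
    def from_predictions(cls, predictions: Sequence[PredictionResult]) -> "CohortCallSummary":
        called = sum(p.call != UNCLASSIFIED for p in predictions)
        return cls(n_total=len(predictions), n_called=called)

    @property
    def n_unclassified(self) -> int:
        return self.n_total - self.n_called

    @property
    def call_rate(self) -> float:
        return self.n_called / self.n_total

    @property
    def unclassified_rate(self) -> float:
        return self.n_unclassified / self.n_total

    @property
    def consistency_rate(self) -> float:
        """Consistent calls among called samples with an evaluable
        (resolved or suspected) diagnosis."""
        if self.n_consistent is None or not self.n_evaluable_called:
            raise ValueError("consistency counts not set")
        return self.n_consistent / self.n_evaluable_called

    @property
    def broad_category_rate(self) -> float:
        """Calls falling inside the designated broad cancer categories,
        among all tumour calls."""
        if self.n_in_broad_category is None:
            raise ValueError("broad-category count not set")
        return self.n_in_broad_category / self.n_called


def save_model(model: EnsembleModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = dict(model.manifest)
    manifest["classes"] = model.classes
    manifest["ncc_class"] = model.ncc_class
    manifest["feature_windows"] = [int(w) for w in model.feature_windows]
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for m, sub in enumerate(model.members):
        joblib.dump(sub, directory / f"member_{m:03d}.joblib")


def load_model(directory: str | Path) -> EnsembleModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    members = [joblib.load(p) for p in sorted(directory.glob("member_*.joblib"))]
    return EnsembleModel(
        members=members,
        feature_windows=np.asarray(manifest["feature_windows"], dtype=np.int64),
        classes=list(manifest["classes"]),
        ncc_class=manifest.get("ncc_class", NCC_CLASS),
        manifest=manifest,
    )
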