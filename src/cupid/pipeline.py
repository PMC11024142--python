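"""End-to-end pipeline orchestration: config validation, staged execution,
and a run manifest sufficient to reproduce every stage bit-identically."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from cupid import __version__
from cupid.array_conversion import build_calibration, convert_array_set, probe_to_window_beta
from cupid.dmr_selection import dedupe_regions, pairwise_dmrs, write_catalog
from cupid.ensemble import (
    TrainParams,
    hand_till_auroc,
    heldout_scores,
    save_model,
    train_ensemble,
)
from cupid.fragment_counts import calibrate_beta, nrpm, write_count_matrix
from cupid.genome_windows import find_overrepresented, write_bed
from cupid.mixture_simulator import mix_all, plan_mixtures, write_specs
from cupid.qc_metrics import (
    GenomeCpGIndex,
    gate_samples,
    qc_sample,
    write_panel,
)
from cupid.synthetic_data import (
    SyntheticConfig,
    make_class_arrays,
    make_ncc_counts,
    make_ncc_fragments,
    make_reference,
    pooled_control_counts,
)

logger = logging.getLogger(__name__)

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "out_dir", "synthetic", "mixtures", "dmr", "train", "convert", "qc"},
    "synthetic": {f.name for f in dataclasses.fields(SyntheticConfig)},
    "mixtures": {"per_class_cap", "tumour_proportions", "ncc_proportions", "depth_range"},
    "dmr": {"fdr", "n_top"},
    "train": {
        "n_members",
        "array_frac",
        "ncc_frac",
        "trees",
        "row_subsample",
        "feature_subsample_frac",
        "feature_subsample_count",
        "learning_rate",
    },
    "convert": {"library_size"},
    "qc": {"relh_min", "hf_min", "n_fragments"},
}


def validate_config(config: dict[str, Any]) -> None:
    """Reject unknown keys before any stage runs."""
    for section, allowed in _SCHEMA.items():
        block = config if section == "" else config.get(section, {})
        if not isinstance(block, dict):
            raise ValueError(f"config section {section or 'top level'!r} must be a mapping")
        unknown = set(block) - allowed - (set(_SCHEMA) if section == "" else set())
        if unknown:
            where = section or "top level"
            raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")
    if "seed" in config and not isinstance(config["seed"], int):
        raise ValueError("seed must be an integer")


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    validate_config(config)
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(seed: int, n: int = 10) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n)]


def run_pipeline(config: dict[str, Any] | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run simulate -> tile/mask -> qc -> calibrate -> convert -> dmr ->
    mix -> train -> held-out evaluation, writing artifacts and a manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        validate_config(config)
    out = Path(out_dir or config.get("out_dir", "cupid_run"))
    out.mkdir(parents=True, exist_ok=True)

    seed = int(config.get("seed", 0))
    seeds = _stage_seeds(seed)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": {
            name: seeds[i]
            for i, name in enumerate(
                ["reference", "arrays", "ncc", "mask", "qc", "convert", "mixtures", "train", "spare1", "spare2"]
            )
        },
        "config": config,
        "stages": {},
    }

    def record(stage: str, **info: Any) -> None:
        manifest["stages"][stage] = info
        logger.info("stage %s: %s", stage, info)

    cfg = SyntheticConfig(**config.get("synthetic", {}))

    # --- simulate + tile ---
    sequences, windows = make_reference(cfg, seed=seeds[0])
    fasta = out / "reference.fa"
    with open(fasta, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    record("tile", n_windows=len(windows), window_size=cfg.window_size)

    # --- mask over-represented windows from pooled control counts ---
    pooled = pooled_control_counts(cfg, windows, seed=seeds[3])
    report = find_overrepresented(pooled, windows)
    write_bed(windows, out / "windows.bed")
    record(
        "mask",
        n_primary=len(report.primary_masked),
        n_adjacent=len(report.adjacent_masked),
        q999=report.q999,
        q99=report.q99,
    )

    # --- NCC profiles + QC ---
    ncc_counts, panel = make_ncc_counts(cfg, windows, seed=seeds[2])
    write_count_matrix(ncc_counts, out / "ncc_counts.tsv")
    write_panel(panel, windows, out / "hyperstable_panel.bed")
    ncc_beta = calibrate_beta(nrpm(ncc_counts, windows), windows, sample_ids=ncc_counts.sample_ids)

    qc_cfg = config.get("qc", {})
    genome_index = GenomeCpGIndex.from_sequences(sequences)
    qc_results = []
    for i, sid in enumerate(ncc_counts.sample_ids):
        frags = make_ncc_fragments(
            cfg, windows, seed=seeds[4] + i, n_fragments=int(qc_cfg.get("n_fragments", 20_000))
        )
        qc_results.append(qc_sample(sid, frags, genome_index, ncc_beta.row(sid), panel))
    qc_table = gate_samples(
        qc_results,
        relh_min=float(qc_cfg.get("relh_min", 2.5)),
        hf_min=float(qc_cfg.get("hf_min", 0.4)),
    )
    qc_table.to_csv(out / "qc.tsv", sep="\t", index=False)
    record("qc", n_pass=int(qc_table["pass"].sum()), n_total=len(qc_table))

    # --- calibration + array conversion ---
    table = build_calibration(ncc_counts, ncc_beta, windows)
    table.write(out / "calibration.tsv")
    arrays, truth = make_class_arrays(cfg, windows, seed=seeds[1])
    window_beta = probe_to_window_beta(arrays, windows)
    window_beta.to_frame().to_csv(out / "array_window_beta.tsv", sep="\t", index=False)
    library_size = int(config.get("convert", {}).get("library_size", 100_000))
    converted = convert_array_set(window_beta, table, windows, library_size, seed=seeds[5])
    write_count_matrix(converted, out / "converted_counts.tsv")
    record("convert", n_arrays=len(arrays.sample_ids), library_size=library_size)

    # --- DMRs on pure (unmixed) array betas ---
    dmr_cfg = config.get("dmr", {})
    catalog = pairwise_dmrs(
        window_beta,
        arrays.labels,
        fdr=float(dmr_cfg.get("fdr", 0.001)),
        n_top=int(dmr_cfg.get("n_top", 250)),
    )
    write_catalog(catalog, out / "dmr_catalog.tsv")
    dmrs = dedupe_regions(catalog)
    pd.DataFrame(
        {"chrom": windows.chrom[dmrs], "start": windows.start[dmrs], "end": windows.end[dmrs], "name": dmrs}
    ).to_csv(out / "dmr_regions.bed", sep="\t", header=False, index=False)
    record("dmr", n_pairs=int(catalog[["class_a", "class_b"]].drop_duplicates().shape[0]), n_unique=len(dmrs))

    # --- mixtures ---
    mix_cfg = config.get("mixtures", {})
    array_labels = dict(zip(arrays.sample_ids, arrays.labels))
    plans = plan_mixtures(
        array_labels,
        ncc_counts.sample_ids,
        seed=seeds[6],
        per_class_cap=int(mix_cfg.get("per_class_cap", 10_000)),
        tumour_proportions=tuple(mix_cfg.get("tumour_proportions", (0.005, 0.10))),
        ncc_proportions=tuple(mix_cfg.get("ncc_proportions", (0.15, 0.50))),
        depth_range=tuple(int(x) for x in mix_cfg.get("depth_range", (50_000, 150_000))),
    )
    components = {sid: converted.counts[i] for i, sid in enumerate(converted.sample_ids)}
    components.update({sid: ncc_counts.counts[i] for i, sid in enumerate(ncc_counts.sample_ids)})
    mixtures = mix_all(plans, components)
    write_specs(plans, out / "mixture_specs.tsv")
    pd.DataFrame({"sample_id": mixtures.counts.sample_ids, "class_label": mixtures.labels}).to_csv(
        out / "mixture_labels.tsv", sep="\t", index=False
    )
    record("mix", n_mixtures=len(mixtures))

    # --- train + held-out evaluation ---
    train_cfg = config.get("train", {})
    params = TrainParams(
        n_members=int(train_cfg.get("n_members", 10)),
        array_frac=float(train_cfg.get("array_frac", 0.8)),
        ncc_frac=float(train_cfg.get("ncc_frac", 0.5)),
        trees=int(train_cfg.get("trees", 200)),
        row_subsample=float(train_cfg.get("row_subsample", 0.5)),
        feature_subsample_frac=float(train_cfg.get("feature_subsample_frac", 0.10)),
        feature_subsample_count=train_cfg.get("feature_subsample_count"),
        learning_rate=float(train_cfg.get("learning_rate", 0.1)),
    )
    model = train_ensemble(mixtures, dmrs, params, seed=seeds[7])
    save_model(model, out / "model")
    scores, n_eligible = heldout_scores(model, mixtures)
    eligible = n_eligible > 0
    labels = np.asarray(mixtures.labels, dtype=object)
    auroc = hand_till_auroc(scores[eligible], labels[eligible], classes=model.classes)
    score_df = pd.DataFrame(scores, columns=model.classes)
    score_df.insert(0, "sample_id", mixtures.counts.sample_ids)
    score_df.insert(1, "n_eligible_members", n_eligible)
    score_df.to_csv(out / "heldout_scores.tsv", sep="\t", index=False)
    record(
        "evaluate",
        heldout_auroc=float(auroc),
        n_eligible=int(eligible.sum()),
        n_zero_eligible=int((~eligible).sum()),
    )

    # --- manifest ---
    manifest["artifact_hashes"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.bed"))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
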