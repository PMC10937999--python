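"""End-to-end orchestration: simulate -> QC -> preprocess -> pool -> train
-> predict -> evaluate, as one seeded, reproducible run.

Maps are streamed one at a time (a full cohort of detector cubes does not
need to be resident); each map passes raw-spectrum QC and the five-step
pretreatment, surviving pixels are pooled per region-selection arm (center
window and/or embedding outlier mask), classifiers are trained on training
split pixels and evaluated on the held-out test samples. A manifest records
every parameter, per-stage pixel accounting (including samples dropped for
having zero QC-passing pixels), and output hashes for rerun verification.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import (FeatureSpec, ModelSpec, build_features, majority_vote,
                       predict_pool, train_model)
from .embedding import center_region_mask, embed_pixels, outlier_mask
from .evaluate import evaluate_predictions
from .io import PixelMask, PixelPool, concat_pools
from .preprocess import PreprocessParams, preprocess_map
from .qc import QCParams
from .synth import SyntheticConfig, cohort_metadata, iter_cohort

__all__ = ["RunConfig", "build_pools", "run_region", "run_pipeline"]


@dataclass
class RunConfig:
    """All stage configs plus the global seed and region/label modes."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    qc: QCParams = field(default_factory=QCParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    features: FeatureSpec = field(default_factory=FeatureSpec)
    models: tuple = tuple(
        ModelSpec(family=f) for f in
        ("lasso_lr", "ridge_lr", "svm", "fcnn", "cnn1d")
    )
    region_mode: str = "both"  # "center" | "pacmap" | "both"
    label_mode: str = "binary"
    center_fraction: float = 21.0 / 128.0  # center window edge / detector edge
    embedding_method: str = "umap"
    embedding_band: tuple = (1500.0, 1700.0)
    knn_k: int = 20
    outlier_percentile: float = 99.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_mode not in ("center", "pacmap", "both"):
            raise ValueError(f"unknown region_mode {self.region_mode!r}")

    def center_size(self, map_shape: tuple) -> int:
        """Center-window edge scaled to the map (21 px on the native 128)."""
        return max(1, round(min(map_shape) * self.center_fraction))


def _pool_from_map(pmap, mask_grid: np.ndarray, meta_row: dict) -> PixelPool:
    idx = np.argwhere(mask_grid)
    spectra = pmap.absorbance[mask_grid]
    rec = pd.DataFrame({
        "sample_id": meta_row["sample_id"],
        "row": idx[:, 0],
        "col": idx[:, 1],
        "mouse_id": meta_row["mouse_id"],
        "strain": meta_row["strain"],
        "dose_gy": meta_row["dose_gy"],
        "day": meta_row["day"],
        "split": meta_row["split"],
    })
    return PixelPool(records=rec, spectra=spectra, axis=pmap.axis)


def build_pools(config: RunConfig) -> dict:
    """Stream the cohort through pooling + QC + pretreatment per region arm.

    QC (SNR and CO2-ratio filters on raw spectra, then the lowest-noise cap)
    applies within each region's pixel pool per image: the center arm first
    restricts to the central window, then filters and caps; the embedding arm
    filters and caps the whole image, then removes embedding-space outliers
    across the cohort. Returns pools keyed by region mode, the QC summary
    table, and samples dropped because no pixel survived.
    """
    from .io import PixelMask as _PM
    from .qc import qc_mask, rank_and_cap

    want_center = config.region_mode in ("center", "both")
    want_pacmap = config.region_mode in ("pacmap", "both")
    center_pools, qc_pools, qc_rows, dropped = [], [], [], []
    map_shape = config.synthetic.map_shape
    center = (center_region_mask(map_shape, config.center_size(map_shape))
              if want_center else None)
    for m, row in iter_cohort(config.synthetic):
        raw = qc_mask(m, config.qc)
        pmap, info = preprocess_map(m, config.preprocess, return_info=True)
        usable = raw.accepted & info["normalized_ok"] & ~info["dead"].accepted
        summary = {"sample_id": row["sample_id"],
                   "n_accepted_raw": raw.n_accepted,
                   "n_usable": int(usable.sum())}
        survived = False
        if want_center:
            pool_mask = _PM(usable & center.accepted, provenance="qc&center")
            capped = rank_and_cap(m, pool_mask, config.qc)
            summary["n_center"] = capped.n_accepted
            if capped.n_accepted:
                center_pools.append(_pool_from_map(pmap, capped.accepted, row))
                survived = True
        if want_pacmap:
            capped = rank_and_cap(m, _PM(usable, provenance="qc"), config.qc)
            summary["n_retained"] = capped.n_accepted
            if capped.n_accepted:
                qc_pools.append(_pool_from_map(pmap, capped.accepted, row))
                survived = True
        qc_rows.append(summary)
        if not survived:
            dropped.append(row["sample_id"])
            continue

    pools: dict = {}
    if want_center:
        pools["center"] = concat_pools(center_pools) if center_pools else None
    if want_pacmap and qc_pools:
        qc_pool = concat_pools(qc_pools)
        emb = embed_pixels(
            qc_pool, band=config.embedding_band, seed=config.seed,
            method=config.embedding_method,
        )
        masks = outlier_mask(
            emb, k=min(config.knn_k, qc_pool.n_pixels - 1),
            percentile=config.outlier_percentile, map_shape=map_shape,
        )
        pools["pacmap"] = qc_pool.subset(emb.accepted)
        pools["pacmap_masks"] = masks
    elif want_pacmap:
        pools["pacmap"] = None
    return {
        "pools": pools,
        "qc_summary": pd.DataFrame(qc_rows),
        "dropped_samples": dropped,
    }


def run_region(pool: PixelPool, config: RunConfig) -> dict:
    """Train every model family on the region's train split, evaluate on test.

    Train/test separation is at the sample level by construction; asserted
    before fitting.
    """
    split = pool.records["split"].to_numpy()
    train_pool = pool.subset(split == "train")
    test_pool = pool.subset(split == "test")
    overlap = set(train_pool.sample_ids) & set(test_pool.sample_ids)
    if overlap:
        raise AssertionError(f"sample leakage across splits: {sorted(overlap)}")
    Xtr, ytr, waves = build_features(train_pool, config.features,
                                     config.label_mode)
    results: dict = {"n_train_pixels": int(len(ytr)),
                     "n_test_pixels": int(test_pool.n_pixels),
                     "models": {}}
    for spec in config.models:
        spec = dataclasses.replace(spec, seed=config.seed + spec.seed)
        model = train_model(spec, Xtr, ytr)
        pred = predict_pool(model, test_pool, config.features)
        report = evaluate_predictions(
            pred.sample_votes,
            pixel_labels=pred.pixel_labels,
            pixel_truth=test_pool.exposed_labels(),
        )
        results["models"][spec.family] = {
            "report": report,
            "votes": pred.sample_votes,
            "spec": spec,
        }
    results["feature_wavenumbers"] = waves
    return results


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _metrics_dict(region_results: dict) -> dict:
    out = {}
    for fam, res in region_results["models"].items():
        r = res["report"]
        out[fam] = {
            "pixel_accuracy": r.pixel_accuracy,
            "sample_accuracy": r.sample_accuracy,
            "balanced_accuracy": r.balanced_accuracy,
            "auc": r.auc,
            "spec_at_sens": r.spec_at_sens,
        }
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Full run; optionally writes cohort/QC/vote/report artifacts to disk."""
    staged = build_pools(config)
    results: dict = {"regions": {}}
    for region in ("center", "pacmap"):
        pool = staged["pools"].get(region)
        if pool is None:
            continue
        results["regions"][region] = run_region(pool, config)

    metrics = {r: _metrics_dict(res) for r, res in results["regions"].items()}
    manifest = {
        "config": {
            "synthetic": dataclasses.asdict(config.synthetic),
            "qc": dataclasses.asdict(config.qc),
            "preprocess": dataclasses.asdict(config.preprocess),
            "features": dataclasses.asdict(config.features),
            "models": [dataclasses.asdict(m) for m in config.models],
            "region_mode": config.region_mode,
            "seed": config.seed,
        },
        "n_samples": int(len(cohort_metadata(config.synthetic))),
        "dropped_samples": staged["dropped_samples"],
        "n_dropped": len(staged["dropped_samples"]),
        "metrics": metrics,
        "metrics_hash": _hash_obj(metrics),
    }
    results["manifest"] = manifest
    results["qc_summary"] = staged["qc_summary"]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort_metadata(config.synthetic).to_csv(out / "cohort.csv", index=False)
        staged["qc_summary"].to_csv(out / "qc_summary.csv", index=False)
        for region, res in results["regions"].items():
            for fam, r in res["models"].items():
                r["votes"].to_csv(out / f"preds_{region}_{fam}.csv", index=False)
        with open(out / "report.json", "w") as f:
            json.dump(manifest, f, indent=2, default=str)
    return results
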