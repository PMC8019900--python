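"""End-to-end orchestration of the classification pipeline.

Glues the stage modules together for the synthetic-data workflow used by the
command-line interface and the acceptance checks: generate or load a dataset,
preprocess, extract feature blocks, select features on the training cohort,
fit per-arm SVMs and evaluate on the held-out cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classify, deepfeat, evaluate, handcrafted, preprocess, select, synthdata

__all__ = ["ArmResult", "PipelineResult", "preprocess_dataset", "run_pipeline"]

CROP_THRESHOLD = 0.05  # synthetic backgrounds carry faint noise


@dataclass
class ArmResult:
    name: str
    report: evaluate.EvaluationReport
    scores: np.ndarray
    best_c: float
    clf: classify.TrainedClassifier | None = None


@dataclass
class PipelineResult:
    arms: dict[str, ArmResult]
    delong: dict[tuple[str, str], evaluate.DeLongResult]
    split: preprocess.CohortSplit
    hcr_selection: select.SelectionResult | None
    deep_selection: select.SelectionResult | None
    test_labels: np.ndarray


def preprocess_dataset(rois, crop_threshold: float = CROP_THRESHOLD) -> list[preprocess.PreprocessedROI]:
    out = []
    for roi in rois:
        cropped = preprocess.crop_background(roi, threshold=crop_threshold)
        norm = preprocess.min_max_normalize(cropped.pixels)
        out.append(preprocess.pad_resize(norm, parent=cropped))
    return out


def _handcrafted_table(prois) -> pd.DataFrame:
    bank = handcrafted.GaborBank()
    rows = [handcrafted.extract_handcrafted(p, bank=bank).values for p in prois]
    return pd.DataFrame(rows, index=[p.roi_id for p in prois], columns=list(handcrafted.FEATURE_NAMES))


def _deep_table(prois, seed: int, train_ids, labels: pd.Series, epochs: int) -> pd.DataFrame:
    net = deepfeat.build_fusion_network(deepfeat.FusionNetworkSpec(seed=seed))
    train = [p for p in prois if p.roi_id in set(train_ids)]
    y = [labels.loc[p.roi_id] for p in train]
    cfg = deepfeat.TrainConfig(epochs=epochs, learning_rate=0.01, seed=seed)
    deepfeat.fine_tune(net, train, y, cfg)
    vecs = deepfeat.extract_deep_features(net, prois)
    return pd.DataFrame(
        [v.values for v in vecs],
        index=[p.roi_id for p in prois],
        columns=[f"d{i:04d}" for i in range(1, deepfeat.FC2_DIM + 1)],
    )


def run_pipeline(
    spec: synthdata.SyntheticSpec,
    arms: tuple[str, ...] = ("Hcr", "Clinical", "Hcr+Clinical"),
    train_fraction: float = preprocess.DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
    k_hcr: int = select.DEFAULT_K_HANDCRAFTED,
    k_deep: int = select.DEFAULT_K_DEEP,
    deep_epochs: int = 30,
    delong_pairs: tuple[tuple[str, str], ...] = (),
    dataset: synthdata.SyntheticDataset | None = None,
) -> PipelineResult:
    """Run the requested model arms on a synthetic dataset and evaluate held-out.

    Feature selection and all scalers are fitted on the training cohort only.
    """
    for arm in arms:
        if arm not in classify.ARM_BLOCKS:
            raise ValueError(f"unknown model arm: {arm}")
    ds = dataset if dataset is not None else synthdata.generate_dataset(spec)
    prois = preprocess_dataset(ds.rois)
    split = preprocess.split_cohorts(ds.rois, train_fraction=train_fraction, seed=seed, mode="by_roi")
    train_ids, test_ids = split.train_ids, split.test_ids
    labels = ds.labels

    need = {blk for arm in arms for blk in classify.ARM_BLOCKS[arm]}
    blocks_train: dict[str, np.ndarray] = {}
    blocks_test: dict[str, np.ndarray] = {}
    hcr_sel = deep_sel = None

    if "clinical" in need:
        records = {
            rid: classify.encode_clinical(
                classify.ClinicalRecord(
                    shape_code=int(row["shape"]),
                    margin_code=int(row["margin"]),
                    composition_code=int(row["composition"]),
                    age_years=float(row["age"]),
                    mass_size=float(row["mass_size"]),
                )
            )
            for rid, row in ds.clinical.iterrows()
        }
        blocks_train["clinical"] = np.vstack([records[r] for r in train_ids])
        blocks_test["clinical"] = np.vstack([records[r] for r in test_ids])

    if "hcr" in need:
        hcr_all = _handcrafted_table(prois)
        hcr_sel = select.mrmr_rank(hcr_all.loc[train_ids], labels.loc[train_ids], k=min(k_hcr, hcr_all.shape[1]))
        cols = hcr_sel.ranked_names
        blocks_train["hcr"] = hcr_all.loc[train_ids, cols].to_numpy()
        blocks_test["hcr"] = hcr_all.loc[test_ids, cols].to_numpy()

    if "deep" in need:
        deep_all = _deep_table(prois, seed, train_ids, labels, deep_epochs)
        deep_sel = select.mrmr_rank(deep_all.loc[train_ids], labels.loc[train_ids], k=min(k_deep, deep_all.shape[1]))
        cols = deep_sel.ranked_names
        blocks_train["deep"] = deep_all.loc[train_ids, cols].to_numpy()
        blocks_test["deep"] = deep_all.loc[test_ids, cols].to_numpy()

    y_train = (labels.loc[train_ids] == "malignant").to_numpy().astype(int)
    y_test = (labels.loc[test_ids] == "malignant").to_numpy().astype(int)

    results: dict[str, ArmResult] = {}
    for arm in arms:
        Xtr = np.hstack([blocks_train[b] for b in classify.ARM_BLOCKS[arm]])
        Xte = np.hstack([blocks_test[b] for b in classify.ARM_BLOCKS[arm]])
        scaler = classify.MinMaxScaler.fit(Xtr)
        clf = classify.train_svm(X=scaler.transform(Xtr), y=y_train, seed=seed, scaler=scaler)
        _, scores = classify.predict(clf, X=scaler.transform(Xte))
        report = evaluate.evaluate_scores(scores, y_test)
        results[arm] = ArmResult(name=arm, report=report, scores=scores, best_c=clf.best_c, clf=clf)

    delong: dict[tuple[str, str], evaluate.DeLongResult] = {}
    for a, b in delong_pairs:
        if a not in results or b not in results:
            raise ValueError(f"DeLong pair ({a}, {b}) not among the evaluated arms")
        delong[(a, b)] = evaluate.delong_test(results[a].scores, results[b].scores, y_test)

    return PipelineResult(
        arms=results,
        delong=delong,
        split=split,
        hcr_selection=hcr_sel,
        deep_selection=deep_sel,
        test_labels=y_test,
    )
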