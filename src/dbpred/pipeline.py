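"""Convenience drivers tying the encoders, fusion and models together."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import infotheory, ksng, ssf
from .fusion import concat_features
from .io_formats import (
    FeatureMatrix,
    LabeledDataset,
    PSSMProfile,
    ProteinSequence,
    SecondaryStructureProfile,
)

#: The three encoder names accepted by :func:`encode_features`; any non-empty
#: subset yields one of the seven single/mixed feature sets.
ENCODERS: tuple[str, ...] = ("it", "ksng", "ssf")


def encode_features(
    sequences: list[ProteinSequence],
    feature_sets: Sequence[str] = ("it",),
    pssms: list[PSSMProfile] | None = None,
    ss_profiles: list[SecondaryStructureProfile] | None = None,
    ksng_cfg: ksng.KSNGConfig | None = None,
    ssf_cfg: ssf.SSFConfig | None = None,
) -> FeatureMatrix:
    """Encode sequences with any subset of {it, ksng, ssf} and fuse the blocks.

    ``ssf`` requires one PSSM and one secondary-structure profile per
    sequence, in the same order.
    """
    if not feature_sets:
        raise ValueError("at least one feature set required")
    unknown = set(feature_sets) - set(ENCODERS)
    if unknown:
        raise ValueError(f"unknown feature sets {sorted(unknown)}")
    blocks: list[FeatureMatrix] = []
    for name in ENCODERS:  # fixed block order regardless of flag order
        if name not in feature_sets:
            continue
        if name == "it":
            blocks.append(infotheory.encode_dataset(sequences))
        elif name == "ksng":
            blocks.append(ksng.encode_dataset(sequences, ksng_cfg))
        else:
            if pssms is None or ss_profiles is None:
                raise ValueError(
                    "the ssf feature set needs PSSM and secondary-structure "
                    "profiles for every sequence"
                )
            block = ssf.encode_dataset(pssms, ss_profiles, ssf_cfg)
            if block.sample_ids != [s.identifier for s in sequences]:
                raise ValueError("profile order does not match sequence order")
            blocks.append(block)
    return concat_features(blocks)


def make_labeled(fm: FeatureMatrix, labels: np.ndarray) -> LabeledDataset:
    return LabeledDataset(features=fm, labels=np.asarray(labels, dtype=int))


def cv_with_selection(
    ds: LabeledDataset,
    m: int,
    k: int = 10,
    seed: int = 0,
    classifier: str = "svm",
    relevance_weight: float = 1.0,
    distance_weight: float = 1.0,
):
    """Stratified k-fold CV with MRMD selection re-fit inside each fold.

    Ranking the features on the full dataset and then cross-validating on
    the same samples leaks the selection step and inflates accuracy on
    uninformative labels, so the honest estimate ranks and selects on each
    training fold only, applying the selected columns to the held-out fold.
    Returns the mean fold accuracy and the per-fold reports.
    """
    from sklearn.model_selection import StratifiedKFold

    from .fusion import mrmd_rank, mrmd_select
    from .models import (
        ModelSpec,
        metrics_from_predictions,
        predict,
        train_classifier,
    )

    spec = ModelSpec(kind=classifier)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for train_idx, test_idx in skf.split(ds.features.values, ds.labels):
        train_ds = ds.subset(train_idx)
        ranking = mrmd_rank(
            train_ds,
            relevance_weight=relevance_weight,
            distance_weight=distance_weight,
        )
        m_eff = min(m, train_ds.features.n_features)
        selected = mrmd_select(train_ds, ranking, m=m_eff)
        model = train_classifier(
            LabeledDataset(features=selected, labels=train_ds.labels),
            spec,
            seed=seed,
        )
        test_fm = ds.subset(test_idx).features.select_columns(
            selected.feature_names
        )
        pred = predict(model, test_fm)
        reports.append(metrics_from_predictions(ds.labels[test_idx], pred))
    mean_acc = float(np.mean([r.acc for r in reports]))
    return mean_acc, reports
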