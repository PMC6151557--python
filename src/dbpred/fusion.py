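"""Feature fusion and max-relevance-max-distance (MRMD) dimension reduction.

Mixed feature sets are plain column-wise concatenations of encoder blocks.
MRMD ranks each feature by a weighted sum of

* *relevance* — the absolute Pearson correlation between the feature column
  and the 0/1 class label (zero-variance columns score 0), and
* *distance* — the mean Euclidean distance between the standardised feature
  column and every other standardised column, scaled by the largest such
  mean so the component lies in [0, 1];

and keeps the top-m features. Because columns are standardised first, the
ranking is invariant to affine rescaling of any feature. The weight ratio
between the two components is configurable; the default weights both
equally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import FeatureMatrix, LabeledDataset

#: m values tried by the automatic sweep (clipped to the matrix width).
AUTO_M_GRID: tuple[int, ...] = (1, 2, 5, 10, 20, 50, 100, 200)


@dataclass
class MRMDRanking:
    """Per-feature relevance/distance scores and the induced ordering.

    ``feature_order`` lists original column indices sorted by the combined
    score, descending; ties keep the original column order.
    """

    feature_names: list[str]
    relevance: np.ndarray
    distance: np.ndarray
    combined: np.ndarray
    feature_order: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature": self.feature_names,
                "relevance": self.relevance,
                "distance": self.distance,
                "combined": self.combined,
            }
        )
        rank = np.empty(len(self.feature_order), dtype=int)
        rank[self.feature_order] = np.arange(1, len(self.feature_order) + 1)
        df["rank"] = rank
        return df.sort_values("rank").reset_index(drop=True)


def concat_features(blocks: list[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation of encoder blocks over identical samples."""
    if not blocks:
        raise ValueError("no feature blocks to concatenate")
    first = blocks[0]
    for block in blocks[1:]:
        if block.sample_ids != first.sample_ids:
            missing = sorted(
                set(first.sample_ids).symmetric_difference(block.sample_ids)
            )
            raise ValueError(
                "feature blocks cover different samples (or a different "
                f"order); mismatched ids: {missing[:10] or 'ordering only'}"
            )
    if len(blocks) == 1:
        return first
    names: list[str] = []
    for block in blocks:
        names.extend(block.feature_names)
    return FeatureMatrix(
        sample_ids=list(first.sample_ids),
        feature_names=names,
        values=np.hstack([b.values for b in blocks]),
    )


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd_safe


def mrmd_rank(
    ds: LabeledDataset,
    relevance_weight: float = 1.0,
    distance_weight: float = 1.0,
) -> MRMDRanking:
    """Score and order features by combined relevance and distance."""
    labels = ds.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("MRMD ranking requires both classes present")
    x = ds.features.values
    n, d = x.shape
    if n < 2:
        raise ValueError("MRMD ranking requires at least 2 samples")

    z = _standardize_columns(x)
    y = (labels - labels.mean()) / labels.std()

    # relevance: |Pearson r| with the label; constant columns get 0
    col_sd = x.std(axis=0)
    relevance = np.abs(z.T @ y) / n
    relevance[col_sd == 0] = 0.0

    # distance: mean Euclidean distance between standardized columns
    gram = z.T @ z
    sq_norms = np.diag(gram)
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * gram
    np.fill_diagonal(d2, 0.0)
    dist_matrix = np.sqrt(np.maximum(d2, 0.0))
    if d > 1:
        mean_dist = dist_matrix.sum(axis=1) / (d - 1)
    else:
        mean_dist = np.zeros(1)
    max_dist = mean_dist.max()
    distance = mean_dist / max_dist if max_dist > 0 else np.zeros(d)

    combined = relevance_weight * relevance + distance_weight * distance
    # stable sort keeps the original index on ties
    feature_order = np.argsort(-combined, kind="stable")
    return MRMDRanking(
        feature_names=list(ds.features.feature_names),
        relevance=relevance,
        distance=distance,
        combined=combined,
        feature_order=feature_order,
    )


def mrmd_select(
    ds: LabeledDataset,
    ranking: MRMDRanking,
    m: int | str = "auto",
    classifier: str = "svm",
    seed: int = 0,
) -> FeatureMatrix:
    """Keep the top-m ranked features (columns reordered by rank).

    With ``m='auto'`` the geometric grid ``1, 2, 5, ..., 200, all`` is swept
    and the smallest m maximising 5-fold cross-validated accuracy of the
    configured classifier is kept.
    """
    d = ds.features.n_features
    if m == "auto":
        m = _auto_m(ds, ranking, classifier=classifier, seed=seed)
    m = int(m)
    if not 1 <= m <= d:
        raise ValueError(f"m must be in 1..{d}, got {m}")
    keep = ranking.feature_order[:m]
    names = [ds.features.feature_names[i] for i in keep]
    return FeatureMatrix(
        sample_ids=list(ds.features.sample_ids),
        feature_names=names,
        values=ds.features.values[:, keep],
    )


def _auto_m(
    ds: LabeledDataset, ranking: MRMDRanking, classifier: str, seed: int
) -> int:
    from .models import ModelSpec, k_fold_cv

    d = ds.features.n_features
    grid = sorted({min(m, d) for m in AUTO_M_GRID} | {d})
    spec = ModelSpec(kind=classifier)
    best_m, best_acc = d, -1.0
    for m in grid:
        keep = ranking.feature_order[:m]
        sub = LabeledDataset(
            features=FeatureMatrix(
                sample_ids=list(ds.features.sample_ids),
                feature_names=[ds.features.feature_names[i] for i in keep],
                values=ds.features.values[:, keep],
            ),
            labels=ds.labels,
        )
        acc, _ = k_fold_cv(sub, k=5, spec=spec, seed=seed)
        if acc > best_acc:  # strict: ties keep the smaller m
            best_m, best_acc = m, acc
    return best_m
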