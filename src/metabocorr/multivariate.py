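"""PCA overview of a run and a reproducible low-total-signal outlier flag.

PCA follows the workflow's convention exactly: missing values are replaced
by zero, every feature is centred and scaled to unit variance, and the
leading components are inspected.  Zero-imputation before scaling biases
variances for sparsely detected features; it is kept as a fidelity choice
(the convention of the workflow being reproduced) rather than a statistical
recommendation.

The outlier flag formalises a manual practice: an injection whose total
peak area is far below the rest (for example a failed injection) is flagged
when its total non-missing peak area lies more than ``k`` median absolute
deviations below the median biological total.  Flagging is advisory —
removal is a separate, explicit pipeline action.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import StageError
from .peaktable import FeatureTable


@dataclass
class PCAResult:
    scores: pd.DataFrame                    # injection x component
    loadings: pd.DataFrame                  # feature x component
    explained_variance_fraction: np.ndarray
    n_components: int
    dropped_features: list                  # zero-variance after imputation


def pca_scores(table: FeatureTable, n_components: int = 3) -> PCAResult:
    """PCA on zero-imputed, autoscaled intensities (samples as observations).

    Component signs are fixed by making each loading's largest-magnitude
    entry positive, so results are reproducible across feature orderings.
    """
    if table.n_samples < 2:
        raise StageError("PCA needs at least two injections")
    X = table.intensities.to_numpy(dtype=float).T   # sample x feature
    X = np.nan_to_num(X, nan=0.0)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = list(table.intensities.index[~keep])
    X = (X[:, keep] - mean[keep]) / sd[keep]
    n_components = min(n_components, min(X.shape) - 0 if min(X.shape) < n_components else n_components)
    n_components = min(n_components, X.shape[0] - 1 if X.shape[0] > 1 else 1, X.shape[1])
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T          # feature x component

    # deterministic sign: largest |loading| entry positive per component
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.intensities.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=table.intensities.index[keep],
                              columns=comp_names),
        explained_variance_fraction=model.explained_variance_ratio_,
        n_components=n_components,
        dropped_features=dropped,
    )


def flag_outliers(table: FeatureTable, k: float = 5.0) -> list:
    """Flag biological injections with anomalously low total peak area.

    A sample is flagged when its total non-missing intensity is more than
    ``k`` median absolute deviations below the median total over biological
    samples.  Returns (sample_id, reason) pairs; advisory only.
    """
    bio_ids = table.manifest.biological_ids()
    if len(bio_ids) < 4:
        raise StageError("outlier flagging needs at least 4 biological injections")
    totals = table.intensities[bio_ids].sum(axis=0, skipna=True)
    med = float(totals.median())
    mad = float((totals - med).abs().median())
    cutoff = med - k * mad
    flagged = []
    for sid, total in totals.items():
        if total < cutoff:
            flagged.append((
                sid,
                f"total peak area {total:.4g} more than {k:g} MADs below the "
                f"biological median {med:.4g}",
            ))
    return flagged
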