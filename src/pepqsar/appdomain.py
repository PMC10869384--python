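"""Applicability-domain screening by the standardization approach.

Each query descriptor value is standardised against the training set,
S_j = |x_j - mean_j| / sd_j.  A peptide is outside the domain when every
descriptor is anomalous (min_j S_j > threshold), inside when none is
(max_j S_j <= threshold), and in the intermediate case inside only when
mean(S) + 1.28 * sd(S) <= threshold, i.e. when roughly 90% of its
descriptors are expected below the cutoff under a normal model of S.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ADModel", "ad_fit", "ad_flag"]


@dataclass(frozen=True)
class ADModel:
    """Per-column training statistics defining the applicability domain."""

    means: np.ndarray
    sds: np.ndarray
    threshold: float = 3.0
    z_factor: float = 1.28
    columns: tuple[int, ...] | None = None  # 1-based X-indices, informational

    def __post_init__(self) -> None:
        if np.any(self.sds < 0):
            raise ValueError("negative standard deviation")


def ad_fit(
    X_train: np.ndarray,
    threshold: float = 3.0,
    z_factor: float = 1.28,
    columns: Sequence[int] | None = None,
) -> ADModel:
    """Fit the domain from training rows already restricted to model columns."""
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 training rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.where(sds == 0)[0]
    if zero.size:
        raise ValueError(f"zero-variance column at index {int(zero[0])} (0-based)")
    return ADModel(
        means=means,
        sds=sds,
        threshold=threshold,
        z_factor=z_factor,
        columns=None if columns is None else tuple(int(c) for c in columns),
    )


def ad_flag(model: ADModel, X_query: np.ndarray, ids: Sequence | None = None) -> pd.DataFrame:
    """Flag each query row inside/outside the training domain.

    Returns a DataFrame with per-row min/max/mean S, the 1.28-rule score
    ``s_rule = mean(S) + z_factor * sd(S)`` (sample sd over the row's
    descriptors), and a boolean ``inside``.
    """
    X = np.atleast_2d(np.asarray(X_query, dtype=float))
    if X.shape[1] != model.means.size:
        raise ValueError(
            f"column mismatch: domain has {model.means.size}, query has {X.shape[1]}"
        )
    S = np.abs(X - model.means) / model.sds
    s_min, s_max, s_mean = S.min(axis=1), S.max(axis=1), S.mean(axis=1)
    s_sd = S.std(axis=1, ddof=1) if S.shape[1] > 1 else np.zeros(S.shape[0])
    s_rule = s_mean + model.z_factor * s_sd
    thr = model.threshold
    inside = np.where(
        s_max <= thr,
        True,
        np.where(s_min > thr, False, s_rule <= thr),
    )
    index = ids if ids is not None else range(X.shape[0])
    return pd.DataFrame(
        {
            "s_min": s_min,
            "s_max": s_max,
            "s_mean": s_mean,
            "s_rule": s_rule,
            "inside": inside.astype(bool),
        },
        index=index,
    )
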