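"""Synthetic spiked expression-profile generator with ground-truth labels.

Emulates a four-condition expression experiment in which most genes follow
one of four characteristic profiles and a minority follow deviant "spike"
profiles.  Rows are drawn as the centre profile plus i.i.d. Gaussian noise
per condition.  The default sizing — 25 genes per base profile plus 5 per
spike shape, 120 genes over 4 conditions — gives separable clusters with a
known outlier structure, which is exactly what is needed to exercise
consensus clustering, robustness scoring and ΔK cluster-number estimation
end to end without external data.

Note that the third spike shape coincides with base profile 3: such rows are
ordinary members of that profile's cluster and are deliberately kept labelled
as spikes in the ground truth, so downstream checks can distinguish
"spike by construction" from "outlier in effect".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix

__all__ = ["BASE_PROFILES", "SPIKE_PROFILES", "SyntheticTruth", "simulate_profiles"]

#: the four characteristic 4-condition profiles
BASE_PROFILES = np.array(
    [[1, 0, 1, 1],
     [0, 1, 1, 0],
     [1, 1, 0, 0],
     [0, 1, 0, 0]], dtype=float
)

#: the four deviant profiles used to spike the data
SPIKE_PROFILES = np.array(
    [[1, 1, 1, 1],
     [0, 0, 1, 1],
     [1, 1, 0, 0],
     [0.5, 0.5, 0, 0]], dtype=float
)

CONDITION_IDS = ["c1", "c2", "c3", "c4"]


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated matrix.

    ``true_profile`` maps every feature to its base-profile index (1..4);
    spike rows are assigned the nearest base profile by Euclidean distance
    (ties toward the lower index).  ``spike_shape`` maps spike features to
    their spike-profile index (1..4).
    """

    true_profile: dict[str, int]
    is_spike: dict[str, bool]
    spike_shape: dict[str, int]
    sigma: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": list(self.true_profile),
                "true_profile": list(self.true_profile.values()),
                "is_spike": [self.is_spike[f] for f in self.true_profile],
                "spike_shape": [self.spike_shape.get(f, 0) for f in self.true_profile],
            }
        )


def _nearest_base(profile: np.ndarray) -> int:
    d = np.linalg.norm(BASE_PROFILES - profile, axis=1)
    return int(np.argmin(d)) + 1  # argmin ties toward the lower index


def simulate_profiles(
    n_per_profile: int = 25,
    sigma: float = 0.1,
    seed: int = 0,
    spike_counts: Sequence[int] = (5, 5, 5, 5),
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a spiked profile matrix and its ground truth.

    Parameters
    ----------
    n_per_profile : int
        Genes drawn around each of the four base profiles (default 25).
    sigma : float
        Standard deviation of the per-condition Gaussian noise (default 0.1;
        profile levels are on a 0–1 scale, so 0.1 is clearly visible yet
        leaves the base profiles separable).
    seed : int
        Generator seed; identical parameters and seed reproduce the matrix
        bitwise.
    spike_counts : sequence of four ints
        Rows per spike shape (default 5 each, for 120 genes in total).
    """
    if sigma < 0:
        raise ValueError(f"sigma must be nonnegative, got {sigma}")
    if n_per_profile < 0 or any(c < 0 for c in spike_counts):
        raise ValueError("row counts must be nonnegative")
    if len(spike_counts) != len(SPIKE_PROFILES):
        raise ValueError(f"expected {len(SPIKE_PROFILES)} spike counts")
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    true_profile: dict[str, int] = {}
    is_spike: dict[str, bool] = {}
    spike_shape: dict[str, int] = {}
    counter = 0
    total = len(BASE_PROFILES) * n_per_profile + int(np.sum(spike_counts))
    width = max(3, len(str(total)))

    def _next_id() -> str:
        nonlocal counter
        counter += 1
        return f"g{counter:0{width}d}"

    for p, centre in enumerate(BASE_PROFILES, start=1):
        for _ in range(n_per_profile):
            fid = _next_id()
            rows.append(centre + rng.normal(0.0, sigma, size=centre.shape))
            true_profile[fid] = p
            is_spike[fid] = False
    for s, centre in enumerate(SPIKE_PROFILES, start=1):
        for _ in range(spike_counts[s - 1]):
            fid = _next_id()
            rows.append(centre + rng.normal(0.0, sigma, size=centre.shape))
            true_profile[fid] = _nearest_base(centre)
            is_spike[fid] = True
            spike_shape[fid] = s
    matrix = ExpressionMatrix(np.array(rows), list(true_profile), CONDITION_IDS)
    truth = SyntheticTruth(true_profile, is_spike, spike_shape, float(sigma), int(seed))
    return matrix, truth
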