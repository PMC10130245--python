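"""Ordinal reader-score simulation.

Radiologist ratings on a 1-5 Likert scale (stent appearance, blooming,
inter-stent visibility) are emulated with a cumulative-threshold model: each
item has a latent quality, each reader a fixed additive bias, and every
rating adds Gaussian perceptual noise before the latent value is cut into
five ordered categories by four ascending cut points.  The same item is
rated in multiple sessions (independent noise draws) so intra-reader
reliability can be computed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError

METRIC_LABELS = ("stent_appearance", "blooming", "inter_stent_visibility")


@dataclass
class ReaderScores:
    """items x readers x sessions array of integer scores in 1..5."""

    scores: np.ndarray
    metric_label: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 3:
            raise InvalidParameterError("scores must be items x readers x sessions")
        if not np.isin(self.scores, [1, 2, 3, 4, 5]).all():
            raise InvalidParameterError("every score must be an integer in 1..5")

    @property
    def n_items(self) -> int:
        return self.scores.shape[0]

    @property
    def n_readers(self) -> int:
        return self.scores.shape[1]

    @property
    def n_sessions(self) -> int:
        return self.scores.shape[2]


def simulate_reader_scores(
    latent_quality_per_item: Sequence[float],
    reader_bias: Sequence[float],
    cut_points: Sequence[float],
    noise_sd: float,
    seed,
    n_sessions: int = 2,
    metric_label: str = "stent_appearance",
) -> ReaderScores:
    """Draw ordinal scores from the cumulative-threshold model.

    score = 1 + number of cut points lying below latent + bias + noise.
    Deterministic for a fixed seed; with ``noise_sd = 0`` the scores are a
    deterministic function of latent + bias.
    """
    latent = np.asarray(list(latent_quality_per_item), dtype=float)
    bias = np.asarray(list(reader_bias), dtype=float)
    cuts = np.asarray(list(cut_points), dtype=float)
    if cuts.size != 4 or not np.all(np.diff(cuts) > 0):
        raise InvalidParameterError("cut_points must be 4 strictly ascending values")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    if n_sessions < 1:
        raise InvalidParameterError("n_sessions must be >= 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    val = latent[:, None, None] + bias[None, :, None]
    val = np.broadcast_to(val, (latent.size, bias.size, n_sessions)).astype(float)
    if noise_sd > 0:
        val = val + rng.normal(0.0, noise_sd, size=val.shape)
    scores = 1 + (val[..., None] > cuts).sum(axis=-1)
    return ReaderScores(scores.astype(int), metric_label=metric_label)
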