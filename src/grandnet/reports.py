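"""Posterior report containers shared by the two inference routes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class DiscreteDist:
    """A normalized distribution on a finite support."""

    support: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        total = float(np.sum(self.probabilities))
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"probabilities sum to {total}, not 1")

    @property
    def mean(self) -> float:
        return float(np.sum(self.support * self.probabilities))

    def to_dict(self) -> dict:
        return {
            "support": np.asarray(self.support).tolist(),
            "probabilities": np.asarray(self.probabilities).tolist(),
        }


@dataclass
class PosteriorReport:
    """Posterior over the network size plus per-node parameter posteriors.

    ``log_weights`` are the unnormalized log posterior weights on ``N_grid``;
    ``probabilities`` their normalization.  ``node_posteriors`` holds one
    distribution per sampled node (degree or latent variable, depending on
    the inference route).  ``diagnostics`` records solver values and
    residuals; ``boundary_flags`` marks > 1% posterior mass at either end of
    the N grid (a sign the grid should be widened).
    """

    N_grid: np.ndarray
    log_weights: np.ndarray
    probabilities: np.ndarray
    node_posteriors: list[DiscreteDist] | None = None
    diagnostics: dict = field(default_factory=dict)
    boundary_flags: dict = field(default_factory=dict)

    @property
    def mode(self) -> int:
        return int(self.N_grid[int(np.argmax(self.probabilities))])

    @property
    def mean(self) -> float:
        return float(np.sum(self.N_grid * self.probabilities))

    def quantile(self, p: float) -> int:
        cdf = np.cumsum(self.probabilities)
        return int(self.N_grid[int(np.searchsorted(cdf, p))])

    def credible_interval(self, level: float = 0.9) -> tuple[int, int]:
        """Central credible interval for N."""
        alpha = (1.0 - level) / 2.0
        return self.quantile(alpha), self.quantile(1.0 - alpha)

    def to_dict(self) -> dict:
        out = {
            "N_grid": self.N_grid.tolist(),
            "log_weights": self.log_weights.tolist(),
            "probabilities": self.probabilities.tolist(),
            "mode": self.mode,
            "mean": self.mean,
            "diagnostics": _jsonable(self.diagnostics),
            "boundary_flags": _jsonable(self.boundary_flags),
        }
        if self.node_posteriors is not None:
            out["node_posteriors"] = [d.to_dict() for d in self.node_posteriors]
        return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
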