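"""Optional electrode-interaction models.

By default electrodes are independent and the rendered percept is the sum
of independent phosphenes.  Two interaction mechanisms can be enabled:

* a *co-stimulation penalty* — a scalar loss discouraging simultaneous
  activation of nearby electrode pairs,

      L = (1/n) * sum_i sum_{j != i} I_i * I_j / (1 + ||p_j - p_i||^2),

* a *coactivation leak* — current of simultaneously active electrodes
  leaks to each other with a rapidly decaying distance kernel,

      I_coact,i = sum_{j != i, active} I_j / (1 + c * ||p_j - p_i||^2),

  added to electrode i's amplitude before the effective-current stage.
  ``c`` defaults to 100 mm^-2.

Self-pairs are excluded from both sums: a self-term would add I_i^2 to the
loss and feed an electrode's own current back to itself, contradicting the
neighbour-interaction purpose of the models.  "Active" means a strictly
positive amplitude on the current frame.  Both quantities are symmetric
under electrode relabelling and invariant under rigid translation of the
layout (they depend on pairwise distances only).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["InteractionConfig", "costim_loss", "coactivation_currents"]

DEFAULT_LEAK_CONSTANT = 100.0  # mm^-2


@dataclass(frozen=True)
class InteractionConfig:
    """Interaction mode for a simulator session.

    ``mode`` is one of ``"none"``, ``"costim_loss"``, ``"coactivation"``;
    ``mode="none"`` reproduces the independent-electrode model exactly.
    """

    mode: str = "none"
    leak_constant: float = DEFAULT_LEAK_CONSTANT

    def __post_init__(self) -> None:
        if self.mode not in ("none", "costim_loss", "coactivation"):
            raise ValueError(f"unknown interaction mode {self.mode!r}")
        if self.leak_constant <= 0:
            raise ValueError("leak_constant must be > 0")


def _pairwise_sq_dist(positions: np.ndarray) -> np.ndarray:
    p = np.asarray(positions, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("positions must have shape (n, 2) in mm")
    diff = p[:, None, :] - p[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def costim_loss(currents, positions) -> float:
    """Scalar co-stimulation penalty over all unordered electrode pairs."""
    I = np.asarray(currents, dtype=float)
    if np.any(I < 0):
        raise ValueError("currents must be >= 0")
    n = len(I)
    if n < 2:
        return 0.0
    d2 = _pairwise_sq_dist(positions)
    kernel = 1.0 / (1.0 + d2)
    np.fill_diagonal(kernel, 0.0)
    return float(I @ kernel @ I) / n


def coactivation_currents(currents, positions,
                          leak_constant: float = DEFAULT_LEAK_CONSTANT) -> np.ndarray:
    """Leak current received by each active electrode from other active ones.

    Inactive electrodes (zero amplitude this frame) neither contribute nor
    receive leak current.  Units follow the input currents.
    """
    I = np.asarray(currents, dtype=float)
    if np.any(I < 0):
        raise ValueError("currents must be >= 0")
    active = I > 0
    d2 = _pairwise_sq_dist(positions)
    kernel = 1.0 / (1.0 + leak_constant * d2)
    np.fill_diagonal(kernel, 0.0)
    out = kernel @ (I * active)
    out[~active] = 0.0
    return out
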