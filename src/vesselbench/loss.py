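"""Region-weighted L1 supervision loss for vessel segmentation.

The loss compares a predicted probability map y_p against the rendered
ground-truth map y_g through four mean-absolute-error terms:

    Loss = 1/N     * ||y_p - y_g||_1            (all N voxels)
         + 1/#S1   * ||(y_p - y_g)_{S1}||_1     (gt > t1: foreground + halo)
         + 1/#S2   * ||(y_p - y_g)_{S2}||_1     (gt > t2: strict foreground)
         + 1/#S2*  * ||(y_p - y_g)_{S2*}||_1    (pred > t2: predicted fg)

The first three terms pull the prediction toward the annotated foreground
with increasing emphasis on vessel voxels; the S2* term, restricted on the
*prediction*, additionally penalizes false-positive foreground.  Terms over
an empty region are defined as 0 (the 0/0 case).  This is a pure numeric
function, usable both for validating supervision maps and for re-use inside
any training framework.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation_maps import T1_DEFAULT, T2_DEFAULT
from .core_model import Volume

__all__ = ["LossBreakdown", "combined_loss"]


@dataclass
class LossBreakdown:
    term_global: float
    term_S1: float
    term_S2: float
    term_S2star: float
    n_voxels: int
    n_S1: int
    n_S2: int
    n_S2star: int
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    @property
    def total(self) -> float:
        w = self.weights
        return (
            w[0] * self.term_global
            + w[1] * self.term_S1
            + w[2] * self.term_S2
            + w[3] * self.term_S2star
        )


def _as_array(x: Volume | np.ndarray) -> np.ndarray:
    return x.data if isinstance(x, Volume) else np.asarray(x)


def combined_loss(
    pred: Volume | np.ndarray,
    gt: Volume | np.ndarray,
    t1: float = T1_DEFAULT,
    t2: float = T2_DEFAULT,
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
) -> LossBreakdown:
    """Evaluate the combined region-weighted L1 loss.

    ``pred`` and ``gt`` are probability volumes in [0, 1] of equal shape.
    Returns the per-term breakdown; ``total`` is the (optionally weighted)
    sum of the four terms.
    """
    p = _as_array(pred).astype(np.float64)
    g = _as_array(gt).astype(np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    err = np.abs(p - g)
    s1 = g > t1
    s2 = g > t2
    s2star = p > t2

    def region_mean(mask: np.ndarray) -> float:
        n = int(mask.sum())
        return float(err[mask].sum() / n) if n else 0.0

    return LossBreakdown(
        term_global=float(err.mean()) if err.size else 0.0,
        term_S1=region_mean(s1),
        term_S2=region_mean(s2),
        term_S2star=region_mean(s2star),
        n_voxels=int(err.size),
        n_S1=int(s1.sum()),
        n_S2=int(s2.sum()),
        n_S2star=int(s2star.sum()),
        weights=weights,
    )
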