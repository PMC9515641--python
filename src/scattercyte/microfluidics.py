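"""Viscoelastic three-dimensional cell-alignment criterion.

In a dilute polymer solution (0.4 wt% PEO in PBS) flowing through a round
capillary, elastic normal-stress gradients migrate suspended cells to the
channel centreline, so each cell crosses the laser in single file at a
reproducible position.  Whether the channel is long enough for a cell of
radius r1 to reach the centreline is captured by the design inequality

    3 Wi beta^2 (L / 2R) > -ln(3.5 beta),

with Weissenberg number Wi = lambda * U / R (fluid relaxation time times
the characteristic shear rate U/R) and beta = r1 / R the blockage ratio.
Larger cells, faster flow, longer channels and more elastic fluids all
favour alignment.

Defaults are the study's operating point: lambda = 0.197 ms, mean velocity
1496 um/s, channel radius 25 um, channel length 0.35 m.  (The velocity is
reported with a garbled unit; dimensional analysis of Wi fixes it as um/s.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AlignmentParams", "weissenberg", "alignment_satisfied"]


@dataclass(frozen=True)
class AlignmentParams:
    """Operating parameters with declared units.

    relaxation_time: ms; mean_velocity: um/s; channel_radius: um;
    channel_length: m; cell_radius: um.
    """

    cell_radius: float
    relaxation_time: float = 0.197
    mean_velocity: float = 1496.0
    channel_radius: float = 25.0
    channel_length: float = 0.35

    def __post_init__(self) -> None:
        for name in (
            "cell_radius",
            "relaxation_time",
            "mean_velocity",
            "channel_radius",
            "channel_length",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive")
        if self.cell_radius >= self.channel_radius:
            raise ValueError("cell_radius must be smaller than channel_radius")

    @property
    def beta(self) -> float:
        """Blockage ratio r1 / R."""
        return self.cell_radius / self.channel_radius


def weissenberg(p: AlignmentParams) -> float:
    """Wi = relaxation_time * mean_velocity / channel_radius (units reconciled
    internally: ms -> s leaves um/s / um = 1/s)."""
    lam_s = p.relaxation_time * 1e-3
    return lam_s * p.mean_velocity / p.channel_radius


def alignment_satisfied(p: AlignmentParams) -> tuple[bool, float]:
    """Evaluate the centreline-alignment inequality.

    Returns (satisfied, margin) with margin = LHS - RHS,
    LHS = 3 Wi beta^2 L/(2R) and RHS = -ln(3.5 beta).  A positive margin
    means the channel is long enough to focus a cell of this size.
    """
    beta = p.beta
    wi = weissenberg(p)
    length_ratio = p.channel_length / (2 * p.channel_radius * 1e-6)  # both in m
    lhs = 3.0 * wi * beta**2 * length_ratio
    rhs = -np.log(3.5 * beta)
    margin = lhs - rhs
    return bool(margin > 0), float(margin)
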