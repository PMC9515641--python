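"""Synthetic labelled cell populations and their simulated LSPs.

Stands in for the microfluidic scattering instrument and the donor samples:
each phenotype (monocyte, M0, M1, M2) is described by Gaussian-distributed
biophysical properties whose means, diameter SDs and sample sizes are the
values the study reports for pooled three-donor data.  Cells are drawn as
independent truncated Gaussians (truncated at the default lookup-grid
bounds so every cell stays invertible), forward-modelled to theoretical
LSPs, and corrupted with multiplicative log-normal intensity noise.

Only the diameter dispersions are reported; the N/C-ratio and refractive
index SDs are the generator's single calibration knob (see
``DEFAULT_NC_SD`` / ``DEFAULT_RI_SD``), frozen after one documented
calibration pass against the reported classification accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lookup import DEFAULT_GRID, GridSpec
from .optics import LSP, CoreShellCell, OpticalConfig, lsp_intensity_batch

__all__ = [
    "PhenotypeSpec",
    "NoiseModel",
    "LSPSet",
    "default_phenotype_specs",
    "sample_cells",
    "add_noise",
    "simulate_dataset",
    "DEFAULT_NC_SD",
    "DEFAULT_RI_SD",
]

PHENOTYPES = ("Mono", "M0", "M1", "M2")

# Unreported dispersions, one calibration pass, then frozen (docs/methods.md).
DEFAULT_NC_SD = 0.02
DEFAULT_RI_SD = 0.006

_PROPS = ("diameter", "nc_ratio", "ri_nucleus", "ri_cytoplasm")


@dataclass(frozen=True)
class PhenotypeSpec:
    """Distributional description of one cell population.

    mean/sd per property; ``n`` is the default sample size of the pooled
    three-donor dataset the study reports.
    """

    label: str
    diameter_mean: float
    diameter_sd: float
    nc_ratio_mean: float
    nc_ratio_sd: float
    ri_nucleus_mean: float
    ri_nucleus_sd: float
    ri_cytoplasm_mean: float
    ri_cytoplasm_sd: float
    n: int

    def __post_init__(self) -> None:
        for p in _PROPS:
            if getattr(self, f"{p}_sd") < 0:
                raise ValueError("SDs must be nonnegative")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    def means(self) -> tuple[float, float, float, float]:
        return tuple(getattr(self, f"{p}_mean") for p in _PROPS)

    def sds(self) -> tuple[float, float, float, float]:
        return tuple(getattr(self, f"{p}_sd") for p in _PROPS)

    def mean_cell(self) -> CoreShellCell:
        return CoreShellCell(*self.means())

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            **{f"{p}_mean": getattr(self, f"{p}_mean") for p in _PROPS},
            **{f"{p}_sd": getattr(self, f"{p}_sd") for p in _PROPS},
            "n": self.n,
        }


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model applied to theoretical LSPs.

    multiplicative_sigma: relative SD of pointwise log-normal intensity
    factors (unit mean).  angle_jitter is kept for completeness; the
    default instrument emulation applies none.
    """

    multiplicative_sigma: float = 0.05
    angle_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.multiplicative_sigma < 0 or self.angle_jitter < 0:
            raise ValueError("noise parameters must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "multiplicative_sigma": self.multiplicative_sigma,
            "angle_jitter": self.angle_jitter,
        }


def default_phenotype_specs(
    nc_sd: float = DEFAULT_NC_SD, ri_sd: float = DEFAULT_RI_SD
) -> dict[str, PhenotypeSpec]:
    """The four study populations with the reported means, diameter SDs
    and pooled sample sizes (monocytes 148, M0 149, M1 167, M2 215)."""
    return {
        "Mono": PhenotypeSpec(
            "Mono", 9.82, 1.59, 0.80, nc_sd, 1.39, ri_sd, 1.36, ri_sd, n=148
        ),
        "M0": PhenotypeSpec(
            "M0", 15.66, 2.84, 0.85, nc_sd, 1.42, ri_sd, 1.39, ri_sd, n=149
        ),
        "M1": PhenotypeSpec(
            "M1", 11.76, 1.72, 0.85, nc_sd, 1.42, ri_sd, 1.38, ri_sd, n=167
        ),
        "M2": PhenotypeSpec(
            "M2", 14.25, 2.29, 0.85, nc_sd, 1.43, ri_sd, 1.39, ri_sd, n=215
        ),
    }


def sample_cells(
    spec: PhenotypeSpec,
    n: int | None = None,
    seed: int | np.random.Generator = 0,
    grid: GridSpec = DEFAULT_GRID,
) -> np.ndarray:
    """Draw ``n`` cells as an (n, 4) parameter array.

    Independent truncated-Gaussian draws per property, truncated at the
    lookup-grid bounds so every sampled cell is representable on the grid.
    Reproducible for a fixed seed.
    """
    n = spec.n if n is None else n
    if n < 1:
        raise ValueError("n must be >= 1")
    if not grid.contains(spec.mean_cell()):
        raise ValueError(f"{spec.label}: mean cell outside the lookup grid bounds")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = []
    for p, ax in zip(_PROPS, grid.axes):
        mean = getattr(spec, f"{p}_mean")
        sd = getattr(spec, f"{p}_sd")
        if sd == 0:
            cols.append(np.full(n, mean))
            continue
        a, b = (ax.min - mean) / sd, (ax.max - mean) / sd
        cols.append(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng))
    return np.stack(cols, axis=1)


def add_noise(
    lsp: LSP | np.ndarray,
    model: NoiseModel = NoiseModel(),
    seed: int | np.random.Generator = 0,
) -> LSP | np.ndarray:
    """Apply unit-mean multiplicative log-normal noise pointwise.

    Accepts a single LSP or a dense intensity matrix; nonnegativity is
    preserved (zero intensities stay zero), sigma=0 is the identity.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = model.multiplicative_sigma
    if isinstance(lsp, LSP):
        noisy = add_noise(lsp.intensities, model, rng)
        return LSP(angles=lsp.angles, intensities=noisy, meta={**lsp.meta, "noise": model.to_dict()})
    inten = np.asarray(lsp, dtype=np.float64)
    if s == 0:
        return inten.copy()
    # mean -s^2/2 in the log makes the factors exactly unit-mean
    factors = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=inten.shape)
    return inten * factors


@dataclass
class LSPSet:
    """A labelled collection of LSPs sharing one angular grid."""

    angles: np.ndarray
    intensities: np.ndarray          # (n_cells, n_angles)
    labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 2 or self.intensities.shape != (
            len(self.labels),
            self.angles.size,
        ):
            raise ValueError("intensities must be (n_cells, n_angles) matching labels/angles")

    def __len__(self) -> int:
        return len(self.labels)

    def to_lsps(self) -> list[LSP]:
        return [
            LSP(self.angles, self.intensities[i], meta={"label": self.labels[i]})
            for i in range(len(self))
        ]


def simulate_dataset(
    specs: Sequence[PhenotypeSpec] | dict[str, PhenotypeSpec] | None = None,
    optics: OpticalConfig = OpticalConfig(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    n_overrides: dict[str, int] | None = None,
    grid: GridSpec = DEFAULT_GRID,
) -> tuple[LSPSet, pd.DataFrame]:
    """Sample cells, forward-model their LSPs and add measurement noise.

    Returns the labelled LSP set together with the ground-truth parameter
    table (one row per cell, in emission order), enabling recovery tests.
    All randomness derives from ``seed`` via one spawned stream per
    phenotype plus one for the noise.
    """
    if specs is None:
        specs = default_phenotype_specs()
    if isinstance(specs, dict):
        specs = list(specs.values())
    if n_overrides:
        specs = [
            replace(s, n=n_overrides.get(s.label, s.n)) for s in specs
        ]
    streams = np.random.SeedSequence(seed).spawn(len(specs) + 1)
    cells_list, labels = [], []
    for s, ss in zip(specs, streams[:-1]):
        cells = sample_cells(s, s.n, np.random.default_rng(ss), grid)
        cells_list.append(cells)
        labels.extend([s.label] * s.n)
    params = np.concatenate(cells_list, axis=0)
    clean = lsp_intensity_batch(params, optics)
    noisy = add_noise(clean, noise, np.random.default_rng(streams[-1]))
    truth = pd.DataFrame(params, columns=["D_um", "nc_ratio", "ri_n", "ri_c"])
    truth["label"] = labels
    lsps = LSPSet(
        angles=optics.angles,
        intensities=noisy,
        labels=labels,
        meta={
            "seed": seed,
            "noise": noise.to_dict(),
            "optics": optics.to_dict(),
            "specs": [s.to_dict() for s in specs],
        },
    )
    return lsps, truth
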