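"""Cumulative dose-volume histograms and dose-volume / EUD metrics.

Doses are RBE-weighted totals for the full treatment course, in Gy(RBE).
A :class:`DVH` stores the cumulative curve: the fraction of the structure
volume receiving at least each dose level. Metrics (``D_v%``, ``D_vcc``,
gEUD) interpolate linearly between cumulative bins; the default bin width
is 0.1 Gy(RBE), finer than the one-decimal clinical reporting precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import logsumexp

RBEModel = Literal["LEM", "MKM"]

DEFAULT_BIN_WIDTH = 0.1

__all__ = [
    "DoseGrid",
    "StructureMask",
    "DVH",
    "VolumeSpec",
    "compute_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "geud",
    "average_dvh",
    "dvh_from_dose_points",
    "uniform_dvh",
    "expand_mask",
]


def _check_rbe_model(rbe_model: str) -> str:
    if rbe_model not in ("LEM", "MKM"):
        raise ValueError(f"rbe_model must be 'LEM' or 'MKM', got {rbe_model!r}")
    return rbe_model


@dataclass(frozen=True)
class DoseGrid:
    """Voxelized RBE-weighted dose distribution.

    Parameters
    ----------
    values : ndarray
        3-D array of non-negative RBE-weighted dose [Gy(RBE)].
    voxel_size : tuple of float
        Voxel dimensions (dx, dy, dz) in mm, all > 0.
    origin : tuple of float
        Grid origin (x, y, z) in mm.
    rbe_model : {"LEM", "MKM"}
        RBE language the dose is expressed in.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rbe_model: RBEModel = "LEM"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3 or values.size == 0:
            raise ValueError("dose grid must be a non-empty 3-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("dose values must be finite")
        if np.any(values < 0):
            raise ValueError("dose values must be non-negative")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel dimensions must be positive")
        _check_rbe_model(self.rbe_model)
        object.__setattr__(self, "values", values)

    @property
    def voxel_volume_cc(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz / 1000.0


@dataclass(frozen=True)
class StructureMask:
    """Binary mask congruent with a :class:`DoseGrid`."""

    mask: np.ndarray
    name: str = "structure"

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError("structure mask must be a 3-D boolean array")
        object.__setattr__(self, "mask", mask)

    def volume_cc(self, voxel_size: Sequence[float]) -> float:
        dx, dy, dz = voxel_size
        return float(self.mask.sum()) * dx * dy * dz / 1000.0


@dataclass(frozen=True)
class VolumeSpec:
    """Volume specification for dose-volume metrics: D_v% or D_vcc."""

    kind: Literal["percent", "cc"]
    amount: float

    def __post_init__(self) -> None:
        if self.kind not in ("percent", "cc"):
            raise ValueError(f"volume kind must be 'percent' or 'cc', got {self.kind!r}")
        if not self.amount > 0:
            raise ValueError("volume amount must be positive")
        if self.kind == "percent" and self.amount > 100:
            raise ValueError("percent volume must be in (0, 100]")

    def fraction(self, total_volume_cc: float) -> float:
        """Volume fraction of the structure this spec addresses."""
        if self.kind == "percent":
            return self.amount / 100.0
        if self.amount > total_volume_cc + 1e-12:
            raise ValueError(
                f"cc volume {self.amount} exceeds structure volume {total_volume_cc} cc"
            )
        return self.amount / total_volume_cc

    def label(self) -> str:
        amount = f"{self.amount:g}"
        return f"D_{amount}%" if self.kind == "percent" else f"D_{amount}cc"


@dataclass(frozen=True)
class DVH:
    """Cumulative dose-volume histogram.

    ``cum_volume_fraction[i]`` is the fraction of the structure volume
    receiving at least ``dose_edges[i]`` Gy(RBE). The curve starts at 1
    (every voxel receives >= 0 dose), ends at 0, and is monotone
    non-increasing over strictly increasing dose edges.
    """

    dose_edges: np.ndarray
    cum_volume_fraction: np.ndarray
    total_volume_cc: float
    rbe_model: RBEModel = "LEM"
    structure: str = "structure"
    patient_id: str | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.dose_edges, dtype=float)
        frac = np.asarray(self.cum_volume_fraction, dtype=float)
        if edges.ndim != 1 or edges.shape != frac.shape or edges.size < 2:
            raise ValueError("dose_edges and cum_volume_fraction must be 1-D of equal length >= 2")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("dose_edges must be strictly increasing")
        if np.any(np.diff(frac) > 1e-12):
            raise ValueError("cum_volume_fraction must be monotone non-increasing")
        if abs(frac[0] - 1.0) > 1e-9 or abs(frac[-1]) > 1e-9:
            raise ValueError("cum_volume_fraction must start at 1 and end at 0")
        if not self.total_volume_cc > 0:
            raise ValueError("total_volume_cc must be positive")
        _check_rbe_model(self.rbe_model)
        object.__setattr__(self, "dose_edges", edges)
        object.__setattr__(self, "cum_volume_fraction", np.clip(frac, 0.0, 1.0))

    @property
    def max_dose(self) -> float:
        return float(self.dose_edges[-1])

    def mean_dose(self) -> float:
        return geud(self, 1.0)


def compute_dvh(
    grid: DoseGrid,
    mask: StructureMask,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> DVH:
    """Bin the masked voxel doses into a cumulative DVH.

    The cumulative fraction at each edge ``d`` is the exact empirical
    survival fraction ``#(dose >= d) / #voxels``; binning only controls
    where the curve is sampled.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if mask.mask.shape != grid.values.shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match grid shape {grid.values.shape}"
        )
    doses = grid.values[mask.mask]
    if doses.size == 0:
        raise ValueError("empty structure")
    n_edges = int(np.ceil(doses.max() / bin_width)) + 2
    edges = np.arange(n_edges) * bin_width
    # survival count at each edge via a sorted search
    sorted_doses = np.sort(doses)
    n_below = np.searchsorted(sorted_doses, edges, side="left")
    frac = 1.0 - n_below / doses.size
    frac[-1] = 0.0  # last edge exceeds max dose by construction
    return DVH(
        dose_edges=edges,
        cum_volume_fraction=frac,
        total_volume_cc=mask.volume_cc(grid.voxel_size),
        rbe_model=grid.rbe_model,
        structure=mask.name,
    )


def dose_at_volume(dvh: DVH, spec: VolumeSpec) -> float:
    """Minimum dose received by the hottest ``spec`` of the structure.

    Returns the smallest dose ``d`` with ``cum_volume_fraction(d) <=``
    the spec's volume fraction, interpolating linearly between bins.
    cc specs are converted through the DVH's total volume.
    """
    f = spec.fraction(dvh.total_volume_cc)
    frac = dvh.cum_volume_fraction
    edges = dvh.dose_edges
    if f >= frac[0]:
        return float(edges[0])
    # first index where the curve has dropped to <= f
    idx = int(np.searchsorted(-frac, -f, side="left"))
    if idx >= frac.size:
        return float(edges[-1])
    if frac[idx] == f:
        return float(edges[idx])
    c0, c1 = frac[idx - 1], frac[idx]
    e0, e1 = edges[idx - 1], edges[idx]
    return float(e0 + (c0 - f) / (c0 - c1) * (e1 - e0))


def volume_at_dose(dvh: DVH, dose: float) -> float:
    """Interpolated cumulative volume fraction receiving at least ``dose``."""
    if dose < 0:
        raise ValueError("dose must be non-negative")
    return float(
        np.interp(
            dose,
            dvh.dose_edges,
            dvh.cum_volume_fraction,
            left=dvh.cum_volume_fraction[0],
            right=0.0,
        )
    )


def _differential(dvh: DVH) -> tuple[np.ndarray, np.ndarray]:
    """Differential DVH (bin-midpoint doses, volume fractions summing to 1)."""
    frac = dvh.cum_volume_fraction
    edges = dvh.dose_edges
    weights = frac[:-1] - frac[1:]
    mids = 0.5 * (edges[:-1] + edges[1:])
    return mids, weights


def geud(dvh: DVH, n: float) -> float:
    """Generalized equivalent uniform dose.

    ``EUD = (sum_i v_i d_i^{1/n})^n`` over the differential DVH, with
    volume fractions ``v_i`` summing to 1. Evaluated in log space so
    small ``n`` (serial organs, exponents of order 1/n) cannot overflow.
    """
    if not n > 0:
        raise ValueError("volume-effect parameter n must be positive")
    mids, weights = _differential(dvh)
    keep = weights > 0
    mids, weights = mids[keep], weights[keep]
    if mids.size == 0 or np.all(mids <= 0):
        return 0.0
    positive = mids > 0
    if not np.any(positive):
        return 0.0
    log_terms = np.log(weights[positive]) + np.log(mids[positive]) / n
    return float(np.exp(n * logsumexp(log_terms)))


def average_dvh(
    dvhs: Sequence[DVH],
    edges: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cohort-average cumulative DVH with per-bin standard deviation.

    All curves are re-sampled onto a shared edge set (by default a regular
    0..max grid at the finest input bin width). Returns
    ``(edges, mean_fraction, sd_fraction)`` where the SD is the population
    (ddof=0) standard deviation, i.e. the half-width of a +/-1 SD band.
    """
    if len(dvhs) < 2:
        raise ValueError("averaging requires at least 2 DVHs")
    if edges is None:
        max_dose = max(d.max_dose for d in dvhs)
        width = min(float(np.diff(d.dose_edges).min()) for d in dvhs)
        width = max(width, 1e-3)
        edges = np.arange(0.0, max_dose + width, width)
    curves = np.vstack([[volume_at_dose(d, e) for e in edges] for d in dvhs])
    return np.asarray(edges, dtype=float), curves.mean(axis=0), curves.std(axis=0)


def dvh_from_dose_points(
    points: dict[VolumeSpec, float],
    total_volume_cc: float,
    rbe_model: RBEModel = "MKM",
    structure: str = "rectum",
    patient_id: str | None = None,
) -> DVH:
    """Piecewise-linear cumulative DVH through tabulated D_v points.

    Useful for published dose-volume tables where only a few (v, D_v)
    pairs are printed: the returned DVH reproduces each ``dose_at_volume``
    exactly and interpolates linearly in between. The curve is anchored at
    (0 Gy, fraction 1) and falls to 0 just above the hottest point.
    """
    if not points:
        raise ValueError("at least one dose point is required")
    pairs = sorted(
        ((spec.fraction(total_volume_cc), dose) for spec, dose in points.items()),
        key=lambda p: -p[0],
    )
    fractions = [1.0] + [f for f, _ in pairs] + [0.0]
    top = pairs[-1][1]
    doses = [0.0] + [d for _, d in pairs] + [top * 1.02 + 0.1]
    if any(d1 <= d0 for d0, d1 in zip(doses, doses[1:])):
        raise ValueError("dose points must increase as volume fraction decreases")
    if any(f1 >= f0 for f0, f1 in zip(fractions, fractions[1:])):
        raise ValueError("volume fractions must be distinct")
    return DVH(
        dose_edges=np.array(doses),
        cum_volume_fraction=np.array(fractions),
        total_volume_cc=total_volume_cc,
        rbe_model=rbe_model,
        structure=structure,
        patient_id=patient_id,
    )


def uniform_dvh(
    dose: float,
    total_volume_cc: float,
    rbe_model: RBEModel = "MKM",
    **kwargs,
) -> DVH:
    """DVH of a structure uniformly irradiated at ``dose`` Gy(RBE)."""
    if dose <= 0:
        raise ValueError("uniform dose must be positive")
    eps = max(dose * 1e-9, 1e-9)
    return DVH(
        dose_edges=np.array([0.0, dose, dose + eps]),
        cum_volume_fraction=np.array([1.0, 1.0, 0.0]),
        total_volume_cc=total_volume_cc,
        rbe_model=rbe_model,
        **kwargs,
    )


def expand_mask(
    mask: StructureMask,
    voxel_size: Sequence[float],
    margin_mm: float,
) -> StructureMask:
    """Isotropic 3-D dilation of a structure mask (e.g. a 5 mm PRV margin).

    A voxel joins the expanded mask when its center lies within
    ``margin_mm`` of the center of any voxel of the original mask.
    """
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    if margin_mm == 0:
        return mask
    dx, dy, dz = voxel_size
    nx, ny, nz = (int(np.floor(margin_mm / s)) for s in (dx, dy, dz))
    x, y, z = np.meshgrid(
        np.arange(-nx, nx + 1) * dx,
        np.arange(-ny, ny + 1) * dy,
        np.arange(-nz, nz + 1) * dz,
        indexing="ij",
    )
    ball = x**2 + y**2 + z**2 <= margin_mm**2
    dilated = ndimage.binary_dilation(mask.mask, structure=ball)
    return StructureMask(mask=dilated, name=f"{mask.name}_prv{margin_mm:g}mm")
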