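"""Dorsoventral axis profiling of a signal channel against a nuclear stain.

Implements the immunofluorescence quantification workflow for a BMP
signaling readout (e.g. phospho-Smad1/5/8 in the Cy5 channel) measured
against a nuclear counterstain (DAPI):

1. :func:`extract_axis_profile` — sum both channels across the
   transverse dimension of a rectangular ROI laid over the embryo,
   yielding one value per position along the ventral-dorsal axis
   (the semantics of ImageJ's Plot Profile on a rectangle).
2. :func:`normalize_and_align` — resample each embryo's profiles onto a
   common normalized axis in [0, 1] with the ventral end at 0, flipping
   profiles recorded dorsal-first.
3. :func:`ratio_profile` — per-position signal/nuclear ratio, masked
   where the nuclear denominator is effectively zero.
4. :func:`aggregate_group` — per-position mean and standard error of
   the mean across the embryos of a group.

The transverse aggregation is a sum, not a mean; the two differ by the
constant ROI-height factor, which cancels in the signal/nuclear ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "RectROI",
    "AxisProfile",
    "GroupProfile",
    "extract_axis_profile",
    "normalize_and_align",
    "ratio_profile",
    "aggregate_group",
]

#: ROI dimensions used for the embryo micrographs this workflow targets.
DEFAULT_ROI_HEIGHT = 200
DEFAULT_ROI_WIDTH = 650


@dataclass(frozen=True)
class RectROI:
    """Rectangular ROI with the profiling axis identified.

    ``axis`` is ``"width"`` when the ventral-dorsal axis runs along the
    ROI's width (profile length = width, summing over rows) or
    ``"height"`` for the transposed layout.  Which *end* of the axis is
    ventral is a per-embryo orientation flag handled downstream by
    :func:`normalize_and_align`.
    """

    top: int
    left: int
    height: int = DEFAULT_ROI_HEIGHT
    width: int = DEFAULT_ROI_WIDTH
    axis: str = "width"

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI height and width must be >= 1")
        if self.axis not in ("width", "height"):
            raise ValueError("axis must be 'width' or 'height'")


@dataclass
class AxisProfile:
    """Per-position profile on the normalized ventral(0)->dorsal(1) axis."""

    positions: np.ndarray
    signal: np.ndarray
    nuclear: np.ndarray
    ratio: np.ndarray | None = None
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.nuclear = np.asarray(self.nuclear, dtype=float)
        n = self.positions.size
        if self.signal.size != n or self.nuclear.size != n:
            raise ValueError("positions, signal and nuclear must have equal length")
        if n < 2 or np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not (np.isclose(self.positions[0], 0.0) and np.isclose(self.positions[-1], 1.0)):
            raise ValueError("positions must span [0, 1]")


@dataclass
class GroupProfile:
    """Group mean +/- SEM of the ratio on a common position grid."""

    positions: np.ndarray
    mean_ratio: np.ndarray
    sem_ratio: np.ndarray
    n: int


def extract_axis_profile(
    image: np.ndarray, roi: RectROI
) -> tuple[np.ndarray, np.ndarray]:
    """Raw signal and nuclear profiles along the ROI's axis.

    ``image`` is a (2, H, W) array, channel 0 = signal, channel 1 =
    nuclear.  Each output value is the sum of the channel across the
    ROI's transverse dimension at that axis position; output length
    equals the ROI extent along the axis.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[0] != 2:
        raise ValueError("expected a (2, H, W) two-channel image")
    _, h, w = image.shape
    if roi.top < 0 or roi.left < 0 or roi.top + roi.height > h or roi.left + roi.width > w:
        raise ValueError("ROI extends outside the image")
    block = image[:, roi.top : roi.top + roi.height, roi.left : roi.left + roi.width]
    transverse = 1 if roi.axis == "width" else 2
    signal, nuclear = block.sum(axis=transverse)
    return signal.astype(float), nuclear.astype(float)


def normalize_and_align(
    raw_profiles: list[tuple[np.ndarray, np.ndarray]],
    target_bins: int = 100,
    ventral_first: list[bool] | bool = True,
) -> list[AxisProfile]:
    """Resample raw per-embryo profiles onto a common [0, 1] axis.

    Each embryo's ROI is assumed to span the ventral edge to the dorsal
    edge, so the profile endpoints are the alignment landmarks: position
    0 maps to the ventral end, 1 to the dorsal end, and the profile is
    linearly interpolated onto ``target_bins`` evenly spaced positions.
    Profiles recorded dorsal-first (``ventral_first=False``) are flipped.
    """
    if target_bins < 2:
        raise ValueError("target_bins must be >= 2")
    if isinstance(ventral_first, bool):
        ventral_first = [ventral_first] * len(raw_profiles)
    if len(ventral_first) != len(raw_profiles):
        raise ValueError("one orientation flag is required per profile")

    grid = np.linspace(0.0, 1.0, target_bins)
    out: list[AxisProfile] = []
    for (signal, nuclear), vfirst in zip(raw_profiles, ventral_first):
        signal = np.asarray(signal, dtype=float)
        nuclear = np.asarray(nuclear, dtype=float)
        if signal.size < 2 or nuclear.size != signal.size:
            raise ValueError("profiles need >= 2 positions and matching channel lengths")
        if not vfirst:
            signal, nuclear = signal[::-1], nuclear[::-1]
        src = np.linspace(0.0, 1.0, signal.size)
        out.append(
            AxisProfile(
                positions=grid,
                signal=np.interp(grid, src, signal),
                nuclear=np.interp(grid, src, nuclear),
            )
        )
    return out


def ratio_profile(
    profile: AxisProfile,
    nuclear_floor: float | None = None,
    max_normalize: bool = False,
) -> AxisProfile:
    """Populate the signal/nuclear ratio, masking degenerate positions.

    Positions where the nuclear channel does not exceed
    ``nuclear_floor`` (default: 1e-6 times the profile's nuclear
    maximum) get ``valid_mask=False`` and a NaN ratio instead of a
    division blow-up; they are excluded from group statistics.

    ``max_normalize`` additionally rescales the ratio to a per-embryo
    maximum of 1.  It is off by default: the plain ratio is the
    quantity of interest, and rescaling discards between-embryo
    amplitude differences.
    """
    if nuclear_floor is None:
        nuclear_floor = 1e-6 * float(np.max(profile.nuclear, initial=0.0))
    valid = profile.nuclear > nuclear_floor
    ratio = np.full_like(profile.signal, np.nan)
    np.divide(profile.signal, profile.nuclear, out=ratio, where=valid)
    if max_normalize and valid.any():
        peak = np.nanmax(ratio[valid])
        if peak > 0:
            ratio = ratio / peak
    return AxisProfile(
        positions=profile.positions,
        signal=profile.signal,
        nuclear=profile.nuclear,
        ratio=ratio,
        valid_mask=valid,
    )


def aggregate_group(profiles: list[AxisProfile]) -> GroupProfile:
    """Per-position mean and SEM of the ratio across embryos.

    All profiles must share the same position grid and have their ratio
    populated.  At each position the mean and the standard error
    (sample s.d. / sqrt(count)) are taken over the embryos whose ratio
    is valid there; positions with fewer than 2 valid embryos get SEM
    NaN.
    """
    if len(profiles) < 2:
        raise ValueError("group aggregation needs n >= 2 profiles")
    grid = profiles[0].positions
    for p in profiles:
        if p.ratio is None or p.valid_mask is None:
            raise ValueError("profiles must have ratio populated (run ratio_profile)")
        if p.positions.shape != grid.shape or not np.allclose(p.positions, grid):
            raise ValueError("all profiles must share the same position grid")

    ratios = np.vstack([p.ratio for p in profiles])
    valid = np.vstack([p.valid_mask for p in profiles])
    counts = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, np.nansum(np.where(valid, ratios, 0.0), axis=0) / np.maximum(counts, 1), np.nan)
        centered = np.where(valid, ratios - mean, 0.0)
        var = np.where(counts > 1, (centered**2).sum(axis=0) / np.maximum(counts - 1, 1), np.nan)
        sem = np.sqrt(var) / np.sqrt(counts)
    return GroupProfile(positions=grid, mean_ratio=mean, sem_ratio=sem, n=len(profiles))
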