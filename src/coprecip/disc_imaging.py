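"""Quantification of eye-antennal imaginal disc z-stacks.

The analysis works on maximum-intensity projections (MIPs) of
3-channel stacks (DAPI / Elav / cleaved-Caspase-3).  The disc is
segmented on the DAPI MIP; the Elav-positive (photoreceptor) area is
expressed as a percent of disc area; apoptotic Caspase-3 foci are called
as connected components at or above 3x the basal in-disc fluorescence,
kept only when their area lies strictly between 1 and 60 um^2; disc
sizes are classified against a control cohort as below / within / above
the control mean +/- 2 sample standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import ContractError, NoDiscFoundError, ValidationError

CHANNELS = ("dapi", "elav", "caspase")

#: 8-connectivity for all 2-D component labeling.
CONNECTIVITY = 2

#: Focus threshold as a multiple of basal fluorescence (inclusive).
FOCUS_THRESHOLD_MULTIPLE = 3.0
#: Area gate in um^2, both bounds strict.
FOCUS_MIN_AREA_UM2 = 1.0
FOCUS_MAX_AREA_UM2 = 60.0


@dataclass
class DiscImageStack:
    """Calibrated 3-channel z-stack of one eye-antennal disc.

    Each channel is a ``(n_z, H, W)`` array; pixel size in um/pixel and
    z step in um are required calibration inputs (they are instrument
    settings, not derivable from the pixels).
    """

    channels: dict[str, np.ndarray]
    z_step: float = 0.5
    pixel_size: float = 0.325

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0")
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValidationError(f"channel shapes differ: {shapes}")
        for name in CHANNELS:
            if name not in self.channels:
                raise ValidationError(f"missing channel {name!r}")
            if self.channels[name].ndim != 3:
                raise ValidationError(f"channel {name!r} is not a z-stack")
            if np.any(self.channels[name] < 0):
                raise ValidationError(f"channel {name!r} has negative intensities")

    @property
    def n_z(self) -> int:
        return next(iter(self.channels.values())).shape[0]


@dataclass(frozen=True)
class CaspaseFocus:
    """One called apoptotic focus on the Caspase MIP."""

    label: int
    area: float  # um^2
    mean_fluorescence: float
    centroid: tuple[float, float]  # (row, col) pixels


@dataclass
class DiscQuantResult:
    """Per-disc summary of all quantified readouts."""

    disc_id: str
    disc_area: float  # um^2
    elav_fraction: float  # percent of disc area
    n_foci: int
    mean_focus_area: float | None  # um^2; None with zero foci
    mean_focus_fluorescence: float | None
    foci: list[CaspaseFocus] = field(default_factory=list)


def max_intensity_projection(stack: DiscImageStack) -> dict[str, np.ndarray]:
    """Pixelwise maximum over z for each channel."""
    if stack.n_z < 1:
        raise ContractError("stack has no z planes")
    return {name: arr.max(axis=0) for name, arr in stack.channels.items()}


def segment_disc(
    dapi_mip: np.ndarray, pixel_size: float
) -> tuple[np.ndarray, float]:
    """Segment the disc on the DAPI MIP.

    Automatic (Otsu) global threshold, largest 8-connected foreground
    component, holes filled.  Returns the boolean mask and its area in
    um^2 (pixel count x pixel_size^2).
    """
    dapi_mip = np.asarray(dapi_mip, dtype=float)
    if dapi_mip.size == 0 or np.ptp(dapi_mip) == 0:
        raise NoDiscFoundError("DAPI projection is constant; no disc to segment")
    thr = threshold_otsu(dapi_mip)
    fg = dapi_mip > thr
    if not fg.any():
        raise NoDiscFoundError("no foreground above the automatic threshold")
    labels = label(fg, connectivity=CONNECTIVITY)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == counts.argmax()
    mask = ndimage.binary_fill_holes(mask)
    area = float(mask.sum()) * pixel_size**2
    return mask, area


def _background_floor(image: np.ndarray, mask: np.ndarray) -> float:
    """Out-of-mask background level + 3 robust sigmas (0 if no background)."""
    outside = image[~mask]
    if outside.size == 0:
        return 0.0
    med = float(np.median(outside))
    sigma = 1.4826 * float(np.median(np.abs(outside - med)))
    return med + 3.0 * sigma


def elav_fraction(elav_mip: np.ndarray, disc_mask: np.ndarray) -> float:
    """Percent of disc area that is Elav-positive.

    Positivity is decided by an Otsu threshold computed from the in-mask
    intensities, guarded by a background floor (out-of-mask median + 3
    robust sigmas) so a signal-free disc does not have its noise split
    in half, and by an explicit branch for a constant in-mask signal
    (all-Elav or all-background disc), where Otsu is undefined.
    """
    elav_mip = np.asarray(elav_mip, dtype=float)
    disc_mask = np.asarray(disc_mask, dtype=bool)
    if not disc_mask.any():
        raise ContractError("empty disc mask")
    inside = elav_mip[disc_mask]
    floor = _background_floor(elav_mip, disc_mask)
    if np.ptp(inside) == 0:
        positive = int(disc_mask.sum()) if inside[0] > floor else 0
        return 100.0 * positive / disc_mask.sum()
    thr = max(threshold_otsu(inside), floor)
    positive = int(((elav_mip >= thr) & disc_mask).sum())
    return 100.0 * positive / disc_mask.sum()


def estimate_basal_fluorescence(
    caspase_mip: np.ndarray, disc_mask: np.ndarray
) -> float:
    """Robust basal level: median Caspase intensity inside the disc.

    The median is insensitive to sparse bright foci (which occupy a few
    percent of the disc at most), so the 3x-basal focus threshold does
    not drift upward in heavily apoptotic discs.
    """
    disc_mask = np.asarray(disc_mask, dtype=bool)
    if not disc_mask.any():
        raise ContractError("empty disc mask")
    return float(np.median(np.asarray(caspase_mip, dtype=float)[disc_mask]))


def call_caspase_foci(
    caspase_mip: np.ndarray,
    disc_mask: np.ndarray,
    basal: float,
    pixel_size: float,
) -> list[CaspaseFocus]:
    """Call Caspase-3-positive foci on the MIP.

    Pixels inside the disc at or above ``FOCUS_THRESHOLD_MULTIPLE x
    basal`` ("starting from 3 times the basal fluorescence", hence
    inclusive) are labeled with 8-connectivity; components are kept iff
    their area lies strictly inside (1, 60) um^2.  Each focus carries
    its area and the mean of its fluorescence signal.
    """
    if basal <= 0:
        raise ContractError("basal fluorescence must be > 0")
    caspase_mip = np.asarray(caspase_mip, dtype=float)
    disc_mask = np.asarray(disc_mask, dtype=bool)
    hot = (caspase_mip >= FOCUS_THRESHOLD_MULTIPLE * basal) & disc_mask
    labels = label(hot, connectivity=CONNECTIVITY)
    foci: list[CaspaseFocus] = []
    for prop in regionprops(labels, intensity_image=caspase_mip):
        area_um2 = prop.area * pixel_size**2
        if FOCUS_MIN_AREA_UM2 < area_um2 < FOCUS_MAX_AREA_UM2:
            foci.append(
                CaspaseFocus(
                    label=int(prop.label),
                    area=float(area_um2),
                    mean_fluorescence=float(prop.intensity_mean),
                    centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                )
            )
    return foci


def quantify_disc(stack: DiscImageStack, disc_id: str = "disc") -> DiscQuantResult:
    """Full per-disc readout: MIPs, segmentation, Elav fraction, foci."""
    mips = max_intensity_projection(stack)
    mask, disc_area = segment_disc(mips["dapi"], stack.pixel_size)
    elav_pct = elav_fraction(mips["elav"], mask)
    basal = estimate_basal_fluorescence(mips["caspase"], mask)
    foci = call_caspase_foci(mips["caspase"], mask, basal, stack.pixel_size)
    return DiscQuantResult(
        disc_id=disc_id,
        disc_area=disc_area,
        elav_fraction=elav_pct,
        n_foci=len(foci),
        mean_focus_area=(
            float(np.mean([f.area for f in foci])) if foci else None
        ),
        mean_focus_fluorescence=(
            float(np.mean([f.mean_fluorescence for f in foci])) if foci else None
        ),
        foci=foci,
    )


def classify_disc_sizes(
    test_areas: list[float], control_areas: list[float]
) -> tuple[float, float, float]:
    """Fractions of test discs below / within / above control mean +/- 2 SD.

    The SD is the sample standard deviation (n-1) of the control areas;
    discs exactly on a bound count as within.  Returns fractions summing
    to 1.
    """
    if len(control_areas) < 2:
        raise ContractError("need at least 2 control areas")
    if not test_areas:
        raise ContractError("empty test set")
    control = np.asarray(control_areas, dtype=float)
    test = np.asarray(test_areas, dtype=float)
    mean = control.mean()
    sd = control.std(ddof=1)
    lo, hi = mean - 2.0 * sd, mean + 2.0 * sd
    n = len(test)
    frac_below = float((test < lo).sum()) / n
    frac_above = float((test > hi).sum()) / n
    return frac_below, 1.0 - frac_below - frac_above, frac_above


def write_disc_stack(stack: DiscImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF, axes (z, channel, H, W)."""
    import tifffile

    path = Path(path)
    data = np.stack(
        [stack.channels[name] for name in CHANNELS], axis=1
    ).astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack", metadata={"axes": "ZCYX"})
    return path


def read_disc_stack(
    path: str | Path,
    pixel_size: float,
    z_step: float = 0.5,
    channel_order: tuple[str, ...] = CHANNELS,
) -> DiscImageStack:
    """Read a multi-page TIFF written with axes (z, channel, H, W).

    Calibration (pixel size, z step) and channel order are declared by
    the caller (typically from a TOML config), not inferred.
    """
    import tifffile

    data = tifffile.imread(Path(path))
    if data.ndim != 4 or data.shape[1] != len(channel_order):
        raise ValidationError(
            f"{path}: expected (z, {len(channel_order)} channels, H, W), "
            f"got shape {data.shape}"
        )
    channels = {
        name: np.asarray(data[:, i], dtype=float)
        for i, name in enumerate(channel_order)
    }
    return DiscImageStack(channels=channels, z_step=z_step, pixel_size=pixel_size)
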