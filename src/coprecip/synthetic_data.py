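"""Spike-in generators for both raw-data modalities.

Two generators make every pipeline stage testable offline with known
ground truth:

* :func:`generate_apms_experiment` emulates a GFP-TRAP pull-down: a bait
  at maximal abundance, true interactors present only in the bait run
  with log-normal peptide abundances and filter statistics that clear
  the stringent thresholds by a margin, and background contaminants that
  also appear independently in each negative-control run.

* :func:`generate_disc_image` emulates a 3-channel eye-antennal disc
  z-stack: DAPI fills an elliptical disc region, Elav fills a posterior
  sub-region of known area fraction, and the Caspase channel is basal
  (+ optional Gaussian noise) with planted apoptotic foci rasterized as
  filled disks at stated multiples of basal.  Truth areas are rasterized
  pixel counts x pixel area, so recovery assertions can be exact.

All randomness flows from a single integer seed through one named
generator (numpy PCG64), so identical configs give identical fixtures.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .disc_imaging import CHANNELS, DiscImageStack
from .errors import ConfigError
from .interactor_calling import FilterThresholds
from .msio import PeptideHit, ProteinGroupRecord, PullDownRun

_AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# AP-MS spike-in tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ApmsSimConfig:
    """Study conditions for the spike-in pull-down generator.

    Defaults mirror the experimental design being emulated: one bait
    pull-down against eight independent negative-control runs, with
    around a dozen true interactors and a large background of
    contaminants that are frequently (p = 0.9) re-observed in controls.
    Class-specific laws are chosen so that true interactors clear every
    filter threshold by a margin (scores >= 120 vs the 50 cut-off,
    coverage >= 25% vs 20%, >= 3 distinct peptides vs 2), while
    contaminants straddle all three thresholds.  Abundances are
    log-normal: true interactors ln-N(12, 1), contaminants ln-N(8, 1.5),
    in arbitrary area units.
    """

    n_true_interactors: int = 12
    n_contaminants: int = 200
    n_control_runs: int = 8
    contaminant_control_presence_prob: float = 0.9
    true_abundance_law: tuple[float, float] = (12.0, 1.0)  # lognormal mu, sigma
    contaminant_abundance_law: tuple[float, float] = (8.0, 1.5)
    true_score_range: tuple[float, float] = (120.0, 400.0)
    contaminant_score_range: tuple[float, float] = (20.0, 120.0)
    true_coverage_range: tuple[float, float] = (25.0, 80.0)
    contaminant_coverage_range: tuple[float, float] = (5.0, 45.0)
    true_peptide_count_range: tuple[int, int] = (3, 9)  # inclusive, support >= 2
    contaminant_single_peptide_prob: float = 0.3
    contaminant_peptide_count_range: tuple[int, int] = (2, 6)
    bait_accession: str = "BAIT_GFP"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contaminant_control_presence_prob <= 1.0:
            raise ConfigError("presence probability must be in [0, 1]")
        if not 0.0 <= self.contaminant_single_peptide_prob <= 1.0:
            raise ConfigError("single-peptide probability must be in [0, 1]")
        if min(self.n_true_interactors, self.n_contaminants, self.n_control_runs) < 0:
            raise ConfigError("counts must be >= 0")
        for law in (self.true_abundance_law, self.contaminant_abundance_law):
            if law[1] < 0:
                raise ConfigError(f"log-normal sigma {law[1]} is negative")
        if self.true_peptide_count_range[0] < 2:
            raise ConfigError("true interactors need >= 2 distinct peptides")


@dataclass(frozen=True)
class ApmsGroundTruth:
    """Which accession is what in a generated experiment."""

    bait_accession: str
    true_interactor_accessions: frozenset[str]
    contaminant_accessions: frozenset[str]

    def __post_init__(self) -> None:
        overlap = (
            ({self.bait_accession} & self.true_interactor_accessions)
            | ({self.bait_accession} & self.contaminant_accessions)
            | (self.true_interactor_accessions & self.contaminant_accessions)
        )
        if overlap:
            raise ConfigError(f"truth classes overlap: {sorted(overlap)}")


def _peptides(
    rng: np.random.Generator, n: int, law: tuple[float, float]
) -> list[PeptideHit]:
    seqs: set[str] = set()
    while len(seqs) < n:
        length = int(rng.integers(8, 16))
        seqs.add("".join(rng.choice(list(_AA), size=length)))
    areas = rng.lognormal(mean=law[0], sigma=law[1], size=n)
    return [PeptideHit(s, float(a)) for s, a in zip(sorted(seqs), areas)]


def _uniform(rng: np.random.Generator, lo_hi: tuple[float, float]) -> float:
    return float(rng.uniform(*lo_hi))


def _contaminant_record(
    rng: np.random.Generator, accession: str, cfg: ApmsSimConfig
) -> ProteinGroupRecord:
    if rng.random() < cfg.contaminant_single_peptide_prob:
        n_pep = 1
    else:
        lo, hi = cfg.contaminant_peptide_count_range
        n_pep = int(rng.integers(lo, hi + 1))
    return ProteinGroupRecord(
        accession=accession,
        description=f"background contaminant {accession}",
        score=_uniform(rng, cfg.contaminant_score_range),
        coverage=_uniform(rng, cfg.contaminant_coverage_range),
        peptides=_peptides(rng, n_pep, cfg.contaminant_abundance_law),
    )


def generate_apms_experiment(
    cfg: ApmsSimConfig,
) -> tuple[PullDownRun, list[PullDownRun], ApmsGroundTruth]:
    """Generate one bait pull-down, its negative controls, and the truth.

    The bait run holds the bait (whose peptide areas are pinned above
    every other area in the run, so it is always the most abundant
    protein), all true interactors, and all contaminants.  Each
    contaminant is independently re-observed in each control run with
    ``contaminant_control_presence_prob``.  Same config, same seed ->
    identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    true_accs = [f"TRUE{i:03d}" for i in range(cfg.n_true_interactors)]
    cont_accs = [f"CONT{i:03d}" for i in range(cfg.n_contaminants)]

    records: list[ProteinGroupRecord] = []
    lo, hi = cfg.true_peptide_count_range
    for acc in true_accs:
        records.append(
            ProteinGroupRecord(
                accession=acc,
                description=f"true interactor {acc}",
                score=_uniform(rng, cfg.true_score_range),
                coverage=_uniform(rng, cfg.true_coverage_range),
                peptides=_peptides(
                    rng, int(rng.integers(lo, hi + 1)), cfg.true_abundance_law
                ),
            )
        )
    for acc in cont_accs:
        records.append(_contaminant_record(rng, acc, cfg))

    # Bait abundance is pinned above everything else in the run.
    max_area = max(
        (p.area for r in records for p in r.peptides if p.area is not None),
        default=1.0,
    )
    bait = ProteinGroupRecord(
        accession=cfg.bait_accession,
        description="GFP-tagged bait",
        score=cfg.true_score_range[1],
        coverage=90.0,
        peptides=[
            PeptideHit(s, 2.0 * max_area + i)
            for i, s in enumerate(
                p.sequence for p in _peptides(rng, 5, cfg.true_abundance_law)
            )
        ],
    )
    bait_run = PullDownRun(
        run_id="bait_pulldown",
        records=[bait] + records,
        bait_accession=cfg.bait_accession,
        is_control=False,
    )
    bait_run.validate()

    controls: list[PullDownRun] = []
    for j in range(cfg.n_control_runs):
        ctrl = PullDownRun(run_id=f"control_{j:02d}", is_control=True)
        present = rng.random(cfg.n_contaminants) < cfg.contaminant_control_presence_prob
        for acc, p in zip(cont_accs, present):
            if p:
                ctrl.records.append(_contaminant_record(rng, acc, cfg))
        ctrl.validate()
        controls.append(ctrl)

    truth = ApmsGroundTruth(
        bait_accession=cfg.bait_accession,
        true_interactor_accessions=frozenset(true_accs),
        contaminant_accessions=frozenset(cont_accs),
    )
    return bait_run, controls, truth


def contaminant_clear_prob(
    cfg: ApmsSimConfig, thresholds: FilterThresholds = FilterThresholds()
) -> float:
    """P(one contaminant clears all three threshold rules), analytically.

    Scores and coverages are uniform on their configured ranges and the
    peptide count is 1 with the configured probability, so the three
    rule-passing events are independent with closed-form probabilities.
    """
    def p_uniform_ge(lo_hi: tuple[float, float], cut: float) -> float:
        lo, hi = lo_hi
        if hi <= lo:
            return float(lo >= cut)
        return min(max((hi - cut) / (hi - lo), 0.0), 1.0)

    p_score = p_uniform_ge(cfg.contaminant_score_range, thresholds.min_score_exclusive)
    p_cov = p_uniform_ge(cfg.contaminant_coverage_range, thresholds.min_coverage)
    if thresholds.min_distinct_peptides <= 1:
        p_pep = 1.0
    elif thresholds.min_distinct_peptides <= cfg.contaminant_peptide_count_range[0]:
        p_pep = 1.0 - cfg.contaminant_single_peptide_prob
    else:
        lo, hi = cfg.contaminant_peptide_count_range
        n_vals = hi - lo + 1
        n_ok = max(hi - thresholds.min_distinct_peptides + 1, 0)
        p_pep = (1.0 - cfg.contaminant_single_peptide_prob) * n_ok / n_vals
    return p_score * p_cov * p_pep


def expected_false_positives(
    cfg: ApmsSimConfig, thresholds: FilterThresholds = FilterThresholds()
) -> float:
    """E[# contaminants surviving the full filter chain].

    A contaminant survives iff it misses all ``n_control_runs`` controls
    (prob ``(1-p)^n``) and clears the three threshold rules.
    """
    p_absent = (1.0 - cfg.contaminant_control_presence_prob) ** cfg.n_control_runs
    return cfg.n_contaminants * p_absent * contaminant_clear_prob(cfg, thresholds)


# ---------------------------------------------------------------------------
# Synthetic disc stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FocusSpec:
    """One planted apoptotic focus: center (row, col) in pixels, target
    area in um^2, and peak intensity as a multiple of basal."""

    center: tuple[int, int]
    area_um2: float
    intensity_multiple: float

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ConfigError("focus area must be > 0")
        if self.intensity_multiple < 0:
            raise ConfigError("focus intensity multiple must be >= 0")


@dataclass(frozen=True)
class DiscSimConfig:
    """Study conditions for the synthetic disc-stack generator.

    15 z planes at a 0.5 um step reflect the acquisition protocol being
    emulated; the 0.325 um/pixel default is an example calibration for a
    mid-magnification widefield objective, not an instrument-derived
    constant.  ``disc_fraction`` is the disc's share of the frame area
    and ``elav_fraction_of_disc`` the Elav sub-region's share of the
    disc.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_z: int = 15
    z_step: float = 0.5
    pixel_size: float = 0.325
    basal_level: float = 100.0
    noise_sd: float = 0.0
    disc_fraction: float = 0.35
    elav_fraction_of_disc: float = 0.40
    dapi_level: float = 200.0
    elav_level: float = 180.0
    background_level: float = 10.0
    foci: tuple[FocusSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be > 0")
        if not 0.0 < self.disc_fraction <= 1.0:
            raise ConfigError("disc_fraction must be in (0, 1]")
        if not 0.0 <= self.elav_fraction_of_disc <= 1.0:
            raise ConfigError("elav_fraction_of_disc must be in [0, 1]")
        if self.n_z < 1:
            raise ConfigError("need at least one z plane")
        if self.noise_sd < 0 or self.basal_level < 0:
            raise ConfigError("intensities must be >= 0")


@dataclass(frozen=True)
class PlantedFocusTruth:
    center: tuple[int, int]
    area_um2: float  # rasterized pixel count x pixel area
    n_pixels: int
    intensity: float  # absolute intensity in the caspase channel


@dataclass
class DiscTruth:
    """Ground truth for a generated stack (serializable to JSON)."""

    disc_area_um2: float
    disc_n_pixels: int
    elav_fraction_pct: float  # pixel-exact achieved fraction
    foci: list[PlantedFocusTruth]
    basal_level: float
    pixel_size: float

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path


def _ellipse_mask(shape: tuple[int, int], fraction: float) -> np.ndarray:
    """Centered filled ellipse (aspect 1.3) covering ~fraction of the frame."""
    h, w = shape
    target = fraction * h * w
    ratio = 1.3
    a = math.sqrt(target * ratio / math.pi)  # semi-axis along columns
    b = a / ratio
    rr, cc = np.mgrid[0:h, 0:w]
    return ((rr - (h - 1) / 2) / b) ** 2 + ((cc - (w - 1) / 2) / a) ** 2 <= 1.0


def _disk_pixels(
    shape: tuple[int, int], center: tuple[int, int], area_um2: float, pixel_size: float
) -> np.ndarray:
    """Boolean mask of a filled disk with ~area_um2 of pixel area."""
    radius_px = math.sqrt(area_um2 / math.pi) / pixel_size
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def generate_disc_image(cfg: DiscSimConfig) -> tuple[DiscImageStack, DiscTruth]:
    """Generate a calibrated 3-channel stack plus pixel-exact ground truth.

    DAPI fills the disc ellipse on every plane; Elav fills the posterior
    (right-hand) sub-region whose achieved pixel fraction is recorded as
    truth; the Caspase channel is basal + Gaussian noise everywhere with
    each planted focus written into one z plane at its stated multiple
    of basal, so the maximum-intensity projection contains it in full.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_shape
    disc = _ellipse_mask(cfg.image_shape, cfg.disc_fraction)
    n_disc = int(disc.sum())
    if n_disc == 0:
        raise ConfigError("disc_fraction too small: empty disc mask")

    # Elav sub-region: rightmost columns of the disc holding the target
    # share of disc pixels (posterior-to-the-furrow geometry).
    col_counts = disc.sum(axis=0)
    target_px = cfg.elav_fraction_of_disc * n_disc
    # cum_from_right[c] = disc pixels in columns >= c (non-increasing);
    # keep the largest cut whose right-hand slab still holds >= target.
    cum_from_right = np.cumsum(col_counts[::-1])[::-1]
    eligible = np.where(cum_from_right >= target_px)[0]
    if target_px <= 0 or eligible.size == 0:
        elav_region = np.zeros_like(disc)
    else:
        cut = int(eligible.max())
        elav_region = disc & (np.arange(w)[None, :] >= cut)
    n_elav = int(elav_region.sum())

    # Validate planted foci: inside the disc, pairwise disjoint.
    focus_masks: list[np.ndarray] = []
    occupied = np.zeros(cfg.image_shape, dtype=bool)
    for spec in cfg.foci:
        fm = _disk_pixels(cfg.image_shape, spec.center, spec.area_um2, cfg.pixel_size)
        if not fm.any():
            raise ConfigError(f"focus at {spec.center} rasterizes to zero pixels")
        if (fm & ~disc).any():
            raise ConfigError(f"focus at {spec.center} extends outside the disc")
        if (fm & occupied).any():
            raise ConfigError(f"focus at {spec.center} overlaps another focus")
        occupied |= fm
        focus_masks.append(fm)

    def noisy(base: np.ndarray) -> np.ndarray:
        planes = np.repeat(base[None, :, :], cfg.n_z, axis=0).astype(float)
        if cfg.noise_sd > 0:
            planes += rng.normal(0.0, cfg.noise_sd, size=planes.shape)
        return np.clip(planes, 0.0, None)

    bg = cfg.background_level
    dapi = noisy(np.where(disc, cfg.dapi_level, bg))
    elav = noisy(np.where(elav_region, cfg.elav_level, bg))

    caspase = noisy(np.full(cfg.image_shape, cfg.basal_level))
    truth_foci: list[PlantedFocusTruth] = []
    for spec, fm in zip(cfg.foci, focus_masks):
        z = int(rng.integers(0, cfg.n_z))
        intensity = spec.intensity_multiple * cfg.basal_level
        plane = caspase[z]
        plane[fm] = intensity
        truth_foci.append(
            PlantedFocusTruth(
                center=spec.center,
                area_um2=float(fm.sum()) * cfg.pixel_size**2,
                n_pixels=int(fm.sum()),
                intensity=float(intensity),
            )
        )

    stack = DiscImageStack(
        channels={"dapi": dapi, "elav": elav, "caspase": caspase},
        z_step=cfg.z_step,
        pixel_size=cfg.pixel_size,
    )
    truth = DiscTruth(
        disc_area_um2=float(n_disc) * cfg.pixel_size**2,
        disc_n_pixels=n_disc,
        elav_fraction_pct=100.0 * n_elav / n_disc,
        foci=truth_foci,
        basal_level=cfg.basal_level,
        pixel_size=cfg.pixel_size,
    )
    return stack, truth


def random_foci(
    cfg: DiscSimConfig,
    n: int,
    rng: np.random.Generator,
    area_range: tuple[float, float] = (4.0, 40.0),
    multiple_range: tuple[float, float] = (4.0, 6.0),
    margin_px: int = 3,
) -> tuple[FocusSpec, ...]:
    """Sample n non-overlapping focus specs that fit inside the disc.

    Centers are drawn where the distance to the disc boundary exceeds
    the focus radius plus a margin; candidates too close to an already
    placed focus are resampled.
    """
    disc = _ellipse_mask(cfg.image_shape, cfg.disc_fraction)
    edt = ndimage.distance_transform_edt(disc)
    placed: list[tuple[int, int, float]] = []  # row, col, radius_px
    specs: list[FocusSpec] = []
    for _ in range(n):
        for _attempt in range(10_000):
            area = float(rng.uniform(*area_range))
            r_px = math.sqrt(area / math.pi) / cfg.pixel_size
            valid = np.argwhere(edt > r_px + margin_px)
            if valid.size == 0:
                raise ConfigError("disc too small for requested focus areas")
            row, col = valid[rng.integers(0, len(valid))]
            if all(
                math.hypot(row - r0, col - c0) > r_px + r0px + margin_px
                for r0, c0, r0px in placed
            ):
                placed.append((int(row), int(col), r_px))
                specs.append(
                    FocusSpec(
                        center=(int(row), int(col)),
                        area_um2=area,
                        intensity_multiple=float(rng.uniform(*multiple_range)),
                    )
                )
                break
        else:  # pragma: no cover
            raise ConfigError("could not place non-overlapping foci")
    return tuple(specs)
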