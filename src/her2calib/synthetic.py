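"""Synthetic study generator: calibrator slides, lab cohorts, TMA scores, ISH.

Everything downstream of this module (bead quantification, LOD estimation,
consensus scoring, dynamic-range and diagnostic-accuracy analyses) is designed
for data produced by a multi-laboratory HER2 IHC survey: each participating
laboratory stains one calibrator slide (microbeads bearing defined HER2
peptide concentrations) plus one tissue-microarray (TMA) slide of 80 breast
carcinoma cores, which is then scored on the 5-level HER2 scale
{0, 0.5 (ultralow), 1, 2, 3} either by a pathologist or by image analysis.

Because no such physical dataset ships with the package, this module emulates
all of it with known ground truth:

* **Calibrator slides** -- RGB photomicrographs of DAB-stained microbead
  spots. Ten spots carry increasing HER2 concentrations, five carry an
  irrelevant peptide (negative controls). Per-bead chromogen intensity
  follows a log-linear dose-response clipped to a baseline below and a
  plateau above, so that the analytic lower limit of detection (LOD) of the
  simulated "assay" is an explicit input.
* **Lab cohorts** -- laboratories drawn per assay family with
  family-specific LOD means/SDs, mirroring the spread observed across
  commercial HER2 assays (roughly 5,000-80,000 molecules per
  cell-equivalent).
* **Score matrices** -- each lab's score of each core is a monotone step
  function of how far the core's latent HER2 expression sits above the
  readout's effective detection limit, perturbed by reader noise.
* **ISH tables** -- HER2/CEP17 ratios correlated with latent expression,
  with a configurable discordance rate and non-evaluable fraction.

All randomness flows from a single root seed; independent stages draw from
substreams derived by stable string labels, so partial re-runs are
bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import disk

__all__ = [
    "SCORE_LEVELS",
    "CALIBRATOR_CONCENTRATIONS",
    "CurveParams",
    "SpotLayout",
    "LabFamily",
    "SimConfig",
    "substream",
    "generate_calibrator_image",
    "generate_cores",
    "generate_lab_cohort",
    "deterministic_score",
    "generate_score_matrix",
    "generate_ish",
    "simulate_study",
]

#: The 5-level HER2 score scale; ultralow is tabulated as 0.5.
SCORE_LEVELS = (0.0, 0.5, 1.0, 2.0, 3.0)

#: Calibrator spot concentrations, molecules (ERF) per cell-equivalent.
#: Ten roughly log-spaced levels spanning 26,000-1,400,000.
CALIBRATOR_CONCENTRATIONS = np.array(
    [26, 40, 60, 90, 140, 210, 320, 500, 850, 1400], dtype=float
) * 1e3

#: Unit RGB absorbance profile of the DAB chromogen (colour-deconvolution
#: convention).  The renderer and the quantifier share this default.
DAB_RGB = np.array([0.26814753, 0.57031375, 0.77642715])
DAB_RGB = DAB_RGB / np.linalg.norm(DAB_RGB)


def substream(seed: int, label: str) -> np.random.Generator:
    """Return an RNG substream derived from ``seed`` and a stable label.

    The label is hashed with CRC-32 so that the mapping is stable across
    processes and Python versions (unlike ``hash()``).
    """
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(label.encode())])


# --------------------------------------------------------------------------
# Calibrator slide rendering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveParams:
    """Analytic dose-response of the simulated assay on calibrator beads.

    On the rising region the mean chromogen intensity of a bead bearing
    concentration ``x`` is ``a * ln(x) + b``, clipped below to the
    negative-control baseline and above to a saturation plateau.  The
    intercept ``b`` is not free: it is chosen so that the curve passes
    through ``neg_mean + 3 * neg_sd`` exactly at the requested true LOD,
    which is what the downstream LOD estimator is defined to recover.

    Intensities are in dimensionless chromogen units (the dot product of the
    background-subtracted RGB signal with the unit DAB profile).
    """

    slope: float = 60.0        # chromogen units per ln(concentration)
    neg_mean: float = 40.0     # baseline (background staining) intensity
    neg_sd: float = 2.0        # spread of negative-control bead intensities
    plateau: float = 250.0     # saturation intensity

    def total_neg_sd(self, bead_noise_sd: float = 0.0) -> float:
        """Realised blank variability: designed spread plus bead noise.

        The LOD is defined against the *measured* negative-control SD, which
        includes whatever per-bead noise the staining run adds, so the curve
        must be anchored to the combined spread.
        """
        return float(np.hypot(self.neg_sd, bead_noise_sd))

    def intercept(self, true_lod: float, bead_noise_sd: float = 0.0) -> float:
        y_star = self.neg_mean + 3.0 * self.total_neg_sd(bead_noise_sd)
        return y_star - self.slope * np.log(true_lod)

    def mean_intensity(self, concentration: float, true_lod: float,
                       bead_noise_sd: float = 0.0) -> float:
        """Clipped curve value for one spot concentration."""
        y = (self.slope * np.log(concentration)
             + self.intercept(true_lod, bead_noise_sd))
        return float(np.clip(y, self.neg_mean, self.plateau))

    @property
    def span(self) -> float:
        """Dynamic span of the rendered response (plateau minus baseline)."""
        return self.plateau - self.neg_mean


@dataclass(frozen=True)
class SpotLayout:
    """Geometry of a rendered calibrator slide.

    Fifteen spots on a 5 x 3 grid: the first ten (row-major) carry the
    calibrator concentrations in ascending order, the last five are negative
    controls.  Beads sit on a jittered grid inside each spot; jitter is
    bounded so beads can never touch, which makes segmentation recovery
    exactly checkable.
    """

    spot_pitch: int = 100
    margin: int = 50
    n_cols: int = 5
    n_rows: int = 3
    bead_radius: int = 6
    bead_pitch: int = 15
    bead_grid: int = 5          # 5x5 grid minus the centre position = 24 beads
    bead_jitter: int = 1
    spot_radius: float = 45.0   # assignment radius for detections

    @property
    def image_shape(self) -> tuple[int, int]:
        return (
            self.margin * 2 + self.spot_pitch * (self.n_rows - 1),
            self.margin * 2 + self.spot_pitch * (self.n_cols - 1),
        )

    @property
    def beads_per_spot(self) -> int:
        return self.bead_grid**2 - 1

    def spot_centers(self) -> list[tuple[int, int]]:
        """(x, y) centres of the 15 spots, row-major."""
        return [
            (self.margin + self.spot_pitch * c, self.margin + self.spot_pitch * r)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
        ]

    def spot_table(self) -> pd.DataFrame:
        """Spot id, centre and concentration (NaN for negative controls)."""
        rows = []
        for i, (x, y) in enumerate(self.spot_centers()):
            conc = CALIBRATOR_CONCENTRATIONS[i] if i < 10 else np.nan
            rows.append(
                {"spot_id": i, "x": x, "y": y,
                 "concentration": conc, "is_negative": i >= 10}
            )
        return pd.DataFrame(rows)


def _negative_pattern(n: int) -> np.ndarray:
    """Deterministic zero-mean, unit-sample-SD pattern of length ``n``.

    Negative-control beads carry ``neg_mean + neg_sd * pattern`` so that the
    *measured* negative mean and SD equal the designed ones even in the
    zero-noise limit; an i.i.d. draw would make the noise-free round trip
    depend on sampling error of the SD.
    """
    z = np.cos(np.arange(n) * 2.3999632297286533)  # golden-angle quasi-pattern
    z = z - z.mean()
    return z / z.std(ddof=1)


def generate_calibrator_image(
    true_lod: float,
    curve: CurveParams = CurveParams(),
    bead_noise_sd: float = 0.0,
    seed: int = 0,
    layout: SpotLayout = SpotLayout(),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render one stained calibrator slide and its ground-truth bead table.

    Parameters
    ----------
    true_lod:
        Analytic LOD of the simulated assay, molecules per cell-equivalent.
        The rendered dose-response crosses ``neg_mean + 3 neg_sd`` exactly
        here.
    curve:
        Dose-response parameters; must imply non-negative intensities.
    bead_noise_sd:
        SD of i.i.d. Gaussian noise added to each bead's intensity, in
        chromogen units.
    seed:
        Root seed for bead jitter, noise and rendering dither.

    Returns
    -------
    image:
        8-bit RGB array, white background, one brown (DAB) filled circle per
        bead.  Anti-aliasing is off and centres are integral.
    truth:
        One row per bead: ``spot_id, concentration, x, y, radius,
        intensity`` where intensity is the realised (noisy, non-negative)
        chromogen value the renderer encoded.

    Notes
    -----
    Each bead's pixels are ``255 - (intensity * dab_profile)`` with
    *stochastic rounding* to 8 bits, so the mean recovered intensity over a
    bead's pixels is unbiased to well below one chromogen unit.  The
    ground-truth table records the pre-quantisation value.  The baseline
    (background staining) level is set high enough that even negative-control
    beads remain clearly segmentable under the default noise level.
    """
    if curve.slope <= 0:
        raise ValueError("curve slope must be positive")
    if curve.neg_mean - 3 * curve.neg_sd < 0 or curve.neg_mean < 0:
        raise ValueError("curve parameters imply negative intensities")
    if curve.plateau * DAB_RGB.max() > 255:
        raise ValueError("plateau too high for 8-bit rendering")

    rng = substream(seed, "calibrator-image")
    shape = layout.image_shape
    img = np.full(shape + (3,), 255, dtype=np.uint8)

    n_neg_beads = 5 * layout.beads_per_spot
    neg_pattern = _negative_pattern(n_neg_beads)

    half = (layout.bead_grid - 1) * layout.bead_pitch // 2
    rows = []
    i_neg = 0
    for spot_id, (sx, sy) in enumerate(layout.spot_centers()):
        negative = spot_id >= 10
        conc = np.nan if negative else CALIBRATOR_CONCENTRATIONS[spot_id]
        for gy in range(layout.bead_grid):
            for gx in range(layout.bead_grid):
                if gx == layout.bead_grid // 2 and gy == layout.bead_grid // 2:
                    continue  # keep the centre clear: 24 beads per spot
                j = layout.bead_jitter
                bx = sx - half + gx * layout.bead_pitch + int(rng.integers(-j, j + 1))
                by = sy - half + gy * layout.bead_pitch + int(rng.integers(-j, j + 1))
                if negative:
                    base = curve.neg_mean + curve.neg_sd * neg_pattern[i_neg]
                    i_neg += 1
                else:
                    base = curve.mean_intensity(conc, true_lod, bead_noise_sd)
                intensity = max(base + bead_noise_sd * rng.standard_normal(), 0.0)
                rr, cc = disk((by, bx), layout.bead_radius, shape=shape)
                target = intensity * DAB_RGB
                # stochastic rounding keeps the pixel-mean unbiased in 8 bits
                quantised = np.floor(target[None, :] + rng.random((rr.size, 3)))
                img[rr, cc] = (255 - quantised).astype(np.uint8)
                rows.append(
                    {"spot_id": spot_id, "concentration": conc,
                     "x": bx, "y": by, "radius": layout.bead_radius,
                     "intensity": intensity}
                )
    return img, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Cohort, cores, scores, ISH
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LabFamily:
    """One assay family in the cohort: LODs are N(lod_mean, lod_sd) > 0."""

    assay: str
    n_labs: int
    lod_mean: float
    lod_sd: float


def _default_cohort() -> tuple[LabFamily, ...]:
    # Families span the observed commercial range: the unmodified predicate
    # assay around 54,436 +/- 19,569, protocol-optimised variants in the
    # 30-50k band, an alternative detection system near 25k, and the
    # high-sensitivity monoclonal kit below 20k.
    return (
        LabFamily("4B5-IFU", 18, 54_436.0, 19_569.0),
        LabFamily("4B5-LDT", 12, 40_000.0, 8_000.0),
        LabFamily("4B5-Optiview", 12, 25_000.0, 5_000.0),
        LabFamily("mHercepTest", 12, 12_000.0, 4_000.0),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of one simulated survey.

    The defaults are the package's reference study conditions: an 80-core TMA
    with 20 cores per intended HER2 category, a 54-lab cohort spanning LODs
    of roughly 5,000-80,000 molecules per cell-equivalent, manual reader
    noise five times the image-analysis noise, and a manual visual detection
    floor of 45,000 molecules (pathologists cannot appreciate staining an
    assay produces below that level, however sensitive the chemistry).
    """

    seed: int = 0
    cores_per_category: tuple[int, int, int, int] = (20, 20, 20, 20)
    lab_cohort: tuple[LabFamily, ...] = field(default_factory=_default_cohort)
    image_analysis_arm: bool = True     # read every slide by IA as well
    reader_noise_manual: float = 0.5    # score-scale SD
    reader_noise_ia: float = 0.1        # score-scale SD
    manual_detection_floor: float = 45_000.0  # molecules/cell-equivalent
    ish_discordance_rate: float = 0.04
    ish_nonevaluable_rate: float = 7.0 / 80.0
    bead_noise_sd: float = 10.5         # 5% of the calibrator dynamic span
    category_medians: tuple[float, ...] = (15e3, 100e3, 350e3, 1.5e6)
    category_log_sd: float = 0.5
    # score thresholds as latent/LOD ratios: detectable, then 1+, 2+, 3+
    score_ratio_thresholds: tuple[float, ...] = (1.0, 2.0, 6.0, 20.0)
    ish_amplified_latent: float = 700e3
    curve: CurveParams = field(default_factory=CurveParams)
    min_lod: float = 3_000.0            # truncation for LOD draws

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.cores_per_category):
            raise ValueError("cores_per_category must be non-negative")
        for sd in (self.reader_noise_manual, self.reader_noise_ia,
                   self.category_log_sd, self.bead_noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        for p in (self.ish_discordance_rate, self.ish_nonevaluable_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if list(self.score_ratio_thresholds) != sorted(self.score_ratio_thresholds):
            raise ValueError("score thresholds must be increasing")

    @property
    def n_cores(self) -> int:
        return sum(self.cores_per_category)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def generate_cores(config: SimConfig) -> pd.DataFrame:
    """Draw the latent TMA: one row per core.

    Latent expression is log-normal around the configured per-category
    median, so each intended category (0-3+) occupies its own expression
    quartile on the median scale while adjacent categories overlap in the
    tails, as graded clinical material does.

    Columns: ``core_id, category, latent_expression``.
    """
    rng = substream(config.seed, "cores")
    rows = []
    for cat, (n, med) in enumerate(zip(config.cores_per_category,
                                       config.category_medians)):
        latent = np.exp(np.log(med)
                        + config.category_log_sd * rng.standard_normal(n))
        for i, lat in enumerate(latent):
            rows.append({"core_id": f"C{cat}{i:02d}", "category": cat,
                         "latent_expression": float(lat)})
    return pd.DataFrame(rows)


def generate_lab_cohort(config: SimConfig) -> pd.DataFrame:
    """Draw the laboratory cohort with true LODs.

    Each physical lab stains one slide; its scores exist as a manual-readout
    arm and, when ``image_analysis_arm`` is set, an image-analysis arm over
    the same staining (same true LOD).  Arms are distinct lab_ids suffixed
    ``-M`` / ``-IA`` so every downstream selection can filter on readout.

    Columns: ``lab_id, assay, readout, true_lod``.
    """
    rng = substream(config.seed, "labs")
    rows = []
    k = 0
    for fam in config.lab_cohort:
        if fam.lod_mean <= 0 or fam.lod_sd < 0:
            raise ValueError("family LOD parameters must be positive")
        lods = fam.lod_mean + fam.lod_sd * rng.standard_normal(fam.n_labs)
        lods = np.clip(lods, config.min_lod, None)
        for lod in lods:
            base = f"L{k:03d}"
            k += 1
            rows.append({"lab_id": f"{base}-M", "assay": fam.assay,
                         "readout": "manual", "true_lod": float(lod)})
            if config.image_analysis_arm:
                rows.append({"lab_id": f"{base}-IA", "assay": fam.assay,
                             "readout": "image_analysis", "true_lod": float(lod)})
    return pd.DataFrame(rows)


def deterministic_score(
    latent_expression: np.ndarray | float,
    effective_lod: float,
    ratio_thresholds: tuple[float, ...] = SimConfig().score_ratio_thresholds,
) -> np.ndarray:
    """Noise-free score: a monotone step function of latent/LOD.

    A core scores 0 while its expression sits below the effective detection
    limit, 0.5 (ultralow) once detectable, and 1/2/3 as expression exceeds
    the configured multiples of the limit.  Lowering the LOD can therefore
    never lower any core's noise-free score.
    """
    ratio = np.asarray(latent_expression, dtype=float) / float(effective_lod)
    score = np.zeros_like(ratio)
    for thr, level in zip(ratio_thresholds, (0.5, 1.0, 2.0, 3.0)):
        score = np.where(ratio >= thr, level, score)
    return score


def snap_to_levels(values: np.ndarray, levels=SCORE_LEVELS) -> np.ndarray:
    """Map values to the nearest allowed score; exact midpoints go down."""
    lv = np.asarray(levels, dtype=float)
    idx = np.argmin(np.abs(np.asarray(values, dtype=float)[..., None] - lv), axis=-1)
    return lv[idx]


def generate_score_matrix(
    cores: pd.DataFrame,
    labs: pd.DataFrame,
    config: SimConfig,
) -> pd.DataFrame:
    """Score every core in every lab/readout arm.

    The observed score is the deterministic step-function score at the arm's
    *effective* LOD (the assay LOD, floored at the visual detection limit for
    manual readouts), plus additive Gaussian reader noise on the score scale,
    snapped back to the 5-level set.  Image analysis reads the true assay
    sensitivity with small noise; manual readout is both noisier and blind to
    staining below its perceptual floor.

    Long format: ``core_id, lab_id, score``.
    """
    required = {"core_id", "latent_expression"}
    if not required <= set(cores.columns):
        raise ValueError("cores must carry core_id and latent_expression")
    if not {"lab_id", "readout", "true_lod"} <= set(labs.columns):
        raise ValueError("labs must carry lab_id, readout and true_lod")

    rng = substream(config.seed, "scores")
    latent = cores["latent_expression"].to_numpy()
    out = []
    for lab in labs.itertuples(index=False):
        if lab.readout == "manual":
            eff = max(lab.true_lod, config.manual_detection_floor)
            sd = config.reader_noise_manual
        else:
            eff = lab.true_lod
            sd = config.reader_noise_ia
        det = deterministic_score(latent, eff, config.score_ratio_thresholds)
        obs = snap_to_levels(det + sd * rng.standard_normal(latent.size))
        out.append(pd.DataFrame({
            "core_id": cores["core_id"].to_numpy(),
            "lab_id": lab.lab_id,
            "score": obs,
        }))
    return pd.concat(out, ignore_index=True)


def generate_ish(cores: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """ISH results per core: HER2/CEP17 ratio plus an evaluable flag.

    Cores above the amplification latent threshold draw a ratio >= 2; the
    rest draw a ratio below 2.  With probability ``ish_discordance_rate`` a
    core's ratio is drawn from the *other* side (gene amplification without
    protein, or vice versa), reproducing the handful of IHC-low/ISH-amplified
    discordant cases such surveys observe.  A configurable fraction of cores
    is flagged non-evaluable for technical reasons.

    Columns: ``core_id, ish_ratio, ish_evaluable``.
    """
    rng = substream(config.seed, "ish")
    rows = []
    for core in cores.itertuples(index=False):
        amplified = core.latent_expression >= config.ish_amplified_latent
        if rng.random() < config.ish_discordance_rate:
            amplified = not amplified
        if amplified:
            ratio = 2.0 + 1.2 * abs(rng.standard_normal())
        else:
            ratio = rng.uniform(0.8, 1.9)
        rows.append({
            "core_id": core.core_id,
            "ish_ratio": float(ratio),
            "ish_evaluable": bool(rng.random() >= config.ish_nonevaluable_rate),
        })
    return pd.DataFrame(rows)


def simulate_study(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Generate the full tabular study: cores, labs, scores and ISH.

    Calibrator images are rendered separately (one slide per lab is costly);
    see :func:`generate_calibrator_image`.
    """
    cores = generate_cores(config)
    labs = generate_lab_cohort(config)
    scores = generate_score_matrix(cores, labs, config)
    ish = generate_ish(cores, config)
    return {"cores": cores, "labs": labs, "scores": scores, "ish": ish}
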