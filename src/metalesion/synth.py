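"""Seeded synthetic cohorts of metabolic-lesion images and score batteries.

The generator emulates the statistical structure the downstream analysis
assumes: ~159 subjects on a coarse (10 mm) grey-matter grid of roughly 2,000
voxels; focal *graded* hypometabolic lesions with near-isotropic spatial
covariance (Gaussian intensity profiles); a binary anisotropic "vascular"
comparator produced by thresholding elongated ellipsoidal fields; per-subject
multiplicative background scaling (global / white-matter / ventricular,
mimicking tracer dose and uptake-time variation); lesion->score effects of
both signs mixed into a correlated multi-instrument battery through a low-rank
factor loading matrix; and missingness at ~24% per instrument, either
completely at random or concentrated on low scorers.

Every quantity the generator draws is recorded in a :class:`GroundTruth`
object for parameter-recovery testing; inference code never reads it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .containers import BinaryLesionStack, CohortStack, GreyMatterMask, ScoreTable
from .volumes import ImageVolume, write_volume

__all__ = [
    "SyntheticCohortConfig",
    "GroundTruth",
    "brain_compartments",
    "default_effect_map",
    "default_instrument_loadings",
    "generate_metabolic_cohort",
    "generate_vascular_comparator",
    "apply_missingness",
    "write_cohort",
]

FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))

# Instruments named after the battery the cohort emulates: WAIS subscales,
# verbal/visual memory, recognition memory, fluency, and affect (HADS, where
# a higher score means worse affect).
DEFAULT_INSTRUMENTS: tuple[str, ...] = (
    "verbal_iq",
    "performance_iq",
    "full_scale_iq",
    "digit_span",
    "arithmetic",
    "block_design",
    "list_learning",
    "design_learning",
    "recognition_words",
    "recognition_faces",
    "naming",
    "phonemic_fluency",
    "semantic_fluency",
    "processing_speed",
    "hads_anxiety",
    "hads_depression",
)
HIGHER_IS_WORSE: dict[str, bool] = {"hads_anxiety": True, "hads_depression": True}


class ConfigurationError(ValueError):
    """Raised for non-finite or out-of-range generator settings."""


def brain_compartments(
    grid_shape: tuple[int, int, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ellipsoidal grey-matter shell, white-matter core and ventricles.

    Returns boolean grids (grey, white, ventricular).  On the default
    20 x 24 x 20 grid the grey shell holds ~1,900 voxels, matching the
    working resolution of a coarse whole-brain PET analysis.
    """
    shape = np.asarray(grid_shape, dtype=float)
    centre = (shape - 1) / 2.0
    ijk = np.stack(
        np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij"), axis=-1
    ).astype(float)
    rel = (ijk - centre) / (shape / 2.0)  # normalized [-1, 1] coordinates
    r2 = (rel**2).sum(axis=-1)
    brain = r2 <= 0.88**2
    white = r2 <= 0.655**2
    vent = r2 <= 0.18**2
    grey = brain & ~white
    white = white & ~vent
    return grey, white, vent


def default_effect_map(mask: GreyMatterMask) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Two implanted spherical effect regions on the in-mask voxels.

    Returns ``(effect_map, regions)`` where ``effect_map[v]`` is the signed
    slope d(score)/d(lesion load) at voxel ``v``:

    * a *deficit* region (slope -1): lesion load lowers the score, so
      hypometabolism there accompanies impairment and surfaces in the
      positive-tail deficit map;
    * an *enhancement* region (slope +1), surfacing in the negative tail.

    ``regions`` maps ``{"deficit", "enhancement"}`` to boolean in-mask
    indicator vectors.
    """
    coords = mask.coordinates().astype(float)
    shape = np.asarray(mask.shape, dtype=float)
    centre = (shape - 1) / 2.0
    # anterior-left and posterior-right loci, placed mid-shell
    c_def = centre + np.array([-0.55, +0.45, 0.10]) * (shape / 2.0)
    c_enh = centre + np.array([+0.55, -0.45, 0.10]) * (shape / 2.0)
    radius_vox = 2.6
    d_def = np.linalg.norm(coords - c_def, axis=1)
    d_enh = np.linalg.norm(coords - c_enh, axis=1)
    deficit = d_def <= radius_vox
    enhancement = d_enh <= radius_vox
    effect = np.zeros(mask.n_voxels)
    effect[deficit] = -1.0
    effect[enhancement] = +1.0
    return effect, {"deficit": deficit, "enhancement": enhancement}


def default_instrument_loadings(
    n_instruments: int = 16, n_factors: int = 3
) -> np.ndarray:
    """Deterministic low-rank loading matrix (instruments x factors).

    Factor 1 is the lesion-driven deficit factor, loading positively on all
    instruments (0.55-0.85); factors 2+ are lesion-independent traits with
    smooth alternating loadings, giving the battery the strong inter-test
    correlation that makes latent-factor imputation worthwhile.
    """
    i = np.arange(n_instruments)
    cols = [0.55 + 0.30 * (np.cos(2 * np.pi * i / n_instruments) + 1) / 2]
    for f in range(1, n_factors):
        cols.append(0.5 * np.sin(2 * np.pi * (f + 1) * i / n_instruments + 0.7 * f))
    return np.column_stack(cols)


@dataclass
class SyntheticCohortConfig:
    """Settings for one synthetic cohort; identical config + seed gives a
    bit-identical cohort.

    ``lesion_amplitude`` is the fractional signal reduction at a focus centre
    (0.4 = 40% hypometabolism); ``lesion_radius_mm`` its Gaussian SD;
    ``lesion_anisotropy`` per-axis radius multipliers ((1,1,1) = isotropic);
    ``n_lesion_foci_per_subject`` an inclusive (low, high) uniform-integer
    range; ``effect_map`` voxel-indexed signed slopes d(score)/d(load) (None =
    built-in two-region default); ``background_scale_sd`` the log-SD of the
    per-subject multiplicative (global, white-matter, ventricular) scalings.
    """

    n_subjects: int = 159
    grid_shape: tuple[int, int, int] = (20, 24, 20)
    voxel_size_mm: float = 10.0
    n_lesion_foci_per_subject: tuple[int, int] = (1, 2)
    lesion_amplitude: float = 0.4
    lesion_radius_mm: float = 15.0
    lesion_anisotropy: tuple[float, float, float] = (1.0, 1.0, 1.0)
    effect_map: np.ndarray | None = None
    score_noise_sd: float = 0.5
    n_instruments: int = 16
    n_factors: int = 3
    instrument_loadings: np.ndarray | None = None
    background_scale_sd: float = 0.10
    missing_rate: float = 0.24
    missing_mechanism: str = "MCAR"  # or "score-dependent"
    seed: int = 0

    def validate(self) -> None:
        def _finite(name: str, v: float) -> float:
            v = float(v)
            if not np.isfinite(v):
                raise ConfigurationError(f"{name} must be finite, got {v}")
            return v

        if int(self.n_subjects) < 0:
            raise ConfigurationError("n_subjects must be >= 0")
        if len(self.grid_shape) != 3 or any(int(g) < 1 for g in self.grid_shape):
            raise ConfigurationError("grid_shape must be 3 positive integers")
        if _finite("voxel_size_mm", self.voxel_size_mm) <= 0:
            raise ConfigurationError("voxel_size_mm must be > 0")
        lo, hi = (int(x) for x in self.n_lesion_foci_per_subject)
        if lo < 0 or hi < lo:
            raise ConfigurationError("n_lesion_foci_per_subject must be 0 <= low <= high")
        if not 0.0 <= _finite("lesion_amplitude", self.lesion_amplitude) <= 1.0:
            raise ConfigurationError("lesion_amplitude must lie in [0, 1]")
        if _finite("lesion_radius_mm", self.lesion_radius_mm) < 0:
            raise ConfigurationError("lesion_radius_mm must be >= 0")
        if len(self.lesion_anisotropy) != 3 or any(
            _finite("lesion_anisotropy", a) <= 0 for a in self.lesion_anisotropy
        ):
            raise ConfigurationError("lesion_anisotropy must be 3 positive scalars")
        if _finite("score_noise_sd", self.score_noise_sd) < 0:
            raise ConfigurationError("score_noise_sd must be >= 0")
        if int(self.n_instruments) < 1 or int(self.n_factors) < 1:
            raise ConfigurationError("n_instruments and n_factors must be >= 1")
        if _finite("background_scale_sd", self.background_scale_sd) < 0:
            raise ConfigurationError("background_scale_sd must be >= 0")
        if not 0.0 <= _finite("missing_rate", self.missing_rate) <= 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1]")
        if self.missing_mechanism not in ("MCAR", "score-dependent"):
            raise ConfigurationError(
                f"unknown missing_mechanism {self.missing_mechanism!r}"
            )


@dataclass
class GroundTruth:
    """Everything the generator drew, for parameter-recovery tests only.

    ``effect_map`` uses the d(score)/d(load) sign convention;
    ``effect_regions`` holds boolean in-mask indicators of the implanted
    deficit (positive-tail) and enhancement (negative-tail) regions.
    Inference modules must never consume this object.
    """

    lesion_centres: list[np.ndarray]  # per subject, (n_foci, 3) voxel coords
    lesion_sigmas_vox: np.ndarray  # per-axis Gaussian SDs in voxels
    effect_map: np.ndarray
    effect_regions: dict[str, np.ndarray]
    deficit_factor: np.ndarray  # standardized lesion-driven latent, per subject
    latent_factors: np.ndarray  # (n_subjects, n_factors), factor 0 = deficit
    scores_prenoise: np.ndarray  # (n_subjects, n_instruments), oriented units
    background_scales: np.ndarray  # (n_subjects, 3): global, WM, ventricular
    lesion_load: np.ndarray  # (n_subjects, n_in_mask_voxels)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "lesion_centres": [c.tolist() for c in self.lesion_centres],
            "lesion_sigmas_vox": self.lesion_sigmas_vox.tolist(),
            "effect_map": self.effect_map.tolist(),
            "effect_regions": {k: v.tolist() for k, v in self.effect_regions.items()},
            "deficit_factor": self.deficit_factor.tolist(),
            "latent_factors": self.latent_factors.tolist(),
            "scores_prenoise": self.scores_prenoise.tolist(),
            "background_scales": self.background_scales.tolist(),
        }
        path.write_text(json.dumps(payload))
        return path


def _baseline_field(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Deterministic smooth positive baseline metabolism field (a.u.)."""
    axes = [np.linspace(0, np.pi, n) for n in grid_shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    ripple = 0.15 * np.sin(2 * gx) * np.cos(1.5 * gy) + 0.10 * np.cos(2.5 * gz)
    return 100.0 * (1.0 + ripple)


def _lesion_load(
    centres: np.ndarray, sigmas_vox: np.ndarray, coords: np.ndarray, amplitude: float
) -> np.ndarray:
    """Summed Gaussian lesion profile at ``coords`` for one subject."""
    if len(centres) == 0 or amplitude == 0.0:
        return np.zeros(len(coords))
    load = np.zeros(len(coords))
    for c in centres:
        d = (coords - c) / np.maximum(sigmas_vox, 1e-12)
        load += amplitude * np.exp(-0.5 * (d**2).sum(axis=1))
    return load


def generate_metabolic_cohort(
    config: SyntheticCohortConfig,
) -> tuple[CohortStack, ScoreTable, GroundTruth]:
    """Generate a seeded cohort of graded hypometabolic-lesion volumes.

    Each subject volume is a smooth baseline field scaled by that subject's
    compartment multipliers (grey/white tissue by the global factor, the
    white core additionally by the white-matter factor, ventricles by the
    ventricular factor), multiplied by ``1 - load`` where ``load`` sums
    Gaussian lesion profiles.  Instrument scores mix a standardized
    lesion-driven deficit factor (load weighted by the effect map) with
    lesion-independent latent traits through the loading matrix, plus
    Gaussian noise.  Missingness is applied per ``config``; the returned
    ScoreTable stores raw units (HADS columns flipped so higher = worse).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    grey, white, vent = brain_compartments(config.grid_shape)
    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])
    mask = GreyMatterMask(grey, affine, config.voxel_size_mm)
    all_coords = np.stack(
        np.meshgrid(*[np.arange(n) for n in config.grid_shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)

    if config.effect_map is None:
        effect_map, regions = default_effect_map(mask)
    else:
        effect_map = np.asarray(config.effect_map, dtype=float)
        if effect_map.shape != (mask.n_voxels,):
            raise ConfigurationError(
                f"effect_map must have {mask.n_voxels} entries (one per in-mask voxel)"
            )
        if not np.all(np.isfinite(effect_map)):
            raise ConfigurationError("effect_map contains non-finite entries")
        regions = {"deficit": effect_map < 0, "enhancement": effect_map > 0}

    loadings = (
        default_instrument_loadings(config.n_instruments, config.n_factors)
        if config.instrument_loadings is None
        else np.asarray(config.instrument_loadings, dtype=float)
    )
    if loadings.shape != (config.n_instruments, config.n_factors):
        raise ConfigurationError(
            "instrument_loadings must be (n_instruments, n_factors)"
        )

    n = int(config.n_subjects)
    baseline = _baseline_field(config.grid_shape)
    sigmas_vox = (
        config.lesion_radius_mm
        * np.asarray(config.lesion_anisotropy, dtype=float)
        / config.voxel_size_mm
    )
    gm_idx = mask.indices
    gm_coords = mask.coordinates().astype(float)
    lo, hi = (int(x) for x in config.n_lesion_foci_per_subject)

    volumes = np.empty((n,) + tuple(config.grid_shape))
    load_gm = np.empty((n, mask.n_voxels))
    centres_all: list[np.ndarray] = []
    bg = np.exp(rng.normal(0.0, config.background_scale_sd, size=(n, 3)))
    for s in range(n):
        n_foci = int(rng.integers(lo, hi + 1))
        centres = gm_coords[rng.integers(0, len(gm_coords), size=n_foci)]
        centres_all.append(centres)
        load_full = _lesion_load(
            centres, sigmas_vox, all_coords.astype(float), config.lesion_amplitude
        ).reshape(config.grid_shape)
        vol = baseline * bg[s, 0]
        vol = np.where(white, vol * bg[s, 1], vol)
        vol = np.where(vent, vol * 0.35 * bg[s, 2] / bg[s, 0], vol)
        vol = vol * np.clip(1.0 - load_full, 0.0, None)
        vol = np.where(grey | white | vent, vol, 0.0)
        volumes[s] = vol
        load_gm[s] = load_full.ravel()[gm_idx]

    # lesion-driven deficit factor: effect-weighted load, standardized
    # (SD-division only, sign preserved)
    u_raw = load_gm @ effect_map
    sd = u_raw.std(ddof=0) if n > 0 else 0.0
    mu = u_raw.mean() if n > 0 else 0.0
    u = (u_raw - mu) / sd if sd > 0 else u_raw - mu
    factors = np.column_stack(
        [u, rng.standard_normal((n, config.n_factors - 1))]
        if config.n_factors > 1
        else [u]
    )
    prenoise = factors @ loadings.T
    oriented_scores = prenoise + rng.normal(
        0.0, config.score_noise_sd, size=prenoise.shape
    )

    names = (
        list(DEFAULT_INSTRUMENTS[: config.n_instruments])
        if config.n_instruments <= len(DEFAULT_INSTRUMENTS)
        else [f"instrument_{i:02d}" for i in range(config.n_instruments)]
    )
    flags = {nm: HIGHER_IS_WORSE.get(nm, False) for nm in names}
    raw = oriented_scores.copy()
    for j, nm in enumerate(names):
        if flags[nm]:
            raw[:, j] = -raw[:, j]
    subject_ids = [f"sub-{s:03d}" for s in range(n)]
    scores = ScoreTable(
        pd.DataFrame(raw, index=subject_ids, columns=names), flags
    )
    scores = apply_missingness(
        scores,
        config.missing_rate,
        config.missing_mechanism,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    stack = CohortStack(
        data=volumes.reshape(n, -1)[:, gm_idx] if n else np.empty((0, mask.n_voxels)),
        subject_ids=subject_ids,
        mask=mask,
        volumes=volumes,
    )
    truth = GroundTruth(
        lesion_centres=centres_all,
        lesion_sigmas_vox=sigmas_vox,
        effect_map=effect_map,
        effect_regions=regions,
        deficit_factor=u,
        latent_factors=factors,
        scores_prenoise=prenoise,
        background_scales=bg,
        lesion_load=load_gm,
    )
    return stack, scores, truth


def generate_vascular_comparator(
    config: SyntheticCohortConfig,
    territory_template: np.ndarray | None = None,
) -> BinaryLesionStack:
    """Binary anisotropic lesion maps emulating vascular-territory structure.

    Each subject receives ellipsoidal binary lesions: a voxel is lesioned
    when its anisotropy-scaled distance to a focus centre is at most the
    lesion radius, so co-lesion dependence elongates along the axes with
    anisotropy > 1.  Alternatively a boolean ``territory_template`` (grid
    shaped) restricts lesions to a fixed territory.  An isotropic config
    without a template is rejected: the comparator would be
    indistinguishable from the metabolic maps.
    """
    config.validate()
    iso = np.allclose(config.lesion_anisotropy, 1.0)
    if iso and territory_template is None:
        raise ConfigurationError(
            "vascular comparator requires anisotropy != (1,1,1) or a territory template"
        )
    rng = np.random.default_rng(config.seed)
    grey, _, _ = brain_compartments(config.grid_shape)
    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])
    mask = GreyMatterMask(grey, affine, config.voxel_size_mm)
    gm_coords = mask.coordinates().astype(float)
    if territory_template is not None:
        territory_template = np.asarray(territory_template, dtype=bool)
        if territory_template.shape != tuple(config.grid_shape):
            raise ConfigurationError("territory template grid mismatch")
        in_territory = territory_template.ravel()[mask.indices]
        if not in_territory.any():
            raise ConfigurationError("territory template covers no in-mask voxel")
    else:
        in_territory = np.ones(mask.n_voxels, dtype=bool)

    radius_vox = config.lesion_radius_mm / config.voxel_size_mm
    semi_axes = np.maximum(
        radius_vox * np.asarray(config.lesion_anisotropy, dtype=float), 1e-12
    )
    n = int(config.n_subjects)
    lo, hi = (int(x) for x in config.n_lesion_foci_per_subject)
    candidate_coords = gm_coords[in_territory]
    data = np.zeros((n, mask.n_voxels), dtype=bool)
    for s in range(n):
        n_foci = int(rng.integers(lo, hi + 1))
        centres = candidate_coords[rng.integers(0, len(candidate_coords), size=n_foci)]
        for c in centres:
            d2 = (((gm_coords - c) / semi_axes) ** 2).sum(axis=1)
            data[s] |= d2 <= 1.0
        data[s] &= in_territory
    return BinaryLesionStack(data, mask, source="synthetic")


def apply_missingness(
    scores: ScoreTable,
    rate: float,
    mechanism: str = "MCAR",
    seed: int = 0,
) -> ScoreTable:
    """Mask score entries as missing at marginal rate ``rate``.

    ``MCAR`` masks each entry independently with probability ``rate``.
    ``score-dependent`` masks low scorers preferentially: per instrument the
    masking probability is ``rate * w / mean(w)`` with logistic weight
    ``w = 1 / (1 + exp(z))`` of the oriented z-score (monotone decreasing in
    performance), clipped to [0, 1]; the marginal rate stays ``rate`` up to
    clipping.  Already-missing entries stay missing.
    """
    rate = float(rate)
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError(f"missing rate must lie in [0, 1], got {rate}")
    if mechanism not in ("MCAR", "score-dependent"):
        raise ConfigurationError(f"unknown missing mechanism {mechanism!r}")
    out = scores.copy()
    if rate == 0.0 or out.values.size == 0:
        return out
    rng = np.random.default_rng(seed)
    vals = out.values.to_numpy(dtype=float)
    if mechanism == "MCAR":
        drop = rng.random(vals.shape) < rate
    else:
        drop = np.zeros(vals.shape, dtype=bool)
        for j, instrument in enumerate(out.instruments):
            col = out.oriented(instrument)
            obs = np.isfinite(col)
            z = np.zeros_like(col)
            if obs.sum() > 1 and np.nanstd(col[obs]) > 0:
                z[obs] = (col[obs] - col[obs].mean()) / col[obs].std(ddof=0)
            w = 1.0 / (1.0 + np.exp(z))
            p = np.clip(rate * w / w[obs].mean() if obs.any() else rate * w, 0.0, 1.0)
            drop[:, j] = rng.random(len(col)) < p
    vals[drop] = np.nan
    out.values.iloc[:, :] = vals
    return out


def write_cohort(
    stack: CohortStack,
    scores: ScoreTable,
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, list[str] | str]:
    """Persist a cohort: one NIfTI per subject, scores CSV, truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if stack.volumes is None:
        raise ValueError("stack carries no full volumes to write")
    image_paths = []
    for s, sid in enumerate(stack.subject_ids):
        p = write_volume(
            ImageVolume(stack.volumes[s], stack.mask.affine, space="synthetic"),
            out_dir / f"{sid}_fdg.nii.gz",
        )
        image_paths.append(str(p))
    scores_path = scores.to_csv(out_dir / "scores.csv")
    truth_path = truth.to_json(out_dir / "ground_truth.json")
    mask_path = write_volume(
        ImageVolume(
            stack.mask.grid.astype(float), stack.mask.affine, space="synthetic"
        ),
        out_dir / "grey_matter_mask.nii.gz",
    )
    return {
        "images": image_paths,
        "scores": str(scores_path),
        "ground_truth": str(truth_path),
        "mask": str(mask_path),
    }
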