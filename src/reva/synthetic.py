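"""Synthetic inputs for the asymmetry pipeline.

Three generators, all deterministic under (parameters, seed):

* stylized retinal-fundus images — a dark branching vessel tree grown by
  recursive bifurcation from an "optic disc", on a bright noisy background;
* aligned left/right image pairs whose structural parameters (branch angles,
  lengths, widths, contrast) differ by zero-mean perturbations of a
  controllable scale, so injected asymmetry has a known magnitude;
* a cohort table of bilateral trait measurements (ophthalmic, ankle-brachial
  pressure, audiometry), runs-of-homozygosity summaries and censored survival
  times, all driven by one latent per-subject asymmetry propensity so that
  cross-trait clustering of asymmetry has a tunable ground truth.

The vessel model is a stylized tree, not a physiological one: its purpose is
to give images nontrivial component and loop structure, not to reproduce
real vasculature geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .persistence import GreyscaleImage

__all__ = [
    "VesselParams",
    "SurvivalParams",
    "SyntheticConfig",
    "TRAIT_DEFINITIONS",
    "make_vessel_image",
    "make_pair",
    "simulate_cohort",
    "measurements_long",
]


@dataclass(frozen=True)
class VesselParams:
    """Geometry and intensity of the simulated vessel tree.

    Intensities are on [0, 1]; the tree and disc are darker than the
    background so they enter the sublevel filtration first.
    """

    depth: int = 5              # bifurcation generations per root branch
    n_roots: int = 4            # branches leaving the optic disc
    root_length_frac: float = 0.30  # root segment length / min(image side)
    length_decay: float = 0.72  # child length / parent length
    branch_angle: float = 0.55  # mean half-angle between children (radians)
    width0: float = 2.6         # root vessel half-width in pixels
    width_decay: float = 0.78
    contrast: float = 0.55      # background minus trunk intensity
    contrast_decay: float = 0.88  # per-generation fading of vessel darkness
    background: float = 0.90
    noise_sd: float = 0.03
    disc_radius_frac: float = 0.09  # optic-disc radius / min(image side)


@dataclass(frozen=True)
class SurvivalParams:
    """Proportional-hazards generator: exponential baseline, log-linear covariates."""

    baseline_hazard: float = 0.012          # events per person-year at covariate reference
    log_hr_age: float = float(np.log(1.10))  # per year of age (centred)
    log_hr_female: float = -0.40
    log_hr_comorbidity: float = 0.20        # per diagnosis, 0-5
    censoring_fraction: float = 0.60        # target fraction censored


#: trait -> (group, population mean, between-subject sd, within-pair noise sd,
#: propensity effect size).  The signed left-right difference of a trait is
#: drawn with standard deviation (effect * u * trait_effect_scale + noise),
#: u being the subject's latent asymmetry propensity.
TRAIT_DEFINITIONS: dict[str, tuple[str, float, float, float, float]] = {
    # nine ophthalmic measurements (keratometry/autorefraction/biometry)
    "spheric_power": ("ophthalmic", -0.50, 1.80, 0.30, 0.25),
    "cylinder_power": ("ophthalmic", -0.75, 0.60, 0.20, 0.15),
    "angle": ("ophthalmic", 90.0, 40.0, 15.0, 9.0),
    "corneal_radius": ("ophthalmic", 7.80, 0.25, 0.05, 0.04),
    "corneal_thickness": ("ophthalmic", 545.0, 30.0, 8.0, 6.0),
    "anterior_chamber_depth": ("ophthalmic", 3.10, 0.35, 0.07, 0.05),
    "lens_thickness": ("ophthalmic", 4.20, 0.40, 0.06, 0.05),
    "posterior_chamber_length": ("ophthalmic", 15.60, 0.90, 0.22, 0.15),
    "axial_length": ("ophthalmic", 23.40, 1.00, 0.15, 0.10),
    # three bilateral Doppler systolic pressures (ABPI family)
    "brachial_systolic": ("abpi", 135.0, 15.0, 5.0, 3.5),
    "posterior_tibial_systolic": ("abpi", 140.0, 16.0, 6.0, 4.0),
    "dorsalis_pedis_systolic": ("abpi", 138.0, 16.0, 6.0, 4.0),
    # eight pure-tone audiometry thresholds (dB HL)
    "hearing_0.25khz": ("audiometry", 14.0, 8.0, 4.0, 2.5),
    "hearing_0.5khz": ("audiometry", 13.0, 8.0, 4.0, 2.5),
    "hearing_1khz": ("audiometry", 13.0, 9.0, 4.0, 2.5),
    "hearing_2khz": ("audiometry", 15.0, 10.0, 4.5, 3.0),
    "hearing_3khz": ("audiometry", 18.0, 12.0, 5.0, 3.0),
    "hearing_4khz": ("audiometry", 22.0, 14.0, 5.0, 3.5),
    "hearing_6khz": ("audiometry", 27.0, 15.0, 6.0, 4.0),
    "hearing_8khz": ("audiometry", 32.0, 17.0, 6.0, 4.5),
}

#: sub-cohort label -> recruitment weight (two island populations and one
#: mainland city, proportions as in the study population of 1873)
COHORT_WEIGHTS = {"Vis": 617, "Korcula": 470, "Split": 786}


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level generator settings.

    ``trait_effect_scale`` multiplies every trait's propensity effect; 0 gives
    the null regime where asymmetries are independent across body parts.
    ``roh_correlation`` is the target Pearson correlation between the latent
    propensity and the ROH segment count, hit by closed-form calibration.
    """

    n_subjects: int = 1873
    image_size: tuple[int, int] = (64, 64)
    asymmetry_level: float = 0.3
    vessel: VesselParams = field(default_factory=VesselParams)
    trait_effect_scale: float = 1.0
    propensity_sigma: float = 0.5
    roh_correlation: float = 0.229
    roh_mean_count: float = 30.0
    roh_mean_segment_kb: float = 3000.0
    unilateral_loss_fraction: float = 0.03
    female_fraction: float = 0.58
    age_mean: float = 53.2
    age_sd: float = 14.5
    comorbidity_p: float = 0.18
    survival: SurvivalParams = field(default_factory=SurvivalParams)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.asymmetry_level < 0:
            raise ValueError("asymmetry_level must be >= 0")
        if not -1.0 < self.roh_correlation < 1.0:
            raise ValueError("roh_correlation must lie in (-1, 1)")
        if not 0.0 <= self.survival.censoring_fraction < 1.0:
            raise ValueError("censoring_fraction must lie in [0, 1)")


# --------------------------------------------------------------------------
# vessel images

def _tree_parameters(params: VesselParams, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Random structural parameters of the full tree, drawn in a fixed order.

    The tree topology is a complete binary tree per root, so the parameter
    vectors have a fixed length given (n_roots, depth); this makes paired
    perturbation (same draw order, shifted values) possible.
    """
    n_nodes = params.n_roots * max(2**params.depth - 1, 0)
    return {
        "root_angles": rng.uniform(0.0, 2 * np.pi, params.n_roots),
        "angle_jitter": rng.normal(0.0, 0.12, n_nodes),
        "branch_angles": rng.normal(params.branch_angle, 0.10, n_nodes),
        "length_factors": rng.uniform(0.85, 1.15, n_nodes),
        "contrast_factor": rng.uniform(0.9, 1.1, 1),
    }


def _perturb_parameters(
    tree: dict[str, np.ndarray], scale: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Zero-mean perturbation of the structural parameters at the given scale."""
    out = {
        "root_angles": tree["root_angles"] + scale * rng.normal(0.0, 0.20, tree["root_angles"].shape),
        "angle_jitter": tree["angle_jitter"] + scale * rng.normal(0.0, 0.15, tree["angle_jitter"].shape),
        "branch_angles": tree["branch_angles"] + scale * rng.normal(0.0, 0.12, tree["branch_angles"].shape),
        "length_factors": tree["length_factors"] * np.exp(scale * rng.normal(0.0, 0.12, tree["length_factors"].shape)),
        "contrast_factor": tree["contrast_factor"] * np.exp(scale * rng.normal(0.0, 0.10, 1)),
    }
    return out


def _stamp_disc(img: np.ndarray, cy: float, cx: float, radius: float, value: float) -> None:
    from skimage.draw import disk

    rr, cc = disk((cy, cx), radius, shape=img.shape)
    img[rr, cc] = np.minimum(img[rr, cc], value)


def _stamp_segment(
    img: np.ndarray, y0: float, x0: float, y1: float, x1: float, half_width: float, value: float
) -> None:
    """Darken a thick segment by stamping small discs along it (min-composited)."""
    from skimage.draw import disk

    length = float(np.hypot(y1 - y0, x1 - x0))
    n = max(2, int(np.ceil(length / 0.5)))
    for t in np.linspace(0.0, 1.0, n):
        rr, cc = disk((y0 + t * (y1 - y0), x0 + t * (x1 - x0)), max(half_width, 0.8), shape=img.shape)
        img[rr, cc] = np.minimum(img[rr, cc], value)


def _render(size: tuple[int, int], params: VesselParams, tree: dict[str, np.ndarray],
            noise: np.ndarray) -> np.ndarray:
    n, m = size
    img = np.full((n, m), params.background, dtype=float)
    short = min(n, m)
    cy, cx = n / 2.0, m * 0.28  # optic disc sits nasally, off-centre
    disc_r = params.disc_radius_frac * short
    contrast = params.contrast * float(tree["contrast_factor"][0])
    _stamp_disc(img, cy, cx, disc_r, params.background - 1.15 * contrast)

    node = 0
    for r in range(params.n_roots):
        if params.depth < 1:  # base case: disc only
            continue
        # each root spawns a complete binary tree of `depth` generations, walked depth-first
        stack = [(cy, cx, float(tree["root_angles"][r]), params.root_length_frac * short,
                  params.width0, contrast, 1)]
        while stack:
            y, x, ang, length, width, ctr, level = stack.pop()
            ang = ang + float(tree["angle_jitter"][node])
            length = length * float(tree["length_factors"][node])
            y1 = y + length * np.sin(ang)
            x1 = x + length * np.cos(ang)
            _stamp_segment(img, y, x, y1, x1, width, params.background - ctr)
            half = float(tree["branch_angles"][node])
            node += 1
            if level < params.depth:
                child_len = length * params.length_decay
                child_w = width * params.width_decay
                child_c = ctr * params.contrast_decay
                stack.append((y1, x1, ang - half, child_len, child_w, child_c, level + 1))
                stack.append((y1, x1, ang + half, child_len, child_w, child_c, level + 1))
    img += noise
    return np.clip(img, 0.0, 1.0)


def make_vessel_image(
    size: tuple[int, int] = (128, 128),
    params: VesselParams = VesselParams(),
    seed: int | np.random.Generator = 0,
) -> GreyscaleImage:
    """One synthetic fundus-style image: dark vessel tree on a bright noisy field.

    Deterministic given (size, params, seed).  ``depth=0`` draws the disc and
    the unbranched root segments only; ``n_roots=0`` warns and returns a
    background-only image.
    """
    if size[0] < 32 or size[1] < 32:
        raise ValueError("image size must be at least 32x32 for nontrivial topology")
    rng = np.random.default_rng(seed)
    if params.n_roots == 0:
        warnings.warn("n_roots=0: generating background-only image", stacklevel=2)
        noise = rng.normal(0.0, params.noise_sd, size)
        return GreyscaleImage(np.clip(params.background + noise, 0.0, 1.0))
    tree = _tree_parameters(params, rng)
    noise = rng.normal(0.0, params.noise_sd, size)
    return GreyscaleImage(_render(size, params, tree, noise))


def make_pair(
    size: tuple[int, int] = (128, 128),
    params: VesselParams = VesselParams(),
    asymmetry_level: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[GreyscaleImage, GreyscaleImage]:
    """Aligned left/right image pair with controllable structural asymmetry.

    The right image reuses the left's structural draw with branch angles,
    segment lengths, widths and contrast shifted by zero-mean noise of scale
    ``asymmetry_level``; the pixel noise field is shared, so level 0 yields
    byte-identical fields.
    """
    if asymmetry_level < 0:
        raise ValueError("asymmetry_level must be >= 0")
    if isinstance(seed, np.random.Generator):  # split the stream deterministically
        rng_tree = seed
        rng_noise = np.random.default_rng(rng_tree.integers(2**31))
        rng_pert = np.random.default_rng(rng_tree.integers(2**31))
    else:
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        rng_tree, rng_noise, rng_pert = (np.random.default_rng(s) for s in ss.spawn(3))
    tree_left = _tree_parameters(params, rng_tree)
    noise = rng_noise.normal(0.0, params.noise_sd, size)
    tree_right = (
        tree_left if asymmetry_level == 0
        else _perturb_parameters(tree_left, asymmetry_level, rng_pert)
    )
    left = GreyscaleImage(_render(size, params, tree_left, noise))
    right = GreyscaleImage(_render(size, params, tree_right, noise))
    return left, right


# --------------------------------------------------------------------------
# cohort table

def _roh_rate_coefficient(target_r: float, lambda0: float, sigma_u: float) -> float:
    """Solve for beta so that corr(u, Poisson count) hits the target.

    With u = exp(sigma_u * s), s ~ N(0,1), and count ~ Poisson(lambda0 *
    exp(beta*s - beta^2/2)) the Pearson correlation has the closed form

        rho(beta) = lambda0 * E[u] * (exp(sigma_u*beta) - 1)
                    / ( sd(u) * sqrt(lambda0 + lambda0^2 * (exp(beta^2) - 1)) ).
    """
    if target_r == 0.0:
        return 0.0
    mean_u = np.exp(sigma_u**2 / 2)
    sd_u = mean_u * np.sqrt(np.expm1(sigma_u**2))

    def rho(beta: float) -> float:
        num = lambda0 * mean_u * np.expm1(sigma_u * beta)
        den = sd_u * np.sqrt(lambda0 + lambda0**2 * np.expm1(beta**2))
        return num / den

    # rho is 0 at beta=0, rises, then decays as the Poisson variance inflates;
    # solve on the rising branch (the smallest-|beta| solution)
    sign = 1.0 if target_r > 0 else -1.0
    grid = sign * np.linspace(1e-6, 5.0, 2001)
    rho_grid = np.array([rho(b) for b in grid])
    peak = int(np.argmax(sign * rho_grid))
    if sign * target_r > sign * rho_grid[peak]:
        raise ValueError(
            f"roh_correlation {target_r} is outside the attainable range "
            f"(max |rho| ~ {abs(rho_grid[peak]):.3f} for these Poisson settings)"
        )
    return float(brentq(lambda b: rho(b) - target_r, sign * 1e-12, grid[peak], xtol=1e-12))


def simulate_cohort(config: SyntheticConfig = SyntheticConfig(), seed: int = 0) -> pd.DataFrame:
    """Per-subject cohort table: demographics, bilateral traits, ROH, survival.

    One latent lognormal propensity ``u`` per subject scales the left-right
    difference of every trait (through the per-trait effect sizes and
    ``trait_effect_scale``) and the ROH segment-count rate (calibrated to the
    target correlation).  Survival times follow an exponential
    proportional-hazards model in age, sex and comorbidity count, with
    independent exponential censoring tuned to the configured fraction.
    """
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    sp = config.survival

    s = rng.normal(0.0, 1.0, n)  # standardized log-propensity
    u = np.exp(config.propensity_sigma * s)

    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 95.0)
    labels = list(COHORT_WEIGHTS)
    probs = np.array(list(COHORT_WEIGHTS.values()), dtype=float)
    cohort = rng.choice(labels, size=n, p=probs / probs.sum())
    comorbidity = rng.binomial(5, config.comorbidity_p, n)
    comorbidity_group = np.select(
        [comorbidity == 0, comorbidity == 1], ["none", "one"], default="multiple"
    )
    unilateral_loss = rng.random(n) < config.unilateral_loss_fraction

    data: dict[str, np.ndarray] = {
        "subject_id": np.array([f"S{k:05d}" for k in range(n)]),
        "sex": sex,
        "age": age,
        "cohort": cohort,
        "comorbidity_count": comorbidity,
        "comorbidity_group": comorbidity_group,
        "unilateral_hearing_loss": unilateral_loss,
        "propensity": u,
        "image_asymmetry": config.asymmetry_level * u,
    }

    for trait, (_, mean, between_sd, noise_sd, effect) in TRAIT_DEFINITIONS.items():
        base = mean + rng.normal(0.0, between_sd, n)
        diff_sd = effect * config.trait_effect_scale * u + noise_sd
        diff = diff_sd * rng.normal(0.0, 1.0, n)
        data[f"{trait}_left"] = base + diff / 2.0
        data[f"{trait}_right"] = base - diff / 2.0

    beta = _roh_rate_coefficient(config.roh_correlation, config.roh_mean_count,
                                 config.propensity_sigma)
    rate = config.roh_mean_count * np.exp(beta * s - beta**2 / 2.0)
    roh_count = rng.poisson(rate)
    # per-segment lengths ~ Gamma(shape 2); the total over k segments is Gamma(2k)
    shape = 2.0 * roh_count
    scale = config.roh_mean_segment_kb / 2.0
    roh_total = np.where(roh_count > 0, rng.gamma(np.maximum(shape, 1e-12), scale), 0.0)
    data["roh_count"] = roh_count
    data["roh_total_kb"] = roh_total
    data["roh_mean_kb"] = np.where(roh_count > 0, roh_total / np.maximum(roh_count, 1), 0.0)

    hazard = sp.baseline_hazard * np.exp(
        sp.log_hr_age * (age - config.age_mean)
        + sp.log_hr_female * (sex == "female")
        + sp.log_hr_comorbidity * comorbidity
    )
    event_time = rng.exponential(1.0 / hazard)
    if sp.censoring_fraction > 0:
        target_events = 1.0 - sp.censoring_fraction

        def event_frac(log_hc: float) -> float:
            hc = np.exp(log_hc)
            return float(np.mean(hazard / (hazard + hc))) - target_events

        log_hc = brentq(event_frac, np.log(hazard.min()) - 20, np.log(hazard.max()) + 20)
        censor_time = rng.exponential(np.exp(-log_hc), n)
    else:
        censor_time = np.full(n, np.inf)
    data["time_years"] = np.maximum(np.minimum(event_time, censor_time), 1e-6)
    data["event"] = (event_time <= censor_time).astype(int)

    return pd.DataFrame(data)


def measurements_long(cohort: pd.DataFrame) -> pd.DataFrame:
    """Melt the wide cohort table into one row per (subject, bilateral trait).

    Columns: subject_id, trait, group, left, right.  Audiometry rows of
    subjects flagged for unilateral hearing loss are set to missing, mirroring
    their exclusion from hearing-asymmetry analysis.
    """
    rows = []
    for trait, (group, *_rest) in TRAIT_DEFINITIONS.items():
        sub = pd.DataFrame(
            {
                "subject_id": cohort["subject_id"],
                "trait": trait,
                "group": group,
                "left": cohort[f"{trait}_left"],
                "right": cohort[f"{trait}_right"],
            }
        )
        if group == "audiometry" and "unilateral_hearing_loss" in cohort:
            excluded = cohort["unilateral_hearing_loss"].to_numpy(dtype=bool)
            sub.loc[excluded, ["left", "right"]] = np.nan
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)
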