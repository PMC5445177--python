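"""Synthetic MWF volumes, FLAIR-like intensities, and patient cohorts.

Every downstream stage is testable without real MRI data.  The generators
emulate the statistical structure the analysis assumes:

* per-voxel MWF values in white matter follow a two-component gamma
  mixture — spatially clustered spherical lesions carry the low-MWF
  component, a thin "dirty WM" rim around each lesion carries the low
  component's upper tail, and the remaining (normal-appearing) WM carries
  the high-MWF component, so the pooled WM histogram matches the
  ground-truth mixture;

* FLAIR-like intensity volumes give lesions a hyperintense offset over WM
  and include a synthetic CSF shell, providing input for the
  percentile-threshold lesion-mask rule;

* cohort tables draw per-subject predictors (mixture parameters, mask-mean
  surrogates, demographics) from configurable distributions and generate
  cortical thickness from a linear model with Gaussian noise.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .masks import LabeledVolume
from .mixture import GammaComponent, GammaMixtureModel

__all__ = [
    "CompartmentFractions",
    "VolumeSpec",
    "CohortSpec",
    "compartments_to_mwf",
    "sample_gamma_mixture",
    "make_mwf_volume",
    "make_flair_like",
    "make_cohort",
    "default_wm_mixture",
    "rrms_cohort_spec",
    "spms_cohort_spec",
    "expected_lesion_volume",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = ["subject_id", "group", "m1", "m2", "lambda", "mean_lesion_mwf",
                  "mean_nawm_mwf", "age", "gender", "dd", "dmt", "cortical_thickness"]


# --------------------------------------------------------------------------
# water compartments
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CompartmentFractions:
    """Per-voxel signal fractions of the three water compartments.

    ``c_mw`` myelin water, ``c_cw`` intra/extra-cellular water, ``c_csf``
    cerebrospinal fluid; all nonnegative, with a positive sum for a valid
    voxel.
    """

    c_mw: float
    c_cw: float
    c_csf: float

    def __post_init__(self) -> None:
        for name in ("c_mw", "c_cw", "c_csf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def compartments_to_mwf(fractions: CompartmentFractions) -> float:
    """MWF: myelin-water signal over total water signal, a ratio in [0, 1]."""
    total = fractions.c_mw + fractions.c_cw + fractions.c_csf
    if total <= 0:
        raise ValueError("invalid voxel: all compartment fractions are zero")
    return fractions.c_mw / total


# --------------------------------------------------------------------------
# ground-truth mixture and sampling
# --------------------------------------------------------------------------


def default_wm_mixture(lam: float = 0.25, m1: float = 0.06, m2: float = 0.17,
                       shape1: float = 2.0, shape2: float = 5.0) -> GammaMixtureModel:
    """Reference two-component WM mixture, parameterized by its modes.

    Scales follow from ``mode = (shape - 1) * scale``.  Defaults place the
    low-MWF (lesion/dirty WM) peak at 0.06 and the high-MWF (NAWM) peak at
    0.17 with a 0.25 mixing ratio — a typical relapsing-stage configuration.
    """
    if not (shape1 > 1 and shape2 > 1):
        raise ValueError("mode parameterization requires shapes > 1")
    return GammaMixtureModel(lam,
                             GammaComponent(shape1, m1 / (shape1 - 1.0)),
                             GammaComponent(shape2, m2 / (shape2 - 1.0)))


def sample_gamma_mixture(model: GammaMixtureModel, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` values: component 1 with probability ``lam``, else component 2."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return model.rvs(n, rng)


# --------------------------------------------------------------------------
# volume generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VolumeSpec:
    """Recipe for one synthetic subject volume.

    The WM mask is an axis-aligned ellipsoid filling ``wm_fraction`` of the
    grid; lesions are non-overlapping spheres (radii uniform in
    ``lesion_radius_range``) centered inside the eroded WM mask, each
    surrounded by a dirty-WM rim of ``dirty_rim_width`` voxels.  Defaults
    give a 64x64x32 grid with ~59,000 WM voxels — desk scale, yet enough for
    a stable EM fit — and a lesion-plus-rim load matching the mixture's
    default mixing ratio so the pooled WM histogram reproduces the mixture.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 32)
    wm_fraction: float = 0.45
    n_lesions: int = 20
    lesion_radius_range: tuple[float, float] = (3.0, 5.0)
    dirty_rim_width: float = 1.5
    mixture: GammaMixtureModel = field(default_factory=default_wm_mixture)
    dirty_overlap: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if not (0 < self.wm_fraction <= np.pi / 6):
            raise ValueError("wm_fraction must lie in (0, pi/6]; the WM ellipsoid "
                             "cannot exceed the inscribed-ellipsoid fraction pi/6")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be nonnegative")
        lo, hi = self.lesion_radius_range
        if not (1.0 <= lo <= hi):
            raise ValueError("lesion radii must be at least 1 voxel and ordered")
        if not (0.0 <= self.dirty_overlap <= 1.0):
            raise ValueError("dirty_overlap must lie in [0, 1]")
        if self.dirty_rim_width < 0:
            raise ValueError("dirty_rim_width must be nonnegative")

    def to_dict(self) -> dict:
        m = self.mixture
        return {
            "grid_shape": list(self.grid_shape),
            "wm_fraction": self.wm_fraction,
            "n_lesions": self.n_lesions,
            "lesion_radius_range": list(self.lesion_radius_range),
            "dirty_rim_width": self.dirty_rim_width,
            "mixture": {"lam": m.lam,
                        "comp1": {"shape": m.comp1.shape, "scale": m.comp1.scale},
                        "comp2": {"shape": m.comp2.shape, "scale": m.comp2.scale}},
            "dirty_overlap": self.dirty_overlap,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VolumeSpec":
        d = dict(d)
        if "mixture" in d and isinstance(d["mixture"], dict):
            m = d["mixture"]
            d["mixture"] = GammaMixtureModel(
                m["lam"],
                GammaComponent(m["comp1"]["shape"], m["comp1"]["scale"]),
                GammaComponent(m["comp2"]["shape"], m["comp2"]["scale"]))
        for key in ("grid_shape", "lesion_radius_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def expected_lesion_volume(spec: VolumeSpec) -> float:
    """Expected voxel volume of one lesion plus its dirty rim.

    For radius ``r ~ U(lo, hi)`` and rim width ``w`` this is
    ``(4/3) pi E[(r + w)^3]``, used to size lesion counts so the low-MWF
    (lesion + rim) share of WM approximates a target mixing ratio.
    """
    lo, hi = spec.lesion_radius_range
    a, b = lo + spec.dirty_rim_width, hi + spec.dirty_rim_width
    e3 = (b ** 4 - a ** 4) / (4.0 * (b - a)) if b > a else a ** 3
    return 4.0 / 3.0 * np.pi * e3


def _ellipsoid_mask(shape, semi_axes) -> np.ndarray:
    center = [(s - 1) / 2.0 for s in shape]
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum(((g - c) / ax) ** 2 for g, c, ax in zip(grids, center, semi_axes))
    return dist2 <= 1.0


def _wm_semi_axes(spec: VolumeSpec) -> np.ndarray:
    # inscribed ellipsoid fills pi/6 of the grid; shrink axes isotropically
    s = (spec.wm_fraction * 6.0 / np.pi) ** (1.0 / 3.0)
    return s * np.asarray(spec.grid_shape, dtype=float) / 2.0


def _place_lesions(spec: VolumeSpec, semi_axes, rng,
                   max_attempts: int = 2000) -> list[tuple[np.ndarray, float]]:
    """Sphere centers inside the eroded WM ellipsoid, pairwise non-overlapping.

    Largest lesions are placed first.  A candidate center is accepted when
    the sphere (including its rim) fits inside the WM ellipsoid eroded by
    its effective radius and keeps at least touching distance from every
    accepted sphere.  Exhausting the attempt budget is an error: the
    requested lesion load does not fit in the WM mask.
    """
    lo, hi = spec.lesion_radius_range
    radii = np.sort(rng.uniform(lo, hi, size=spec.n_lesions))[::-1]
    center = np.array([(s - 1) / 2.0 for s in spec.grid_shape])
    placed: list[tuple[np.ndarray, float]] = []
    for r in radii:
        r_eff = r + spec.dirty_rim_width
        eroded = semi_axes - r_eff
        if (eroded <= 1.0).any():
            raise RuntimeError(f"lesion of radius {r:.2f} (plus rim) cannot fit inside "
                               "the WM ellipsoid")
        for _ in range(max_attempts):
            cand = center + (2.0 * rng.random(3) - 1.0) * eroded
            if np.sum(((cand - center) / eroded) ** 2) > 1.0:
                continue
            ok = all(np.linalg.norm(cand - c0) >= r_eff + r0 + spec.dirty_rim_width
                     for c0, r0 in placed)
            if ok:
                placed.append((cand, float(r)))
                break
        else:
            raise RuntimeError(f"could not place lesion of radius {r:.2f} after "
                               f"{max_attempts} attempts; reduce n_lesions or radii")
    return placed


def make_mwf_volume(spec: VolumeSpec) -> LabeledVolume:
    """Generate one labeled MWF volume from a :class:`VolumeSpec`.

    Ground-truth labels are returned: the lesion mask is the union of the
    placed spheres; NAWM is its complement within WM (the dirty rim, being
    normal-appearing by construction, belongs to NAWM).  Lesion and rim
    voxels together carry one iid sample from the low-MWF component — with
    the rim receiving values from the sample's upper portion, the extent
    controlled by ``dirty_overlap`` — and the remaining WM carries the
    high-MWF component, so the pooled WM histogram is exactly the
    generating mixture (``spec.mixture``).  All values are clipped to
    [0, 1] since MWF is a signal fraction.
    """
    rng = np.random.default_rng(spec.seed)
    semi_axes = _wm_semi_axes(spec)
    wm = _ellipsoid_mask(spec.grid_shape, semi_axes)

    lesion = np.zeros(spec.grid_shape, dtype=bool)
    rim = np.zeros(spec.grid_shape, dtype=bool)
    if spec.n_lesions > 0:
        grids = np.ogrid[tuple(slice(0, s) for s in spec.grid_shape)]
        for cand, r in _place_lesions(spec, semi_axes, rng):
            dist2 = sum((g - c) ** 2 for g, c in zip(grids, cand))
            lesion |= dist2 <= r ** 2
            rim |= dist2 <= (r + spec.dirty_rim_width) ** 2
        rim &= ~lesion
        rim &= wm
        lesion &= wm  # spheres fit inside WM by construction; guard discretization

    mix = spec.mixture.ordered()
    low, high = mix.comp1, mix.comp2
    values = np.zeros(spec.grid_shape, dtype=float)
    n_les = int(lesion.sum())
    n_rim = int(rim.sum())
    n_low = n_les + n_rim
    if n_low:
        # one iid low-component sample for lesion + rim, so the pooled WM
        # histogram is exactly spec.mixture; the rim receives values from
        # the sample's upper portion (dirty_overlap=1: strictly the top order
        # statistics; dirty_overlap=0: a random subset, no rim/lesion contrast)
        low_vals = np.sort(low.rvs(n_low, rng))
        pool_size = n_rim + round((1.0 - spec.dirty_overlap) * (n_low - n_rim))
        pool_idx = np.arange(n_low - pool_size, n_low)
        rim_idx = rng.choice(pool_idx, size=n_rim, replace=False)
        values[rim] = low_vals[rim_idx]
        lesion_idx = np.setdiff1d(np.arange(n_low), rim_idx)
        values[lesion] = rng.permutation(low_vals[lesion_idx])
    rest = wm & ~lesion & ~rim
    values[rest] = high.rvs(int(rest.sum()), rng)
    np.clip(values, 0.0, 1.0, out=values)

    return LabeledVolume(values=values, wm=wm, lesion=lesion, nawm=wm & ~lesion)


def make_flair_like(volume: LabeledVolume, lesion_gain: float = 20.0,
                    noise_sd: float = 5.0, seed=None,
                    wm_intensity: float = 100.0, csf_intensity: float = 30.0
                    ) -> tuple[LabeledVolume, np.ndarray]:
    """FLAIR-like intensity volume plus a CSF+lesion ("class 3") map.

    Intensities: WM at ``wm_intensity``, lesions raised by ``lesion_gain``,
    a synthetic CSF shell (two-voxel dilation of WM) at ``csf_intensity``,
    Gaussian noise of ``noise_sd`` on all brain voxels, background zero.

    The class-3 map emulates an intensity-driven three-class segmentation
    whose third class mixes CSF and WM lesions: it is the CSF shell united
    with robust hyperintensity outliers (brain voxels brighter than the WM
    median plus twice the MAD-based sigma).  When ``lesion_gain`` is well
    above the noise this covers essentially every lesion voxel; with no
    gain it contains only noise voxels, so downstream recovery is at chance.
    """
    if volume.lesion is None:
        raise ValueError("volume must carry WM and lesion labels")
    rng = np.random.default_rng(seed)
    shell = ndimage.binary_dilation(volume.wm, iterations=2) & ~volume.wm
    brain = volume.wm | shell

    intensity = np.zeros(volume.shape, dtype=float)
    intensity[volume.wm] = wm_intensity
    intensity[volume.lesion] += lesion_gain
    intensity[shell] = csf_intensity
    if noise_sd > 0:
        intensity[brain] += rng.normal(0.0, noise_sd, size=int(brain.sum()))

    wm_vals = intensity[volume.wm]
    med = float(np.median(wm_vals))
    sigma = 1.4826 * float(np.median(np.abs(wm_vals - med)))
    hyper = brain & (intensity > med + 2.0 * sigma)
    class3 = shell | hyper

    out = LabeledVolume(values=intensity, wm=volume.wm, lesion=volume.lesion,
                        nawm=volume.nawm, affine=volume.affine)
    return out, class3


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic patient cohort.

    ``predictor_distributions`` maps a column name to a sampling rule:

    * ``("normal", mean, sd)``
    * ``("truncnormal", mean, sd, lower, upper)``
    * ``("uniform", lower, upper)``
    * ``("bernoulli", p)`` — 0/1 indicator (e.g. gender)
    * ``("surrogate", base_column, factor, sd)`` — noisy linear surrogate of
      an already-sampled column (e.g. mask-mean MWF derived from a mode)

    Cortical thickness is ``intercept + sum(coef * column) + N(0, noise_sd)``
    with coefficients from ``true_coefficients`` (key ``"intercept"``
    required; every other key must name a predictor column).
    """

    n_subjects: int
    group_label: str
    true_coefficients: dict
    noise_sd: float
    predictor_distributions: dict
    seed: int = 0

    def __post_init__(self) -> None:
        n_pred = sum(1 for k in self.true_coefficients if k != "intercept")
        if self.n_subjects < 2 + n_pred:
            raise ValueError(f"n_subjects must be at least {2 + n_pred} "
                             "(2 + number of predictors)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def to_dict(self) -> dict:
        return {"n_subjects": self.n_subjects, "group_label": self.group_label,
                "true_coefficients": dict(self.true_coefficients),
                "noise_sd": self.noise_sd,
                "predictor_distributions": {k: list(v) for k, v in
                                            self.predictor_distributions.items()},
                "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["predictor_distributions"] = {k: tuple(v) for k, v in
                                        d["predictor_distributions"].items()}
        return cls(**d)


def _sample_distribution(rule, n: int, rng, sampled: dict[str, np.ndarray]) -> np.ndarray:
    kind = rule[0]
    if kind == "normal":
        _, mean, sd = rule
        return rng.normal(mean, sd, size=n)
    if kind == "truncnormal":
        _, mean, sd, lo, hi = rule
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    if kind == "uniform":
        _, lo, hi = rule
        return rng.uniform(lo, hi, size=n)
    if kind == "bernoulli":
        _, p = rule
        return (rng.random(n) < p).astype(float)
    if kind == "surrogate":
        _, base, factor, sd = rule
        if base not in sampled:
            raise ValueError(f"surrogate base column {base!r} has not been sampled yet")
        return factor * sampled[base] + rng.normal(0.0, sd, size=n)
    raise ValueError(f"unknown distribution kind {kind!r}")


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample one cohort table from a :class:`CohortSpec`.

    Base predictors are sampled first (in insertion order), then surrogate
    columns, then the response.  Unknown predictor names in
    ``true_coefficients`` are an error.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    sampled: dict[str, np.ndarray] = {}
    deferred = {k: v for k, v in spec.predictor_distributions.items() if v[0] == "surrogate"}
    for name, rule in spec.predictor_distributions.items():
        if rule[0] != "surrogate":
            sampled[name] = _sample_distribution(rule, n, rng, sampled)
    for name, rule in deferred.items():
        sampled[name] = _sample_distribution(rule, n, rng, sampled)

    unknown = [k for k in spec.true_coefficients if k != "intercept" and k not in sampled]
    if unknown:
        raise ValueError(f"true_coefficients name unsampled predictors: {unknown}")
    if "intercept" not in spec.true_coefficients:
        raise ValueError("true_coefficients must include an 'intercept' entry")

    thickness = np.full(n, float(spec.true_coefficients["intercept"]))
    for name, coef in spec.true_coefficients.items():
        if name != "intercept":
            thickness = thickness + coef * sampled[name]
    if spec.noise_sd > 0:
        thickness = thickness + rng.normal(0.0, spec.noise_sd, size=n)

    table = {"subject_id": [f"{spec.group_label}-{i:03d}" for i in range(n)],
             "group": [spec.group_label] * n}
    table.update(sampled)
    table["cortical_thickness"] = thickness
    frame = pd.DataFrame(table)
    ordered = [c for c in COHORT_COLUMNS if c in frame.columns]
    extra = [c for c in frame.columns if c not in ordered]
    return frame[ordered + extra]


def rrms_cohort_spec(n_subjects: int = 134, seed: int = 0, noise_sd: float = 0.11,
                     **overrides) -> CohortSpec:
    """Relapsing-remitting-like cohort defaults.

    Demographics match the relapsing-stage group of a large MS clinic
    cohort (age 40.3 +- 9.7 y, disease duration 7.7 +- 7.3 y, treatment
    duration 4.2 +- 4.1 y, 67% female, cortical thickness around
    2.46 mm); cortical thickness is generated from the low mode, the
    mixing ratio, and age with coefficients 1.56 (per MWF), -0.30 (per
    mixing-ratio unit) and -0.0031 mm/year.  Mask-mean columns are noisy
    linear surrogates of the modes, mirroring how a lesion mask's mean MWF
    tracks the low-mode component (a gamma with shape 2 and mode m has mean
    2 m; shape 5 and mode m has mean 1.25 m).
    """
    spec = CohortSpec(
        n_subjects=n_subjects,
        group_label="RRMS",
        true_coefficients={"intercept": 2.5663, "m1": 1.56, "lambda": -0.30,
                           "age": -0.0031},
        noise_sd=noise_sd,
        predictor_distributions={
            "m1": ("truncnormal", 0.06, 0.010, 0.02, 0.12),
            "m2": ("truncnormal", 0.17, 0.015, 0.125, 0.24),
            "lambda": ("truncnormal", 0.25, 0.08, 0.02, 0.60),
            "age": ("truncnormal", 40.3, 9.7, 18.0, 75.0),
            "gender": ("bernoulli", 90.0 / 134.0),
            "dd": ("truncnormal", 7.7, 7.3, 0.0, 40.0),
            "dmt": ("truncnormal", 4.2, 4.1, 0.0, 30.0),
            "mean_lesion_mwf": ("surrogate", "m1", 2.0, 0.012),
            "mean_nawm_mwf": ("surrogate", "m2", 1.25, 0.012),
        },
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def spms_cohort_spec(n_subjects: int = 23, seed: int = 0, noise_sd: float = 0.10,
                     **overrides) -> CohortSpec:
    """Secondary-progressive-like cohort defaults.

    Demographics follow the progressive-stage group (age 57.4 +- 7.8 y,
    disease duration 21.7 +- 11.0 y, treatment duration 10.6 +- 6.1 y, 70%
    female, thickness around 2.27 mm); the mixture shifts toward lower
    modes and a higher mixing ratio, and thickness depends on the high
    (NAWM) mode alone with coefficient 4.72 mm per MWF unit.
    """
    spec = CohortSpec(
        n_subjects=n_subjects,
        group_label="SPMS",
        true_coefficients={"intercept": 1.5384, "m2": 4.72},
        noise_sd=noise_sd,
        predictor_distributions={
            "m1": ("truncnormal", 0.05, 0.010, 0.015, 0.11),
            "m2": ("truncnormal", 0.155, 0.020, 0.115, 0.22),
            "lambda": ("truncnormal", 0.45, 0.12, 0.05, 0.90),
            "age": ("truncnormal", 57.4, 7.8, 30.0, 80.0),
            "gender": ("bernoulli", 16.0 / 23.0),
            "dd": ("truncnormal", 21.7, 11.0, 1.0, 50.0),
            "dmt": ("truncnormal", 10.6, 6.1, 0.0, 35.0),
            "mean_lesion_mwf": ("surrogate", "m1", 2.0, 0.012),
            "mean_nawm_mwf": ("surrogate", "m2", 1.25, 0.012),
        },
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec
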