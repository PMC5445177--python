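"""End-to-end study orchestration at desk scale.

``run_subject`` performs the per-subject reduction: fit the single gamma and
the gamma mixture to pooled WM MWF values, choose between them with the
penalized bootstrap LRT, derive (m1, m2, lambda), and — when a lesion mask
is available — compute NAWM, mask-mean MWF, the mode-derived ROIs and their
Dice overlaps.

``run_study`` assembles the full analysis: an image-level arm (simulated or
ingested volumes -> per-subject fits and group Dice comparisons) and a
cohort-level arm (subject-feature tables -> Welch group comparisons, the
two predictor-set regressions with exhaustive CV selection, and the LMG
importance of the selected gamma-mixture model).  Every stage writes its
own artifact; the manifest records seeds and any stage failures so a
partial bundle remains machine-readable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import masks as mk
from . import mixture as mx
from . import regression as rg
from . import simulate as sim

__all__ = ["RunConfig", "SubjectResult", "run_subject", "run_study"]

logger = logging.getLogger("mwfmix")

COVARIATES = ["age", "gender", "dd", "dmt"]
GAMMA_SET = ["m1", "m2", "lambda"] + COVARIATES
MASK_SET = ["mean_lesion_mwf", "mean_nawm_mwf"] + COVARIATES

# image-arm subject-level parameter ranges per group: (m1, m2, lam) truncated
# normals; the mixing ratio is capped so the implied lesion load still packs
# into the WM ellipsoid without overlap
_IMAGE_PARAM_RULES = {
    "RRMS": {"m1": (0.06, 0.010, 0.03, 0.10), "m2": (0.17, 0.015, 0.13, 0.22),
             "lam": (0.22, 0.06, 0.08, 0.30)},
    "SPMS": {"m1": (0.05, 0.010, 0.02, 0.09), "m2": (0.155, 0.018, 0.12, 0.20),
             "lam": (0.28, 0.05, 0.10, 0.32)},
}


@dataclass
class RunConfig:
    """Configuration of one study run; serialized into the manifest."""

    out_dir: str
    seed: int = 0
    mode: str = "simulate"                      # "simulate" | "ingest"
    n_image_subjects: dict = field(default_factory=lambda: {"RRMS": 10, "SPMS": 10})
    volume: dict | None = None                  # VolumeSpec overrides
    cohorts: dict | None = None                 # per-group CohortSpec overrides
    subject_dirs: list | None = None            # ingest mode: NIfTI directories
    n_bootstrap: int = 39
    alpha: float = 0.05
    cv_folds: int = 10
    max_fit_voxels: int = 20000
    save_nifti: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if self.mode == "ingest":
            if not self.subject_dirs:
                raise ValueError("ingest mode requires subject_dirs")
            missing = [d for d in self.subject_dirs if not Path(d).exists()]
            if missing:
                raise FileNotFoundError(f"subject directories not found: {missing}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


@dataclass
class SubjectResult:
    """Per-subject reduction outputs plus the fit objects themselves."""

    features: dict
    single: mx.GammaMLE | None = None
    mixture: mx.GammaMixtureEM | None = None
    selection: mx.ModelSelection | None = None
    roi_m1: np.ndarray | None = None
    roi_m2: np.ndarray | None = None


def _subsample(x: np.ndarray, max_n: int | None, rng: np.random.Generator) -> np.ndarray:
    if max_n is None or x.size <= max_n:
        return x
    return rng.choice(x, size=max_n, replace=False)


def run_subject(volume: mk.LabeledVolume, subject_id: str = "subject",
                n_bootstrap: int = 39, alpha: float = 0.05, seed=None,
                max_fit_voxels: int | None = None, out_dir=None,
                save_nifti: bool = False) -> SubjectResult:
    """Reduce one subject's MWF volume to its mixture and mask features.

    When model selection prefers the single gamma, the mixture fields are
    left null and the subject is flagged (``mixture_chosen = False``) so the
    caller can exclude it from mixture-parameter analyses.
    """
    rng = np.random.default_rng(seed)
    x_all = volume.wm_values()
    x = _subsample(x_all[x_all > 0], max_fit_voxels, rng)
    logger.info("subject %s: %d WM voxels (%d used for fitting)",
                subject_id, x_all.size, x.size)

    features: dict = {"subject_id": subject_id, "n_wm_voxels": int(volume.wm.sum()),
                      "n_fit_values": int(x.size),
                      "mean_wm_mwf": float(x_all.mean()),
                      "mixture_chosen": False, "selection_p": None,
                      "m1": None, "m2": None, "lambda": None}

    single = mx.GammaMLE().fit(x)
    mixture = selection = None
    try:
        mixture = mx.GammaMixtureEM().fit(x)
    except mx.ComponentCollapseError as err:
        logger.info("subject %s: mixture collapsed (%s); keeping single gamma",
                    subject_id, err)
    if mixture is not None:
        selection = mx.penalized_lrt(single, mixture, x, n_bootstrap=n_bootstrap,
                                     alpha=alpha, seed=rng)
        features["selection_p"] = selection.p_value
        logger.info("subject %s: EM %d iters, LRT stat %.1f, p=%.4g -> %s",
                    subject_id, mixture.n_iter_, selection.statistic,
                    selection.p_value, selection.chosen)
        if selection.chosen == "mixture":
            m1, m2, lam = mx.summarize_fit(mixture)
            features.update(mixture_chosen=True, m1=m1, m2=m2, **{"lambda": lam})
        else:
            logger.info("subject %s excluded from mixture-parameter analyses: "
                        "selection preferred the single gamma", subject_id)

    roi_m1 = roi_m2 = None
    if features["mixture_chosen"]:
        roi_m1, roi_m2 = mk.roi_from_modes(volume, features["m1"], features["m2"])
    if volume.lesion is not None:
        nawm = volume.nawm if volume.nawm is not None else mk.nawm_mask(volume)
        n_les = int(volume.lesion.sum())
        features["mean_lesion_mwf"] = (float(volume.values[volume.lesion].mean())
                                       if n_les else None)
        features["mean_nawm_mwf"] = (float(volume.values[nawm].mean())
                                     if nawm.any() else None)
        if roi_m1 is not None and n_les:
            features["dice_lesion_roi_m1"] = mk.dice(volume.lesion, roi_m1)
            features["dice_lesion_roi_m2"] = mk.dice(volume.lesion, roi_m2)
            features["dice_nawm_roi_m1"] = mk.dice(nawm, roi_m1)
            features["dice_nawm_roi_m2"] = mk.dice(nawm, roi_m2)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = {"features": features,
                   "single": {"shape": single.shape_, "scale": single.scale_,
                              "log_likelihood": single.log_likelihood_},
                   "mixture": None if mixture is None else {
                       "lam": mixture.lam_,
                       "comp1": {"shape": mixture.model_.comp1.shape,
                                 "scale": mixture.model_.comp1.scale},
                       "comp2": {"shape": mixture.model_.comp2.shape,
                                 "scale": mixture.model_.comp2.scale},
                       "log_likelihood": mixture.log_likelihood_,
                       "n_iter": mixture.n_iter_, "converged": mixture.converged_},
                   "selection": None if selection is None else {
                       "statistic": selection.statistic, "p_value": selection.p_value,
                       "chosen": selection.chosen,
                       "n_bootstrap": selection.n_bootstrap}}
        with open(out_dir / f"{subject_id}.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        if save_nifti and roi_m1 is not None:
            import nibabel as nib
            nib.save(nib.Nifti1Image(roi_m1.astype(np.uint8), volume.affine),
                     str(out_dir / f"{subject_id}_roi_m1.nii.gz"))
            nib.save(nib.Nifti1Image(roi_m2.astype(np.uint8), volume.affine),
                     str(out_dir / f"{subject_id}_roi_m2.nii.gz"))

    return SubjectResult(features=features, single=single, mixture=mixture,
                         selection=selection, roi_m1=roi_m1, roi_m2=roi_m2)


# --------------------------------------------------------------------------
# study assembly
# --------------------------------------------------------------------------


def _truncnorm(rng, mean, sd, lo, hi) -> float:
    from scipy import stats
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _simulated_image_subjects(config: RunConfig, rng: np.random.Generator):
    """Yield (group, subject_id, LabeledVolume) with group-typical mixtures."""
    base = sim.VolumeSpec(**(config.volume or {}))
    n_wm = base.wm_fraction * float(np.prod(base.grid_shape))
    for group, n in config.n_image_subjects.items():
        rules = _IMAGE_PARAM_RULES.get(group, _IMAGE_PARAM_RULES["RRMS"])
        for i in range(int(n)):
            m1 = _truncnorm(rng, *rules["m1"])
            m2 = _truncnorm(rng, *rules["m2"])
            lam = _truncnorm(rng, *rules["lam"])
            mixture = sim.default_wm_mixture(lam=lam, m1=m1, m2=m2)
            seed = int(rng.integers(2 ** 31))
            if (config.volume or {}).get("n_lesions") == 0:
                # an explicit zero in the config means lesion-free subjects
                yield group, f"{group}-{i:03d}", sim.make_mwf_volume(
                    replace(base, mixture=mixture, seed=seed))
                continue
            n_lesions = max(1, round(lam * n_wm / sim.expected_lesion_volume(base)))
            # back off the lesion count when the load does not pack into WM
            volume = None
            while n_lesions >= 1:
                try:
                    volume = sim.make_mwf_volume(replace(base, mixture=mixture,
                                                         n_lesions=n_lesions, seed=seed))
                    break
                except RuntimeError:
                    n_lesions = int(n_lesions * 0.8) if n_lesions > 1 else 0
            if volume is None:
                logger.warning("skipping %s-%03d: lesion load does not fit", group, i)
                continue
            yield group, f"{group}-{i:03d}", volume


def _ingested_subjects(config: RunConfig):
    for d in config.subject_dirs:
        d = Path(d)
        yield "INGEST", d.name, mk.LabeledVolume.load(d)


def run_study(config: RunConfig) -> dict:
    """Run the full study; returns the results bundle (also written to disk).

    Bundle contents: per-subject fit files, per-group Dice comparison tables
    and tests, per-group Welch comparisons of cohort characteristics, both
    predictor-set regressions per group with adjusted R², the LMG table of
    the selected gamma-mixture model, and a manifest with configuration,
    seeds and a machine-readable list of stage errors.  A stage failure is
    recorded and the remaining stages still run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    errors: list[dict] = []
    bundle: dict = {"subjects": {}, "dice": {}, "welch": {}, "models": {},
                    "lmg": {}, "manifest": {}}
    ss = np.random.SeedSequence(config.seed)
    seed_image, seed_cohort, seed_subject = ss.spawn(3)
    rng_image = np.random.default_rng(seed_image)
    rng_subject = np.random.default_rng(seed_subject)

    # ---- image arm: per-subject fits and Dice ----------------------------
    subject_rows = []
    dice_inputs: dict[str, list] = {}
    try:
        subjects = (_simulated_image_subjects(config, rng_image)
                    if config.mode == "simulate" else _ingested_subjects(config))
        for group, sid, volume in subjects:
            res = run_subject(volume, subject_id=sid, n_bootstrap=config.n_bootstrap,
                              alpha=config.alpha, seed=rng_subject,
                              max_fit_voxels=config.max_fit_voxels,
                              out_dir=out / "fits", save_nifti=config.save_nifti)
            row = dict(res.features, group=group)
            subject_rows.append(row)
            bundle["subjects"][sid] = row
            if (res.roi_m1 is not None and volume.lesion is not None
                    and volume.lesion.any()):
                nawm = volume.nawm if volume.nawm is not None else mk.nawm_mask(volume)
                dice_inputs.setdefault(group, []).append(
                    (volume.lesion, nawm, res.roi_m1, res.roi_m2))
    except Exception as err:  # pragma: no cover - defensive
        logger.exception("image arm failed")
        errors.append({"stage": "image_subjects", "error": str(err)})

    if subject_rows:
        pd.DataFrame(subject_rows).to_csv(out / "subjects.csv", index=False)

    for group, entries in sorted(dice_inputs.items()):
        try:
            if len(entries) < 3:
                raise ValueError(f"group {group}: fewer than 3 subjects with defined "
                                 "Dice; comparison skipped")
            lesion_cmp = mk.compare_dice_groups(
                [(les, r1, r2) for les, _, r1, r2 in entries], reference="lesion")
            nawm_cmp = mk.compare_dice_groups(
                [(na, r1, r2) for _, na, r1, r2 in entries], reference="nawm")
            bundle["dice"][group] = {
                "lesion": _dice_dict(lesion_cmp), "nawm": _dice_dict(nawm_cmp)}
            pd.DataFrame({
                "dice_lesion_roi_m1": lesion_cmp.per_subject_dice_m1,
                "dice_lesion_roi_m2": lesion_cmp.per_subject_dice_m2,
                "dice_nawm_roi_m1": nawm_cmp.per_subject_dice_m1,
                "dice_nawm_roi_m2": nawm_cmp.per_subject_dice_m2,
            }).to_csv(out / f"dice_{group}.csv", index=False)
        except Exception as err:
            logger.warning("Dice stage failed for group %s: %s", group, err)
            errors.append({"stage": f"dice_{group}", "error": str(err)})
    if not dice_inputs:
        errors.append({"stage": "dice",
                       "error": "no subjects with nonempty lesion masks and a chosen "
                                "mixture; group Dice comparison aborted"})

    # ---- cohort arm: Welch comparisons and regressions --------------------
    cohort_overrides = config.cohorts or {}
    cohort_seeds = seed_cohort.generate_state(2) % 2 ** 31
    specs = {"RRMS": sim.rrms_cohort_spec(seed=int(cohort_seeds[0]),
                                          **cohort_overrides.get("RRMS", {})),
             "SPMS": sim.spms_cohort_spec(seed=int(cohort_seeds[1]),
                                          **cohort_overrides.get("SPMS", {}))}
    tables = {}
    for group, spec in specs.items():
        try:
            tables[group] = sim.make_cohort(spec)
        except Exception as err:
            errors.append({"stage": f"cohort_{group}", "error": str(err)})
    if tables:
        pd.concat(tables.values(), ignore_index=True).to_csv(out / "cohort.csv",
                                                             index=False)

    if len(tables) == 2:
        try:
            welch = {}
            for col in ("age", "cortical_thickness", "mean_nawm_mwf", "mean_lesion_mwf"):
                res = rg.welch_t(tables["RRMS"][col], tables["SPMS"][col])
                welch[col] = {"t": res.statistic, "df": res.df, "p": res.p_value}
            bundle["welch"] = welch
        except Exception as err:
            errors.append({"stage": "welch", "error": str(err)})

    for group, table in tables.items():
        try:
            cmp = rg.compare_predictor_sets(table, GAMMA_SET, MASK_SET,
                                            "cortical_thickness", k=config.cv_folds,
                                            seed=config.seed)
            bundle["models"][group] = cmp.to_dict()
            if cmp.model_gamma.predictors:
                imp = rg.lmg_importance(table, cmp.model_gamma.predictors,
                                        "cortical_thickness")
                bundle["lmg"][group] = {"shares": imp.shares,
                                        "relative": imp.relative, "r2": imp.r2}
        except Exception as err:
            logger.warning("regression stage failed for group %s: %s", group, err)
            errors.append({"stage": f"models_{group}", "error": str(err)})

    # ---- provenance --------------------------------------------------------
    import mwfmix
    bundle["manifest"] = {"config": config.to_dict(), "seed": config.seed,
                          "version": mwfmix.__version__, "errors": errors}
    for name in ("dice", "welch", "models", "lmg", "manifest"):
        with open(out / f"{name}.json", "w") as fh:
            json.dump(bundle[name], fh, indent=1, sort_keys=True, default=float)
    return bundle


def _dice_dict(cmp: mk.DiceComparison) -> dict:
    return {"reference": cmp.reference,
            "mean_dice_roi_m1": float(np.mean(cmp.per_subject_dice_m1)),
            "mean_dice_roi_m2": float(np.mean(cmp.per_subject_dice_m2)),
            "t": cmp.t_statistic, "df": cmp.df, "p": cmp.p_value,
            "direction": cmp.direction, "n": len(cmp.per_subject_dice_m1)}
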