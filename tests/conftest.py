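import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mwfmix import GammaMixtureEM, make_mwf_volume, sample_gamma_mixture
from mwfmix.simulate import VolumeSpec, default_wm_mixture

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_mixture():
    """Two-component WM mixture with modes 0.06 / 0.17 and mixing ratio 0.25."""
    return default_wm_mixture()


@pytest.fixture(scope="session")
def big_sample(reference_mixture):
    """100,000 seeded draws from the reference mixture."""
    return sample_gamma_mixture(reference_mixture, 100_000, seed=0)


@pytest.fixture(scope="session")
def big_fit(big_sample):
    """EM fit of the 100,000-draw reference sample (shared across tests)."""
    return GammaMixtureEM().fit(big_sample)


@pytest.fixture(scope="session")
def default_volume():
    """One synthetic subject volume at the default spec."""
    return make_mwf_volume(VolumeSpec())


def small_volume_spec(**overrides) -> VolumeSpec:
    """Desk-scale volume spec for fast tests (~2,700 WM voxels)."""
    base = dict(grid_shape=(24, 24, 12), wm_fraction=0.40, n_lesions=4,
                lesion_radius_range=(1.5, 2.5), dirty_rim_width=1.0)
    base.update(overrides)
    return VolumeSpec(**base)


@pytest.fixture(scope="session")
def dice_cohort():
    """Dice inputs for 20 synthetic subjects at the default volume spec.

    Per subject: the gamma mixture is fitted to a 20,000-voxel subsample of
    the pooled WM values and the mode-derived ROIs are compared against the
    ground-truth lesion and NAWM masks.
    """
    from dataclasses import replace

    from mwfmix import dice, roi_from_modes

    rows = []
    rng = np.random.default_rng(2024)
    spec = VolumeSpec()
    for seed in range(20):
        vol = make_mwf_volume(replace(spec, seed=seed))
        x = vol.wm_values()
        sub = rng.choice(x, size=20_000, replace=False)
        fit = GammaMixtureEM().fit(sub)
        roi1, roi2 = roi_from_modes(vol, fit.m1_, fit.m2_)
        rows.append({
            "lesion": vol.lesion, "nawm": vol.nawm, "roi1": roi1, "roi2": roi2,
            "dice_lesion_roi1": dice(vol.lesion, roi1),
            "dice_lesion_roi2": dice(vol.lesion, roi2),
            "dice_nawm_roi1": dice(vol.nawm, roi1),
            "dice_nawm_roi2": dice(vol.nawm, roi2),
        })
    return rows
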