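import numpy as np
import pytest

from spiscreen.synthetic import ScreenSimConfig, generate_screen


@pytest.fixture
def small_noiseless_config():
    """24 strains, 4 replicates, no noise: every colony equals baseline."""
    return ScreenSimConfig(
        n_strains=24,
        replicates_per_strain=4,
        plate_rows=8,
        plate_cols=12,
        colony_noise_cv=0.0,
        plate_effect_cv=0.0,
        seed=11,
    )


@pytest.fixture
def planted_screen():
    """1000-strain noisy screen with 10 planted hits of true LGR >= 0.8."""
    hits = {f"strain-{i:04d}": 0.8 + 0.05 * i for i in range(1, 11)}
    cfg = ScreenSimConfig(
        n_strains=1000,
        replicates_per_strain=4,
        colony_noise_cv=0.2,
        plate_effect_cv=0.1,
        hit_lgr=hits,
        seed=7,
    )
    layout, tables, truth = generate_screen(cfg)
    return cfg, layout, tables, truth


def brute_force_sphere_count(shape, center_um, radius_um, vz_nm, vxy_nm):
    """Exhaustive voxel-center enumeration oracle for sphere rasterization."""
    vz, vxy = vz_nm / 1000.0, vxy_nm / 1000.0
    count = 0
    for k in range(shape[0]):
        for j in range(shape[1]):
            for i in range(shape[2]):
                d2 = (
                    (k * vz - center_um[0]) ** 2
                    + (j * vxy - center_um[1]) ** 2
                    + (i * vxy - center_um[2]) ** 2
                )
                if d2 <= radius_um**2:
                    count += 1
    return count
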