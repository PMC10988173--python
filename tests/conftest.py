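"""Session-scoped trained models over the canonical desk-scale studies.

The study conditions (scene recipe, class prior, schedules) live in
`blindpick.experiments`; several tests share each trained model, so the
whole suite performs four optimization runs in total.
"""

import pytest

from blindpick.experiments import (desk_cfg, flat_noise_scenes,
                                   make_scene_set, noise_recovery_cfg)
from blindpick.training import train


@pytest.fixture(scope="session")
def snr05_data():
    return make_scene_set(snr=0.5, seed=10)


@pytest.fixture(scope="session")
def snr05_eval_data():
    return make_scene_set(snr=0.5, seed=77, n_scenes=3)


@pytest.fixture(scope="session")
def snr01_data():
    return make_scene_set(snr=0.1, seed=10)


@pytest.fixture(scope="session")
def snr01_eval_data():
    return make_scene_set(snr=0.1, seed=77, n_scenes=3)


@pytest.fixture(scope="session")
def joint_snr05(snr05_data):
    """Joint model with consistency regularization, trained at SNR 0.5."""
    scenes, _ = snr05_data
    return train(scenes, desk_cfg())


@pytest.fixture(scope="session")
def consistency_ablation(snr05_data):
    """Controlled lambda_cons ablation: 0.1 vs 0, same data/seed.

    Input augmentation is off in both arms — with it on, both arms converge
    to near-equivariant solutions at desk scale and the consistency
    mechanism is not resolvable above the noise floor.
    """
    scenes, _ = snr05_data
    cons = train(scenes, desk_cfg(input_augmentation=False, max_iters=200))
    nocons = train(scenes, desk_cfg(input_augmentation=False, max_iters=200,
                                    lambda_cons=0.0))
    return cons, nocons


@pytest.fixture(scope="session")
def joint_snr01(snr01_data):
    """Joint model trained at SNR 0.1 for the denoising-recovery check."""
    scenes, _ = snr01_data
    return train(scenes, desk_cfg(max_iters=150))


@pytest.fixture(scope="session")
def denoise_only_500(snr05_data):
    """Denoise-only run (500 iterations) plus its iteration-0 twin."""
    scenes, _ = snr05_data
    at_init = train(scenes, desk_cfg(mode="denoise_only", max_iters=0,
                                     lambda_cons=0.0))
    trained = train(scenes, desk_cfg(mode="denoise_only", max_iters=500,
                                     lambda_cons=0.0))
    return at_init, trained


@pytest.fixture(scope="session")
def noise_recovery():
    """Denoise-only training on flat images with known Gaussian sigma = 2."""
    scenes = flat_noise_scenes(seed=300)
    return train(scenes, noise_recovery_cfg(seed=0)), scenes
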