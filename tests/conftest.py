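import numpy as np
import pytest

from organoidseg import (
    PhantomParams,
    TrainingConfig,
    build_munet,
    confusion,
    generate_phantom,
    metrics,
    predict_mask,
    train,
)


@pytest.fixture(scope="session")
def clean_disk():
    """A noise-free, bud-free, debris-free phantom: one dark ellipse on a
    uniform bright field — the easy case every baseline must nail."""
    params = PhantomParams(
        side=128, n_buds_range=(0, 0), debris_density=0.0,
        shot_noise_scale=None, texture_amplitude=0.0, seed=5,
    )
    return generate_phantom(params, 0)


@pytest.fixture(scope="session")
def noisy_phantom():
    """A phantom at the generator's defaults (buds, debris, shot noise)."""
    return generate_phantom(PhantomParams(side=128, seed=5), 1)


@pytest.fixture(scope="session")
def overfit_result():
    """Mu-Net trained to memorize a single 64x64 phantom (the single-image
    overfit sanity check); shared across tests because the run is the most
    expensive fixture in the suite."""
    img, mask = generate_phantom(PhantomParams(side=64, seed=3), 0)
    spec = build_munet(64)
    cfg = TrainingConfig(seed=0, max_epochs=200, patience=200)
    model = train(spec, [(img, mask)], cfg)
    pred = predict_mask(model, img)
    dice = metrics(confusion(pred, mask)).dice
    return {"model": model, "dice": dice, "img": img, "mask": mask}


def dice_of(pred, gt) -> float:
    return metrics(confusion(pred, gt)).dice
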