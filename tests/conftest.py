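import numpy as np
import pytest

from deepflow import (
    ArchitectureConfig,
    SyntheticConfig,
    generate,
)

#: reduced network used throughout the suite: 4 modules (2 reduction),
#: widths <= 64, 32 px input, 64-d pooled features
REDUCED_WIDTHS = [16, 32, 48, 64]


def reduced_arch(n_classes: int = 3) -> ArchitectureConfig:
    return ArchitectureConfig(
        input_side=32,
        input_channels=2,
        n_classes=n_classes,
        n_modules=4,
        n_reduction_modules=2,
        width_schedule=list(REDUCED_WIDTHS),
        feature_dim=64,
    )


@pytest.fixture(scope="session")
def default_arch() -> ArchitectureConfig:
    return ArchitectureConfig()


@pytest.fixture(scope="session")
def tiny_set():
    """60 synthetic cells, three interphase classes, 32 px."""
    cfg = SyntheticConfig(
        n_cells=60,
        side=32,
        stage_priors=(0.4, 0.3, 0.3, 0, 0, 0, 0),
        damaged_fraction=0.0,
        seed=42,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def separable_set():
    """64 cells from two temporally distant (well-separated) classes."""
    cfg = SyntheticConfig(
        n_cells=64,
        side=32,
        stage_priors=(0.5, 0, 0, 0, 0, 0, 0.5),
        damaged_fraction=0.0,
        seed=5,
    )
    ds, gt = generate(cfg)
    return ds.select_channels(["brightfield", "darkfield"]), gt
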