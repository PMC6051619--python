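import numpy as np
import pandas as pd
import pytest

from thyrodwi.phantom import (
    BENIGN_NODULE,
    PTC_NODULE,
    Nodule,
    PhantomConfig,
    generate_phantom,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Two homogeneous spherical nodules in normal thyroid, no noise."""
    cfg = PhantomConfig(
        grid_shape=(48, 48, 8),
        noise_sigma=0.0,
        seed=7,
        nodules=(
            Nodule((12, 12, 4), 4.0, BENIGN_NODULE),
            Nodule((36, 36, 4), 4.0, PTC_NODULE),
        ),
    )
    series, labels, tissues = generate_phantom(cfg)
    return cfg, series, labels, tissues


def make_flowchart_cohort():
    """Cohort mirroring the study's exclusion flow: 68 benign records of
    which 3 are too-tiny-solid, 1 massive hemorrhage, 1 without normal
    tissue and 1 with IQ 1; 55 matched carcinomas of which 3 have IQ 1."""
    rows = []
    for i in range(68):
        flag, iq = "", 4
        if i < 3:
            flag = "tiny_solid"
        elif i == 3:
            flag = "hemorrhage"
        elif i == 4:
            flag = "no_normal_tissue"
        elif i == 5:
            iq = 1
        rows.append({"nodule_id": f"b{i:03d}", "class_label": "benign",
                     "IQ": iq, "exclusion_flags": flag})
    for i in range(55):
        iq = 1 if i < 3 else 4
        rows.append({"nodule_id": f"m{i:03d}", "class_label": "PTC",
                     "IQ": iq, "exclusion_flags": ""})
    return pd.DataFrame(rows)


@pytest.fixture()
def flowchart_cohort():
    return make_flowchart_cohort()
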