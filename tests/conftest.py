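import numpy as np
import pandas as pd
import pytest

from soyphen.design import build_design
from soyphen.pipeline import run

#: a scaled-down trial (34 plots, 30 genotypes, 3 blocks) with the same
#: structure as the full design; keeps end-to-end tests fast
SMALL_DESIGN_CONFIG = {
    "design": {"n_unreplicated": 28, "check_classes": [[2, 3]], "grid": [4, 3], "n_blocks": 3}
}


@pytest.fixture(scope="session")
def small_design():
    return build_design(
        n_unreplicated=28, check_classes=((2, 3),), grid=(4, 3), n_blocks=3, seed=11
    )


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One full pipeline run on the scaled-down scenario, shared read-only."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    manifest = run(config=SMALL_DESIGN_CONFIG, seed=7, outdir=outdir)
    return outdir, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def read_csv(outdir, name):
    return pd.read_csv(outdir / name)
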