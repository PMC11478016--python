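"""Shared fixtures.

The contrast-depth study (phantom + XFET expectation) is the expensive,
deterministic backbone of several tests; it is computed once per session and
replicate noise realizations are drawn from it cheaply.
"""

import numpy as np
import pytest

import xfetsim as x
from xfetsim.studies import run_contrast_depth_study


@pytest.fixture(scope="session")
def study():
    return run_contrast_depth_study(seed=1)


@pytest.fixture(scope="session")
def xfet_cnr_table(study):
    """Five-replicate XFET CNR table at the study's operating point."""
    return study.xfet_cnr_table(seeds=[11, 12, 13, 14, 15])


@pytest.fixture(scope="session")
def ct_cnr_tables(study):
    """Five-replicate PCCT and EICT CNR tables for the 3.25-mm plane."""
    return {
        "pcct": study.ct_cnr_table(3.25, "pcct", [21, 22, 23, 24, 25]),
        "eict": study.ct_cnr_table(3.25, "eict", [31, 32, 33, 34, 35]),
    }


@pytest.fixture(scope="session")
def contrast_phantom():
    return x.build_contrast_depth_phantom()


@pytest.fixture(scope="session")
def mouse_phantom():
    return x.build_mouse_phantom(0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20241015)
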