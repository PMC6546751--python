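"""Shared fixtures: generated scenes and sequence sets (no stored data)."""

import numpy as np
import pytest

from porethread.backbone import DihedralRepeat, build_chain
from porethread.sequences import load_casein_precursors
from porethread.synthetic import make_channel_scene
from porethread.threading import RotamerSet


#: the selected two-residue repeat of the channel strand
SELECTED_REPEAT = DihedralRepeat(-92.0, 118.0, -102.0, 110.0)


@pytest.fixture(scope="session")
def selected_repeat() -> DihedralRepeat:
    return SELECTED_REPEAT


@pytest.fixture(scope="session")
def chain13(selected_repeat):
    return build_chain(selected_repeat, 13)


@pytest.fixture(scope="session")
def casein():
    return load_casein_precursors()


@pytest.fixture(scope="session")
def rotamers():
    rs = RotamerSet()
    for aa in "ACDEFGHIKLMNPQRSTVWY":  # warm the template cache once
        rs.template(aa)
    return rs


@pytest.fixture(scope="session")
def scene9(rotamers):
    """Small noiseless channel scene shared by read-only tests."""
    return make_channel_scene(seed=11, k=9, rotamers=rotamers)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
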