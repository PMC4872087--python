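"""Shared helpers for the test suite."""

import numpy as np
import pytest

from readerscreen import ControlSet


def make_controls(mu_max, sd_max, mu_min, sd_min, blanks=()):
    """Two-point control arms with exact mean and sample SD (ddof=1).

    For values m +/- d the sample standard deviation is d*sqrt(2), so
    d = sd/sqrt(2) reproduces the requested SD exactly.
    """
    dp = sd_max / np.sqrt(2.0)
    dn = sd_min / np.sqrt(2.0)
    return ControlSet(
        positive_values=(mu_max + dp, mu_max - dp),
        negative_values=(mu_min + dn, mu_min - dn),
        blank_values=blanks,
    )


@pytest.fixture
def paper_fp_refs():
    from readerscreen import PolarizationReferences

    return PolarizationReferences(p_dstar=25.0, p_dstar_r=225.0, g_factor=0.91)
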