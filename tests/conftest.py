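import numpy as np
import pytest

from c14pop import (FilterCriteria, UncalDate, toy_identity_curve,
                    toy_wiggly_curve)


@pytest.fixture(scope="session")
def identity_curve():
    """mu(t) = t, sigma_curve = 0: calibration is exactly Gaussian."""
    return toy_identity_curve(8000, 2000, 0.0)


@pytest.fixture(scope="session")
def noisy_identity_curve():
    return toy_identity_curve(8000, 2000, 10.0)


@pytest.fixture(scope="session")
def wiggly_curve():
    """Knotted IntCal-like curve with sinusoidal wiggles."""
    return toy_wiggly_curve(8000, 2000)


def make_date(cra, site="s1", label="A", error=30.0, **kw):
    kw.setdefault("method", "AMS")
    kw.setdefault("material_class", "terrestrial")
    return UncalDate(lab_id=kw.pop("lab_id", f"L{cra:.0f}"), site_id=site,
                     set_label=label, cra=float(cra), error=float(error), **kw)


@pytest.fixture
def six_row_table():
    """1 marine, 1 high-d13C, 1 outside the CRA window, 3 clean."""
    return [
        make_date(5000, lab_id="clean1"),
        make_date(5200, lab_id="marine1", material_class="marine"),
        make_date(5400, lab_id="highc13", delta13c=-23.0),
        make_date(8000, lab_id="tooold"),
        make_date(5600, lab_id="clean2", delta13c=-25.5),
        make_date(3000, lab_id="clean3"),
    ]
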