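import pytest

from cimion.spectra_io import Spectrum

# Worked-example data: observed m/z, theoretical m/z, printed mass error
# (mDa, theoretical minus observed) and ion species, per compound.
TABLE4 = {
    "3,4-dihydroxyphenylacetic acid": {
        "base_formula": "C8H8O4",
        "n_tms": 3,
        "derivatized": "C17H32O4Si3",
        "rows": [
            (384.1612, 384.1608, -0.4, "[M]+"),
            (369.1377, 369.1374, -0.3, "[M-CH3]+"),
            (413.2004, 413.2000, -0.4, "[M+C2H5]+"),
            (425.1996, 425.2000, 0.4, "[M+C3H5]+"),
            (457.2088, 457.2082, -0.6, "[M+TMS]+"),
        ],
    },
    "phosphoric acid": {
        "base_formula": "H3PO4",
        "n_tms": 3,
        "derivatized": "C9H27O4PSi3",
        "rows": [
            (315.1031, 315.1033, 0.2, "[M+H]+"),
            (299.0719, 299.0720, 0.1, "[M-CH3]+"),
            (343.1345, 343.1346, 0.1, "[M+C2H5]+"),
            (355.1342, 355.1346, 0.4, "[M+C3H5]+"),
            (387.1428, 387.1428, 0.0, "[M+TMS]+"),
        ],
    },
    "2,5-dihydroxyphenylacetic acid": {
        "base_formula": "C8H8O4",
        "n_tms": 3,
        "derivatized": "C17H32O4Si3",
        "rows": [
            (384.1608, 384.1608, 0.0, "[M]+"),
            (369.1374, 369.1374, 0.0, "[M-CH3]+"),
            (413.1995, 413.2000, 0.5, "[M+C2H5]+"),
            (425.1985, 425.2000, 1.5, "[M+C3H5]+"),
            (457.2082, 457.2082, 0.0, "[M+TMS]+"),
        ],
    },
}


@pytest.fixture
def phosphoric_toy() -> Spectrum:
    """The four observed phosphoric-acid 3TMS pattern ions as a toy spectrum."""
    return Spectrum(
        [(299.0719, 80.0), (315.1031, 100.0), (343.1345, 3.0), (355.1342, 2.0)],
        {"Name": "phosphoric acid"},
    )


@pytest.fixture
def phosphoric_toy_with_tms(phosphoric_toy) -> Spectrum:
    """Same toy plus the observed [M+TMS]+ rearrangement peak at 20% bp."""
    return Spectrum(
        phosphoric_toy.peaks + [(387.1428, 20.0)],
        dict(phosphoric_toy.metadata),
    )
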