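"""Shared fixtures: packaged study tables and the printed reference values."""

import pytest

from nmrbind.datasets import (
    load_dilution_series,
    load_dosy_experiment,
    load_nick_map,
    load_shift_records,
)

# Per-proton self-association constants (mM^-1) and limiting shifts (Hz) as
# printed for the study, used as an external reference for the refits.
PRINTED_KA = {
    "1": {
        "H12": 0.554, "H9": 4.536, "H11": 5.770, "H23": 8.007, "H5": 9.122,
        "H24a": 10.012, "H24b": 7.438, "H26/H27": 5.302, "H14": 6.952,
        "H17a": 5.989, "H17b": 5.719, "H18": 6.183, "H19": 7.478,
    },
    "2": {
        "H12": 1.851, "H9": 2.950, "H11": 1.907, "H22": 2.153, "H23": 6.322,
        "H5": 3.871, "H24a": 2.930, "H25/H28": 1.029, "H14": 1.869,
        "H17a": 1.161, "H19": 5.573,
    },
}

PRINTED_MEANS = {
    # compound -> (mean over all protons, mean after exclusions)
    "1": (6.4, 6.9),
    "2": (2.9, 2.2),
}


@pytest.fixture(scope="session")
def nick_map():
    return load_nick_map()


@pytest.fixture(scope="session")
def dilution_1():
    return load_dilution_series("1")


@pytest.fixture(scope="session")
def dilution_2():
    return load_dilution_series("2")


@pytest.fixture(scope="session")
def dosy_1():
    return load_dosy_experiment("1")


@pytest.fixture(scope="session")
def dosy_2():
    return load_dosy_experiment("2")


@pytest.fixture(scope="session")
def dna_shifts_1():
    return load_shift_records("dna", "1")


@pytest.fixture(scope="session")
def dna_shifts_2():
    return load_shift_records("dna", "2")


@pytest.fixture(scope="session")
def ligand_shifts_1():
    return load_shift_records("ligand", "1")
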