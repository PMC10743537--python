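"""Accessors for the packaged study tables.

The package ships the printed tables of the nicked-decamer interaction
study as plain CSV fixtures (dilution shift series for both diastereomers,
free-species diffusion coefficients, the equimolar DOSY experiments, and
the ligand/DNA shift tables), plus the duplex nick map.  These are the
single transcription of the study data; analyses and tests read them
through this module rather than duplicating numbers.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

from .dosy import BindingExperiment, experiment_from_records
from .tables import (
    DiffusionRecord,
    DilutionSeries,
    NickMap,
    ShiftRecord,
    read_diffusion_table,
    read_dilution_table,
    read_shift_table,
)

__all__ = [
    "data_path",
    "load_dilution_series",
    "load_free_diffusion",
    "load_dosy_experiment",
    "load_shift_records",
    "load_nick_map",
    "EXCLUDED_PROTONS",
    "STUDY_CONCENTRATION_MM",
]

#: Protons excluded from the compound-level mean Ka, as reported by the
#: experimenters (deviations left unexplained; exclusion is explicit input).
EXCLUDED_PROTONS = {"1": ("H12",), "2": ("H23", "H19")}

#: Ligand and duplex total concentration (mM) of the equimolar DOSY mixtures.
STUDY_CONCENTRATION_MM = 0.60


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(files("nmrbind") / "data" / name))


def load_dilution_series(compound: str) -> list[DilutionSeries]:
    """Dilution shift series (Hz vs. mM) for compound ``"1"`` or ``"2"``."""
    return read_dilution_table(data_path(f"dilution_compound{compound}.csv"))


def load_free_diffusion(compound: str | None = None) -> list[DiffusionRecord]:
    """Free-species diffusion coefficients vs. concentration.

    With ``compound`` given, only that species' records are returned.
    """
    records = read_diffusion_table(data_path("diffusion_free.csv"))
    if compound is None:
        return records
    return [r for r in records if r.species_id == compound]


def load_dosy_experiment(compound: str) -> BindingExperiment:
    """The equimolar (0.60 mM / 0.60 mM) DOSY binding experiment."""
    records = read_diffusion_table(data_path(f"dosy_compound{compound}.csv"))
    return experiment_from_records(records,
                                   c_ligand=STUDY_CONCENTRATION_MM,
                                   c_dna=STUDY_CONCENTRATION_MM)


def load_shift_records(kind: str, compound: str) -> list[ShiftRecord]:
    """Shift tables: ``kind`` is ``"ligand"`` or ``"dna"``."""
    if kind not in ("ligand", "dna"):
        raise ValueError(f"kind must be 'ligand' or 'dna', got {kind!r}")
    return read_shift_table(data_path(f"shifts_{kind}{compound}.csv"))


def load_nick_map() -> NickMap:
    """Topology of the nicked decamer duplex (nick between T5 and G6)."""
    return NickMap.from_json(data_path("nick_map.json"))
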