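"""Data model and CSV readers/writers for the three table families.

Three plain-text table dialects are supported, mirroring how NMR titration
results are conventionally tabulated:

* **dilution tables** (wide): one ``conc`` column in mM plus one column per
  proton holding the chemical-shift change Δδ in Hz relative to the most
  dilute sample (positive = low-frequency shift);
* **diffusion tables** (long): ``species, conc, D, sigma`` with diffusion
  coefficients in units of 1e-10 m² s⁻¹;
* **shift tables** (long): ``unit, class, free, complex`` with chemical
  shifts in ppm of the free species and of the same proton in the mixture.

Units are fixed by dialect — concentrations are always mM, dilution shifts
always Hz, shift tables always ppm.  There is deliberately no unit
autodetection: silently mixing Hz and ppm is the main foreseeable bug in
this kind of analysis.  Proton and unit labels are free strings matched
exactly and case-sensitively.

An optional JSON sidecar ``<table>.csv.meta.json`` may carry sample metadata
(compound id, buffer, temperature, pH); it is attached to the parsed objects
and carried through to reports.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: Allowed proton-class tokens in shift tables.
PROTON_CLASSES = ("H6/H8", "H1'", "ligand")

#: Unicode characters accepted as a negative sign in numeric cells.
_MINUS_VARIANTS = {"−": "-", "–": "-", "—": "-"}


class TableFormatError(ValueError):
    """A table file does not match its declared dialect."""


class TableParseError(ValueError):
    """A cell could not be parsed; the message names the row and column."""


def _parse_number(token: str, *, row: int | str, column: str) -> float:
    """Parse one numeric cell, accepting U+2212 et al. as a minus sign."""
    text = str(token).strip()
    for bad, good in _MINUS_VARIANTS.items():
        text = text.replace(bad, good)
    try:
        return float(text)
    except ValueError as exc:
        raise TableParseError(
            f"non-numeric cell {token!r} at row {row}, column {column!r}"
        ) from exc


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DilutionPoint:
    """One (total concentration, shift change) observation.

    ``conc_total`` is the total ligand concentration [L0] in mM;
    ``delta_shift`` is Δδ in Hz relative to the most dilute sample,
    positive meaning a low-frequency (upfield) shift.
    """

    conc_total: float
    delta_shift: float

    def __post_init__(self) -> None:
        if not self.conc_total > 0:
            raise ValueError(f"conc_total must be > 0, got {self.conc_total}")


@dataclass(frozen=True)
class DilutionSeries:
    """Concentration → Δδ(Hz) curve for one proton of one compound."""

    compound_id: str
    proton_label: str
    points: tuple[DilutionPoint, ...]
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if len(self.points) < 4:
            raise ValueError(
                f"series {self.proton_label!r} has {len(self.points)} points; "
                "at least 4 are required"
            )
        concs = self.concentrations
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError(
                f"series {self.proton_label!r}: concentrations must be "
                "strictly increasing"
            )
        if self.points[0].delta_shift != 0.0:
            raise ValueError(
                f"series {self.proton_label!r}: the lowest-concentration point "
                "must have delta_shift = 0 (it is the shift reference)"
            )

    @property
    def concentrations(self) -> tuple[float, ...]:
        return tuple(p.conc_total for p in self.points)

    @property
    def shifts(self) -> tuple[float, ...]:
        return tuple(p.delta_shift for p in self.points)


@dataclass(frozen=True)
class DiffusionRecord:
    """A diffusion coefficient for one species at one concentration.

    ``d_coef`` and ``d_sigma`` are in units of 1e-10 m² s⁻¹; ``conc`` in mM.
    """

    species_id: str
    conc: float
    d_coef: float
    d_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not self.d_coef > 0:
            raise ValueError(f"d_coef must be > 0, got {self.d_coef}")
        if self.d_sigma < 0:
            raise ValueError(f"d_sigma must be >= 0, got {self.d_sigma}")


@dataclass(frozen=True)
class ShiftRecord:
    """Chemical shift of one proton group, free and in the mixture (ppm)."""

    unit_label: str
    proton_class: str
    delta_free: float
    delta_complex: float

    def __post_init__(self) -> None:
        if self.proton_class not in PROTON_CLASSES:
            raise ValueError(
                f"unknown proton class {self.proton_class!r}; "
                f"expected one of {PROTON_CLASSES}"
            )
        for name, value in (("delta_free", self.delta_free),
                            ("delta_complex", self.delta_complex)):
            if not 0.0 <= value <= 20.0:
                raise ValueError(f"{name} = {value} ppm outside 0-20 ppm")


@dataclass(frozen=True)
class NickMap:
    """Topology of the nicked decamer duplex.

    Strand 1 carries the single-strand break (between ``nick_after`` and the
    following unit); strand 2 is intact.  ``nick_adjacent_set`` lists the
    units of the two base pairs flanking each face of the nick, the region
    where an intercalating ligand is expected to perturb shifts.
    """

    strand1_units: tuple[str, ...]
    strand2_units: tuple[str, ...]
    nick_after: str
    nick_adjacent_set: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "strand1_units", tuple(self.strand1_units))
        object.__setattr__(self, "strand2_units", tuple(self.strand2_units))
        object.__setattr__(self, "nick_adjacent_set",
                           frozenset(self.nick_adjacent_set))
        all_units = self.all_units
        if not self.nick_adjacent_set <= all_units:
            extra = self.nick_adjacent_set - all_units
            raise ValueError(f"nick-adjacent units not on either strand: {extra}")
        if self.nick_after not in self.strand1_units:
            raise ValueError("the nick must lie inside strand 1")
        if self.strand1_units.index(self.nick_after) == len(self.strand1_units) - 1:
            raise ValueError("the nick cannot fall after the 3' terminal unit")

    @property
    def all_units(self) -> frozenset[str]:
        return frozenset(self.strand1_units) | frozenset(self.strand2_units)

    @classmethod
    def from_json(cls, path: str | Path) -> "NickMap":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            strand1_units=raw["strand1_units"],
            strand2_units=raw["strand2_units"],
            nick_after=raw["nick_after"],
            nick_adjacent_set=raw["nick_adjacent_set"],
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _load_sidecar(path: Path) -> dict:
    sidecar = path.with_name(path.name + ".meta.json")
    if sidecar.exists():
        return json.loads(sidecar.read_text(encoding="utf-8"))
    return {}


def read_dilution_table(path: str | Path,
                        compound_id: str | None = None) -> list[DilutionSeries]:
    """Read a wide dilution table into one :class:`DilutionSeries` per proton.

    Rows are sorted by concentration; the compound id comes from, in order,
    the ``compound_id`` argument, the JSON sidecar, or the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    if "conc" not in df.columns:
        raise TableFormatError(
            f"{path.name}: missing required concentration column 'conc'"
        )
    meta = _load_sidecar(path)
    if compound_id is None:
        compound_id = str(meta.get("compound_id", path.stem))

    proton_cols = [c for c in df.columns if c != "conc"]
    if df.empty:
        return []

    parsed = pd.DataFrame({
        col: [
            _parse_number(v, row=i, column=col)
            for i, v in zip(df.index, df[col])
        ]
        for col in df.columns
    })
    parsed = parsed.sort_values("conc", kind="stable").reset_index(drop=True)

    out = []
    for col in proton_cols:
        points = [
            DilutionPoint(conc_total=c, delta_shift=s)
            for c, s in zip(parsed["conc"], parsed[col])
        ]
        out.append(DilutionSeries(compound_id=compound_id, proton_label=col,
                                  points=points, metadata=meta))
    return out


def read_diffusion_table(path: str | Path) -> list[DiffusionRecord]:
    """Read a long diffusion table (``species, conc, D, sigma``).

    Records are returned in file order.  A missing ``sigma`` column is
    tolerated: uncertainties default to 0 and a warning is logged.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for col in ("species", "conc", "D"):
        if col not in df.columns:
            raise TableFormatError(f"{path.name}: missing required column {col!r}")
    has_sigma = "sigma" in df.columns
    if not has_sigma:
        logger.warning("%s: no 'sigma' column; uncertainties set to 0", path.name)

    out = []
    for i, row in df.iterrows():
        out.append(DiffusionRecord(
            species_id=str(row["species"]).strip(),
            conc=_parse_number(row["conc"], row=i, column="conc"),
            d_coef=_parse_number(row["D"], row=i, column="D"),
            d_sigma=(_parse_number(row["sigma"], row=i, column="sigma")
                     if has_sigma else 0.0),
        ))
    return out


def read_shift_table(path: str | Path) -> list[ShiftRecord]:
    """Read a long shift table (``unit, class, free, complex``).

    Each (unit, class) pair must be unique; a duplicate is a validation
    error rather than a silent overwrite.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for col in ("unit", "class", "free", "complex"):
        if col not in df.columns:
            raise TableFormatError(f"{path.name}: missing required column {col!r}")

    seen: set[tuple[str, str]] = set()
    out = []
    for i, row in df.iterrows():
        key = (str(row["unit"]).strip(), str(row["class"]).strip())
        if key in seen:
            raise ValueError(f"{path.name}: duplicated unit+class pair {key}")
        seen.add(key)
        out.append(ShiftRecord(
            unit_label=key[0],
            proton_class=key[1],
            delta_free=_parse_number(row["free"], row=i, column="free"),
            delta_complex=_parse_number(row["complex"], row=i, column="complex"),
        ))
    return out


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)
# ---------------------------------------------------------------------------

def write_dilution_table(series: list[DilutionSeries], path: str | Path) -> None:
    """Write dilution series back to the wide CSV dialect.

    All series must share one concentration grid (they come from the same
    dilution experiment).
    """
    if not series:
        raise ValueError("nothing to write")
    grid = series[0].concentrations
    for s in series:
        if s.concentrations != grid:
            raise ValueError("all series must share one concentration grid")
    df = pd.DataFrame({"conc": grid})
    for s in series:
        df[s.proton_label] = s.shifts
    df.to_csv(path, index=False, float_format="%.12g")


def write_diffusion_table(records: list[DiffusionRecord], path: str | Path) -> None:
    df = pd.DataFrame([
        {"species": r.species_id, "conc": r.conc, "D": r.d_coef, "sigma": r.d_sigma}
        for r in records
    ], columns=["species", "conc", "D", "sigma"])
    df.to_csv(path, index=False, float_format="%.12g")


def write_shift_table(records: list[ShiftRecord], path: str | Path) -> None:
    df = pd.DataFrame([
        {"unit": r.unit_label, "class": r.proton_class,
         "free": r.delta_free, "complex": r.delta_complex}
        for r in records
    ], columns=["unit", "class", "free", "complex"])
    df.to_csv(path, index=False, float_format="%.12g")
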