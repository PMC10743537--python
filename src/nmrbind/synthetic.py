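"""Synthetic-data generators with the statistical structure the analysis assumes.

Each generator draws from the forward model of the corresponding analysis
stage — isodesmic stacking for dilution shift curves, 1:1 mass action plus
fast-exchange averaging for DOSY experiments, localized perturbations on a
baseline for CSP tables — and adds homoscedastic Gaussian noise on each
observable (Hz, coefficient units, ppm respectively).  All draws come from
``numpy.random.default_rng(seed)``, so output is bit-reproducible for a
fixed seed and spec, and noiseless generation followed by the matching
estimator is the identity on the ground-truth parameters.

Defaults are the working scale of a dilution/DOSY study on a sparingly
soluble intercalator with a DNA decamer: an eight-point dilution grid from
0.013 to 0.789 mM, diffusion coefficients of order 2 (ligand) and 0.75
(duplex) in 1e-10 m² s⁻¹, and ±0.05 coefficient noise — so synthetic tests
run at the same scale as a real study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dosy import BindingExperiment, solve_equilibrium
from .selfassoc import isodesmic_shift
from .tables import DilutionPoint, DilutionSeries, NickMap, ShiftRecord

__all__ = [
    "SyntheticSpec",
    "generate_dilution_series",
    "generate_dosy_experiment",
    "generate_csp_tables",
]

#: Eight-point dilution grid (mM) typical of a stepwise 1:1 dilution from
#: the solubility limit down to ~0.013 mM.
DEFAULT_CONC_GRID = (0.013, 0.027, 0.053, 0.099, 0.199, 0.349, 0.543, 0.789)


def _default_delta_max() -> dict:
    # the per-proton limiting-shift scale of a camptothecin-family stacker:
    # strongly shielded aromatic protons (hundreds of Hz), weakly responding
    # aliphatic ones (tens of Hz), and two shifting the opposite way
    return {
        "H12": 745.9, "H9": 111.9, "H11": 232.5, "H23": -87.7, "H5": 200.0,
        "H24a": 176.3, "H24b": 211.2, "H26/H27": -42.7, "H14": 274.7,
        "H17a": 53.8, "H17b": 82.2, "H18": 29.9, "H19": 26.8,
    }


def _default_csp_baseline() -> dict:
    return {}


@dataclass
class SyntheticSpec:
    """Ground-truth parameters, grids, noise levels and seed for all generators."""

    seed: int = 0
    conc_grid: tuple[float, ...] = DEFAULT_CONC_GRID
    truth_ka: float = 5.0                      # mM^-1, self-association
    truth_delta_max: dict = field(default_factory=_default_delta_max)  # Hz
    shift_noise_sd: float = 0.0                # Hz
    binding_truth_ka: float = 100.0            # mM^-1, 1:1 binding
    d_free_ligand: float = 2.1                 # 1e-10 m^2 s^-1
    d_free_dna: float = 0.75
    d_complex: float = 0.75
    d_noise_sd: float = 0.0
    csp_baseline: dict = field(default_factory=_default_csp_baseline)  # unit -> ppm
    csp_perturbation_sites: dict = field(default_factory=dict)         # unit -> ppm
    csp_noise_sd: float = 0.0                  # ppm

    def __post_init__(self) -> None:
        self.conc_grid = tuple(float(c) for c in self.conc_grid)
        for name in ("shift_noise_sd", "d_noise_sd", "csp_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(b <= a for a, b in zip(self.conc_grid, self.conc_grid[1:])):
            raise ValueError("conc_grid must be strictly increasing")
        if not self.d_free_ligand > self.d_free_dna:
            raise ValueError("d_free_ligand must exceed d_free_dna")
        if self.d_complex > self.d_free_dna:
            raise ValueError("d_complex cannot exceed d_free_dna")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def generate_dilution_series(spec: SyntheticSpec,
                             compound_id: str = "synthetic") -> list[DilutionSeries]:
    """Dilution shift curves from the isodesmic forward model plus noise.

    For every proton in ``truth_delta_max`` the clean curve is evaluated on
    ``conc_grid``, Gaussian noise of SD ``shift_noise_sd`` (Hz) is added,
    and the curve is re-referenced so the lowest-concentration point is
    exactly 0 — the convention of measured dilution tables, where the most
    dilute sample is the shift reference.
    """
    rng = spec.rng()
    conc = np.asarray(spec.conc_grid)
    out = []
    for label, dmax in spec.truth_delta_max.items():
        clean = isodesmic_shift(spec.truth_ka, conc, dmax)
        noisy = clean + rng.normal(0.0, spec.shift_noise_sd, size=conc.shape)
        rereferenced = noisy - noisy[0]
        points = [DilutionPoint(conc_total=float(c), delta_shift=float(s))
                  for c, s in zip(conc, rereferenced)]
        out.append(DilutionSeries(compound_id=compound_id, proton_label=label,
                                  points=points,
                                  metadata={"synthetic": True, "seed": spec.seed}))
    return out


def generate_dosy_experiment(spec: SyntheticSpec, c_dna: float,
                             c_ligand: float) -> BindingExperiment:
    """A DOSY binding experiment from the 1:1 mass-action forward model.

    The complex concentration comes from the equilibrium solver at
    ``binding_truth_ka``; observed coefficients are the fast-exchange
    population averages of the free and complexed species (using the true
    ``d_complex``), plus Gaussian noise of SD ``d_noise_sd``.  Setting
    ``d_complex`` below ``d_free_dna`` quantifies the bias of the
    complex-diffuses-like-the-duplex analysis assumption.
    """
    rng = spec.rng()
    cc = solve_equilibrium(spec.binding_truth_ka, c_dna, c_ligand)
    mf_free_l = (c_ligand - cc) / c_ligand
    mf_free_dna = (c_dna - cc) / c_dna
    d_obs_l = mf_free_l * spec.d_free_ligand + (1.0 - mf_free_l) * spec.d_complex
    d_obs_dna = mf_free_dna * spec.d_free_dna + (1.0 - mf_free_dna) * spec.d_complex
    noise = rng.normal(0.0, spec.d_noise_sd, size=2) if spec.d_noise_sd else (0.0, 0.0)
    return BindingExperiment(
        c_ligand=c_ligand,
        c_dna=c_dna,
        d_obs_ligand=float(d_obs_l + noise[0]),
        d_obs_dna=float(d_obs_dna + noise[1]),
        d_free_ligand=spec.d_free_ligand,
        d_free_dna=spec.d_free_dna,
        sigma_d={"d_obs_ligand": spec.d_noise_sd, "d_obs_dna": spec.d_noise_sd},
    )


def generate_csp_tables(spec: SyntheticSpec, nick: NickMap,
                        proton_class: str = "H1'") -> list[ShiftRecord]:
    """Free/complexed shift records with perturbations injected at known units.

    The free shift of every unit in ``csp_baseline`` is the baseline value;
    the complexed shift is baseline − injected Δδ (at ``csp_perturbation_sites``)
    plus Gaussian noise of SD ``csp_noise_sd`` everywhere.  Records carry
    both columns, ready for :func:`nmrbind.csp.compute_csp` or for writing
    with :func:`nmrbind.tables.write_shift_table`.
    """
    rng = spec.rng()
    baseline = spec.csp_baseline or {u: 6.0 for u in
                                     nick.strand1_units + nick.strand2_units}
    unknown_base = set(baseline) - nick.all_units
    if unknown_base:
        raise ValueError(f"baseline units not in the nick map: {sorted(unknown_base)}")
    unknown = set(spec.csp_perturbation_sites) - set(baseline)
    if unknown:
        raise ValueError(f"unknown perturbation sites: {sorted(unknown)}")
    out = []
    for unit, free in baseline.items():
        injected = spec.csp_perturbation_sites.get(unit, 0.0)
        noise = rng.normal(0.0, spec.csp_noise_sd) if spec.csp_noise_sd else 0.0
        out.append(ShiftRecord(
            unit_label=unit,
            proton_class=proton_class,
            delta_free=float(free),
            delta_complex=float(free - injected + noise),
        ))
    return out
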