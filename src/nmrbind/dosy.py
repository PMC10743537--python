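"""Binding-constant estimation from DOSY diffusion coefficients.

A small ligand L binding a much larger DNA duplex under fast exchange shows
a single, population-averaged diffusion coefficient:

    D_obs(L) = MF_L * D_L + (1 - MF_L) * D(DNA·L)

where MF_L is the mole fraction of *free* ligand.  Inverting this gives
MF_L from three measurable coefficients; with 1:1 stoichiometry the complex
concentration is [DNA·L] = (1 - MF_L)·C_L, and the mass-action constant

    Ka = [DNA·L] / ((C_DNA - [DNA·L]) (C_L - [DNA·L]))     (mM⁻¹).

Because the duplex is ~15x heavier than the ligand, the complex diffuses
like the duplex, so D(DNA·L) is approximated by the duplex coefficient
observed in the mixture.  The free-ligand coefficient must come from the
most dilute available measurement: self-association depresses the apparent
ligand coefficient at working concentrations.

Hard model assumptions, echoed in every report: 1:1 stoichiometry, fast
exchange on the NMR diffusion timescale, ligand self-association neglected,
and the complex-diffuses-like-the-duplex approximation.

Uncertainties on the coefficients are pushed through the closed-form chain
by first-order (delta-method) propagation; a Monte-Carlo cross-check of the
same propagation lives in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .tables import DiffusionRecord

__all__ = [
    "BindingExperiment",
    "BindingResult",
    "TrendReport",
    "DegenerateContrastError",
    "SaturationError",
    "free_fraction",
    "complex_concentration",
    "binding_constant",
    "analyze_binding",
    "solve_equilibrium",
    "check_concentration_trend",
    "experiment_from_records",
    "select_free_ligand_record",
]

#: Model assumptions carried into every report.
MODEL_ASSUMPTIONS = (
    "1:1 DNA:ligand stoichiometry",
    "fast exchange: observed D is a population-weighted average",
    "ligand self-association neglected in the binding equilibrium",
    "complex diffusion coefficient approximated by the duplex coefficient "
    "observed in the mixture",
)


class DegenerateContrastError(ValueError):
    """Free and complex coefficients coincide; binding is unobservable."""


class SaturationError(ValueError):
    """Complex concentration reaches a total concentration; Ka undefined."""


@dataclass(frozen=True)
class BindingExperiment:
    """Inputs of one DOSY binding measurement.

    Coefficients are in 1e-10 m² s⁻¹, concentrations in mM.  ``sigma_d``
    maps coefficient names (``d_obs_ligand``, ``d_obs_dna``,
    ``d_free_ligand``, ``d_free_dna``) to their stated uncertainties.
    """

    c_ligand: float
    c_dna: float
    d_obs_ligand: float
    d_obs_dna: float
    d_free_ligand: float
    d_free_dna: float
    sigma_d: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("c_ligand", "c_dna", "d_obs_ligand", "d_obs_dna",
                     "d_free_ligand", "d_free_dna"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.d_free_ligand > self.d_free_dna:
            raise ValueError(
                "d_free_ligand must exceed d_free_dna (the ligand is much "
                "smaller than the duplex)"
            )


@dataclass(frozen=True)
class BindingResult:
    """Derived quantities of one DOSY binding analysis."""

    mf_free_ligand: float
    mf_bound: float
    complex_conc: float
    ka: float
    ka_sigma: float
    no_binding: bool = False
    assumptions: tuple[str, ...] = MODEL_ASSUMPTIONS

    def __post_init__(self) -> None:
        if not 0.0 <= self.mf_free_ligand <= 1.0:
            raise ValueError("mf_free_ligand must lie in [0, 1]")
        if self.ka < 0:
            raise ValueError("ka must be >= 0")


def free_fraction(d_obs: float, d_free: float, d_complex: float,
                  noise: float = 0.0) -> float:
    """Mole fraction of the free species from its averaged coefficient.

    MF = (d_obs − d_complex) / (d_free − d_complex).  Values outside [0, 1]
    by at most ``noise`` (the measurement uncertainty on the fraction) are
    clipped with a warning; larger excursions raise, because they mean the
    two-state fast-exchange model is violated rather than merely noisy.
    """
    if d_free == d_complex:
        raise DegenerateContrastError(
            "free and complex coefficients are equal: binding is "
            "unobservable by diffusion"
        )
    mf = (d_obs - d_complex) / (d_free - d_complex)
    if mf < 0.0 or mf > 1.0:
        excess = max(-mf, mf - 1.0)
        if excess <= noise:
            warnings.warn(
                f"mole fraction {mf:.4f} outside [0, 1] by {excess:.4f} "
                "(within measurement noise); clipping",
                stacklevel=2,
            )
            mf = min(1.0, max(0.0, mf))
        else:
            raise ValueError(
                f"mole fraction {mf:.4f} outside [0, 1] by more than the "
                f"stated noise ({noise}); the two-state fast-exchange model "
                "does not hold for these inputs"
            )
    return float(mf)


def complex_concentration(mf_bound: float, c_total: float) -> float:
    """[DNA·L] = bound mole fraction × total concentration (mM)."""
    if not 0.0 <= mf_bound <= 1.0:
        raise ValueError(f"mf_bound must lie in [0, 1], got {mf_bound}")
    return mf_bound * c_total


def binding_constant(complex_conc: float, c_dna: float, c_ligand: float) -> float:
    """1:1 mass-action constant Ka (mM⁻¹) from the complex concentration.

    Ka = [DNA·L] / ((C_DNA − [DNA·L])(C_L − [DNA·L])).
    """
    if complex_conc >= min(c_dna, c_ligand):
        raise SaturationError(
            f"complex concentration {complex_conc} reaches a total "
            f"concentration (C_DNA={c_dna}, C_L={c_ligand}); Ka is undefined"
        )
    if complex_conc < 0:
        raise ValueError("complex_conc must be >= 0")
    return complex_conc / ((c_dna - complex_conc) * (c_ligand - complex_conc))


def solve_equilibrium(ka: float, c_dna: float, c_ligand: float) -> float:
    """Equilibrium [DNA·L] (mM) for a 1:1 binding with constant ``ka``.

    Solves Ka·x² − (Ka·(C_DNA + C_L) + 1)·x + Ka·C_DNA·C_L = 0 for the root
    in [0, min(C_DNA, C_L)), using the numerically stable citardauq form of
    the quadratic formula.  ka = 0 gives 0; ka → ∞ approaches the
    stoichiometric limit min(C_DNA, C_L).
    """
    if ka < 0:
        raise ValueError(f"ka must be >= 0, got {ka}")
    if ka == 0.0:
        return 0.0
    b = ka * (c_dna + c_ligand) + 1.0
    disc = b * b - 4.0 * ka * ka * c_dna * c_ligand
    # physical root is the smaller one; compute it as 2c/(b + sqrt(disc))
    x = 2.0 * ka * c_dna * c_ligand / (b + math.sqrt(disc))
    return float(x)


def _ka_chain(d_obs_l: float, d_complex: float, d_free_l: float,
              c_ligand: float, c_dna: float) -> float:
    mf_free = (d_obs_l - d_complex) / (d_free_l - d_complex)
    mf_free = min(1.0, max(0.0, mf_free))
    cc = (1.0 - mf_free) * c_ligand
    if cc >= min(c_dna, c_ligand):
        raise SaturationError("complex concentration reaches a total concentration")
    return cc / ((c_dna - cc) * (c_ligand - cc))


def analyze_binding(exp: BindingExperiment,
                    d_complex: float | None = None) -> BindingResult:
    """Run the full DOSY chain: mole fraction → [DNA·L] → Ka ± sigma.

    ``d_complex`` defaults to the duplex coefficient observed in the mixture
    (the complex-diffuses-like-the-duplex approximation); pass an
    independently determined complex coefficient to override it.

    Uncertainty: first-order propagation of the stated coefficient sigmas
    (``d_obs_ligand``, ``d_obs_dna``/``d_complex``, ``d_free_ligand``)
    through the closed-form chain, with central-difference sensitivities.
    """
    dc = exp.d_obs_dna if d_complex is None else d_complex
    sig = exp.sigma_d
    noise_mf = 0.0
    if sig:
        denom = abs(exp.d_free_ligand - dc)
        noise_mf = (sig.get("d_obs_ligand", 0.0)
                    + sig.get("d_obs_dna", 0.0)
                    + sig.get("d_free_ligand", 0.0)) / denom

    mf_free = free_fraction(exp.d_obs_ligand, exp.d_free_ligand, dc,
                            noise=noise_mf)
    mf_bound = 1.0 - mf_free
    cc = complex_concentration(mf_bound, exp.c_ligand)

    if mf_bound == 0.0:
        return BindingResult(mf_free_ligand=1.0, mf_bound=0.0, complex_conc=0.0,
                             ka=0.0, ka_sigma=0.0, no_binding=True)

    ka = binding_constant(cc, exp.c_dna, exp.c_ligand)

    # delta-method: ka_sigma² = Σ (∂Ka/∂Di)² σi²
    sigmas = (sig.get("d_obs_ligand", 0.0),
              sig.get("d_obs_dna", 0.0) if d_complex is None else 0.0,
              sig.get("d_free_ligand", 0.0))
    point = (exp.d_obs_ligand, dc, exp.d_free_ligand)
    var = 0.0
    for i, s in enumerate(sigmas):
        if s == 0.0:
            continue
        h = 1e-6 * max(1.0, abs(point[i]))
        hi = list(point)
        lo = list(point)
        hi[i] += h
        lo[i] -= h
        grad = (_ka_chain(*hi, exp.c_ligand, exp.c_dna)
                - _ka_chain(*lo, exp.c_ligand, exp.c_dna)) / (2.0 * h)
        var += (grad * s) ** 2

    return BindingResult(
        mf_free_ligand=mf_free,
        mf_bound=mf_bound,
        complex_conc=cc,
        ka=ka,
        ka_sigma=math.sqrt(var),
    )


def mf_dna_consistency(exp: BindingExperiment,
                       d_complex: float | None = None) -> float:
    """DNA-side free fraction, an optional consistency check.

    Computes MF_DNA from the duplex analogue of the averaging relation using
    the free-duplex coefficient; under the complex-diffuses-like-the-duplex
    approximation the contrast D_DNA − D(DNA·L) is tiny, so this estimate is
    very noisy and is not part of the main chain.
    """
    dc = exp.d_obs_dna if d_complex is None else d_complex
    return free_fraction(exp.d_obs_dna, exp.d_free_dna, dc)


# ---------------------------------------------------------------------------
# concentration-trend check (qualitative evidence of self-aggregation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendReport:
    """Whether a species' diffusion coefficient falls with concentration."""

    species_id: str
    monotone_decreasing: bool
    violations: tuple[tuple[float, float], ...]
    conclusion: str


def check_concentration_trend(records: list[DiffusionRecord]) -> TrendReport:
    """Check that D is non-increasing with concentration, within sigma.

    A decreasing trend is the qualitative diffusion signature of
    self-aggregation (larger average particles at higher concentration).
    A pair of consecutive concentrations where D *increases* by more than
    the combined stated sigmas is a violation.
    """
    if len(records) < 2:
        raise ValueError("at least 2 records are required for a trend check")
    species = {r.species_id for r in records}
    if len(species) != 1:
        raise ValueError(f"records mix species: {sorted(species)}")
    ordered = sorted(records, key=lambda r: r.conc)
    violations = []
    for a, b in zip(ordered, ordered[1:]):
        if b.d_coef > a.d_coef + (a.d_sigma + b.d_sigma):
            violations.append((a.conc, b.conc))
    monotone = not violations
    strictly_flat = all(b.d_coef == a.d_coef
                        for a, b in zip(ordered, ordered[1:]))
    if strictly_flat:
        conclusion = "no concentration trend; no diffusion evidence of aggregation"
    elif monotone:
        conclusion = ("diffusion coefficient decreases with concentration "
                      "(within sigma): consistent with self-aggregation")
    else:
        conclusion = ("diffusion coefficient increases with concentration "
                      "beyond sigma: inconsistent with self-aggregation")
    return TrendReport(
        species_id=records[0].species_id,
        monotone_decreasing=monotone and not strictly_flat,
        violations=tuple(violations),
        conclusion=conclusion,
    )


# ---------------------------------------------------------------------------
# building experiments from long diffusion tables
# ---------------------------------------------------------------------------

def select_free_ligand_record(records: list[DiffusionRecord]) -> DiffusionRecord:
    """Pick the most dilute measurement as the free-ligand coefficient.

    Self-association depresses the apparent ligand coefficient at working
    concentrations, so the free coefficient must come from the lowest
    concentration available, never the working one.
    """
    if not records:
        raise ValueError("no ligand records to select from")
    return min(records, key=lambda r: r.conc)


def experiment_from_records(records: list[DiffusionRecord],
                            c_ligand: float, c_dna: float) -> BindingExperiment:
    """Assemble a :class:`BindingExperiment` from a long diffusion table.

    The table must contain species ids ``ligand_obs``, ``dna_obs``,
    ``ligand_free`` and ``dna_free``; if several ``ligand_free`` rows are
    present the most dilute one is used.
    """
    by_species: dict[str, list[DiffusionRecord]] = {}
    for r in records:
        by_species.setdefault(r.species_id, []).append(r)
    required = ("ligand_obs", "dna_obs", "ligand_free", "dna_free")
    missing = [s for s in required if s not in by_species]
    if missing:
        raise ValueError(f"diffusion table lacks species rows: {missing}")
    for s in ("ligand_obs", "dna_obs", "dna_free"):
        if len(by_species[s]) != 1:
            raise ValueError(f"expected exactly one {s!r} row")
    lig_free = select_free_ligand_record(by_species["ligand_free"])
    lig_obs = by_species["ligand_obs"][0]
    dna_obs = by_species["dna_obs"][0]
    dna_free = by_species["dna_free"][0]
    return BindingExperiment(
        c_ligand=c_ligand,
        c_dna=c_dna,
        d_obs_ligand=lig_obs.d_coef,
        d_obs_dna=dna_obs.d_coef,
        d_free_ligand=lig_free.d_coef,
        d_free_dna=dna_free.d_coef,
        sigma_d={
            "d_obs_ligand": lig_obs.d_sigma,
            "d_obs_dna": dna_obs.d_sigma,
            "d_free_ligand": lig_free.d_sigma,
            "d_free_dna": dna_free.d_sigma,
        },
    )
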