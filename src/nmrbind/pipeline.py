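"""Orchestration: run all analysis stages and emit a combined report.

A :class:`RunConfig` names the input tables per compound plus the analysis
options (exclusions, CSP threshold, nick map).  :func:`run_pipeline`
executes the self-association, binding and CSP stages for every compound
present, records any stage error without aborting the remaining stages,
and returns a self-describing report: every numeric block carries its
units, the sign conventions, and the list of model assumptions that
produced it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import csp as csp_mod
from . import dosy as dosy_mod
from . import selfassoc
from .tables import NickMap, read_diffusion_table, read_dilution_table, read_shift_table

logger = logging.getLogger(__name__)

__all__ = ["CompoundInputs", "RunConfig", "run_pipeline", "packaged_config",
           "report_to_text"]

CONVENTIONS = {
    "concentration_unit": "mM",
    "dilution_shift_unit": "Hz",
    "csp_shift_unit": "ppm",
    "diffusion_unit": "1e-10 m^2 s^-1",
    "ka_unit": "mM^-1",
    "delta_delta_sign": "delta_free - delta_complex; positive = low-frequency shift",
}


@dataclass
class CompoundInputs:
    """Input tables for one compound; any stage may be omitted (path None)."""

    compound_id: str
    dilution: str | None = None
    exclude: tuple[str, ...] = ()
    dosy: str | None = None
    c_ligand: float | None = None
    c_dna: float | None = None
    shifts_ligand: str | None = None
    shifts_dna: str | None = None


@dataclass
class RunConfig:
    """Full pipeline configuration (JSON-serializable)."""

    compounds: list[CompoundInputs]
    nick_map: str | None = None
    threshold: float = csp_mod.DEFAULT_THRESHOLD_PPM
    rounding_slack: bool = True
    offset_free: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        compounds = [CompoundInputs(**{**c, "exclude": tuple(c.get("exclude", ()))})
                     for c in raw.pop("compounds", [])]
        if not compounds:
            raise ValueError("config names no compounds")
        return cls(compounds=compounds, **raw)


def packaged_config() -> RunConfig:
    """A config pointing at the packaged study tables for both diastereomers."""
    from .datasets import EXCLUDED_PROTONS, STUDY_CONCENTRATION_MM, data_path

    compounds = []
    for cid in ("1", "2"):
        compounds.append(CompoundInputs(
            compound_id=cid,
            dilution=str(data_path(f"dilution_compound{cid}.csv")),
            exclude=EXCLUDED_PROTONS[cid],
            dosy=str(data_path(f"dosy_compound{cid}.csv")),
            c_ligand=STUDY_CONCENTRATION_MM,
            c_dna=STUDY_CONCENTRATION_MM,
            shifts_ligand=str(data_path(f"shifts_ligand{cid}.csv")),
            shifts_dna=str(data_path(f"shifts_dna{cid}.csv")),
        ))
    return RunConfig(compounds=compounds, nick_map=str(data_path("nick_map.json")))


def _selfassoc_stage(inputs: CompoundInputs, offset_free: bool) -> dict:
    series = read_dilution_table(inputs.dilution, compound_id=inputs.compound_id)
    fits = [selfassoc.fit_isodesmic(s, offset_free=offset_free) for s in series]
    summary = selfassoc.summarize_ka(fits, excluded=inputs.exclude,
                                     compound_id=inputs.compound_id)
    summary_all = selfassoc.summarize_ka(fits, excluded=(),
                                         compound_id=inputs.compound_id)
    logger.info("selfassoc[%s]: mean Ka %.2f +/- %.2f mM^-1 (%d fits, excluded %s)",
                inputs.compound_id, summary.mean_ka, summary.sd_ka,
                len(fits), list(inputs.exclude) or "none")
    return {
        "model": "isodesmic (equal-K) self-association",
        "offset_free": offset_free,
        "concentration_grid_mM": list(series[0].concentrations) if series else [],
        "fits": [dataclasses.asdict(f) for f in fits],
        "mean_ka": summary_all.mean_ka,
        "sd_ka": summary_all.sd_ka,
        "mean_ka_excluding": summary.mean_ka,
        "sd_ka_excluding": summary.sd_ka,
        "excluded": list(inputs.exclude),
    }


def _binding_stage(inputs: CompoundInputs) -> dict:
    records = read_diffusion_table(inputs.dosy)
    exp = dosy_mod.experiment_from_records(records, c_ligand=inputs.c_ligand,
                                           c_dna=inputs.c_dna)
    result = dosy_mod.analyze_binding(exp)
    logger.info("binding[%s]: Ka %.1f +/- %.1f mM^-1, bound fraction %.2f",
                inputs.compound_id, result.ka, result.ka_sigma, result.mf_bound)
    return {
        "inputs": dataclasses.asdict(exp),
        "assumptions": list(result.assumptions),
        "mf_free_ligand": result.mf_free_ligand,
        "mf_bound": result.mf_bound,
        "complex_conc_mM": result.complex_conc,
        "ka": result.ka,
        "ka_sigma": result.ka_sigma,
        "no_binding": result.no_binding,
    }


def _csp_stage(inputs: CompoundInputs, nick: NickMap | None,
               threshold: float, rounding_slack: bool) -> dict:
    out: dict = {"threshold_ppm": threshold, "rounding_slack": rounding_slack}
    for kind, path in (("ligand", inputs.shifts_ligand), ("dna", inputs.shifts_dna)):
        if path is None:
            continue
        records = read_shift_table(path)
        flagged = csp_mod.flag_significant(csp_mod.compute_csp(records),
                                           threshold=threshold,
                                           rounding_slack=rounding_slack)
        out[kind] = {
            "records": [
                {"unit": r.unit_label, "class": r.proton_class,
                 "delta_delta_ppm": r.delta_delta_rounded, "flagged": r.flagged}
                for r in flagged
            ],
            "n_flagged": sum(r.flagged for r in flagged),
        }
        if kind == "dna" and nick is not None:
            summary = csp_mod.localize_to_nick(flagged, nick)
            out["localization"] = dataclasses.asdict(summary)
            logger.info("csp[%s]: %d/%d flagged DNA protons nick-adjacent",
                        inputs.compound_id, summary.n_flagged_near_nick,
                        summary.n_flagged)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; never abort on a single stage error.

    Returns the report dict; ``report["n_errors"]`` counts failed stages and
    each failure is recorded under the compound it belongs to.
    """
    nick = NickMap.from_json(config.nick_map) if config.nick_map else None
    report: dict = {
        "conventions": CONVENTIONS,
        "assumptions": list(dosy_mod.MODEL_ASSUMPTIONS)
        + ["isodesmic (equal-K) stacking for self-association"],
        "seed": config.seed,
        "compounds": {},
    }
    n_errors = 0
    for inputs in config.compounds:
        block: dict = {}
        stages = (
            ("self_association", lambda i=inputs: _selfassoc_stage(i, config.offset_free),
             inputs.dilution is not None),
            ("binding", lambda i=inputs: _binding_stage(i),
             inputs.dosy is not None),
            ("csp", lambda i=inputs: _csp_stage(i, nick, config.threshold,
                                                config.rounding_slack),
             inputs.shifts_ligand is not None or inputs.shifts_dna is not None),
        )
        for name, stage, enabled in stages:
            if not enabled:
                continue
            try:
                block[name] = stage()
            except Exception as exc:  # keep running the remaining stages
                logger.error("%s stage failed for compound %s: %s",
                             name, inputs.compound_id, exc)
                block[name] = {"error": str(exc)}
                n_errors += 1
        report["compounds"][inputs.compound_id] = block
    report["n_errors"] = n_errors
    return report


def report_to_text(report: dict) -> str:
    """Human-readable summary of a pipeline report."""
    lines = ["nmrbind pipeline report", "=" * 23, ""]
    lines.append("Conventions: " + "; ".join(f"{k}={v}" for k, v in
                                             report["conventions"].items()))
    lines.append("Assumptions: " + "; ".join(report["assumptions"]))
    for cid, block in report["compounds"].items():
        lines.append("")
        lines.append(f"Compound {cid}")
        lines.append("-" * (9 + len(cid)))
        sa = block.get("self_association")
        if sa:
            if "error" in sa:
                lines.append(f"  self-association: ERROR {sa['error']}")
            else:
                lines.append(
                    f"  self-association Ka = {sa['mean_ka']:.1f} "
                    f"+/- {sa['sd_ka']:.1f} mM^-1 "
                    f"({sa['mean_ka_excluding']:.1f} +/- {sa['sd_ka_excluding']:.1f} "
                    f"without {', '.join(sa['excluded']) or 'exclusions'})"
                )
        b = block.get("binding")
        if b:
            if "error" in b:
                lines.append(f"  binding: ERROR {b['error']}")
            else:
                lines.append(
                    f"  binding Ka = {b['ka']:.0f} +/- {b['ka_sigma']:.0f} mM^-1, "
                    f"bound fraction {b['mf_bound']:.2f}, "
                    f"[complex] = {b['complex_conc_mM']:.2f} mM"
                )
        c = block.get("csp")
        if c:
            if "error" in c:
                lines.append(f"  csp: ERROR {c['error']}")
            else:
                loc = c.get("localization")
                if loc:
                    lines.append(
                        f"  csp: flagged DNA units {', '.join(loc['flagged_units'])}; "
                        f"{loc['conclusion']}"
                    )
    if report.get("n_errors"):
        lines.append("")
        lines.append(f"{report['n_errors']} stage(s) failed")
    return "\n".join(lines) + "\n"
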