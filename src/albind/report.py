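"""End-to-end orchestration: run every applicable stage and build a summary.

The central artefact is a per-temperature table in the shape conventionally
printed for albumin-binding studies —

    T (K) | Ksv | Kq | n | Ka | dG | dH | dS

— plus mechanism / force / binding-site verdicts with their evidence, all in
a JSON-serializable structure whose numeric entries carry explicit units.
"""

from __future__ import annotations

import json
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

from . import binding_thermo, displacement as disp_mod, lifetime as lt_mod, quenching
from .io import AnalysisConfig, RunRecord
from .preprocess import TitrationSeries
from .structure import CDSample, SynchronousSeries, extract_3d_peaks, sync_peak_shift


def _round_trip_safe(obj):
    """Recursively convert numpy scalars/arrays and enums to plain JSON types."""
    if isinstance(obj, dict):
        return {str(k): _round_trip_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_trip_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_round_trip_safe(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str, bool)):
        return obj.value  # enums
    return obj


def run_report(
    config: AnalysisConfig,
    titrations: Sequence[TitrationSeries],
    decays: Optional[Sequence[lt_mod.DecayCurve]] = None,
    displacement_series: Optional[Mapping[str, disp_mod.DisplacementSeries]] = None,
    cd_ellipticities: Optional[Mapping[str, float]] = None,
    synchronous: Optional[Mapping[float, SynchronousSeries]] = None,
    grids3d: Optional[Mapping[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]] = None,
    record: Optional[RunRecord] = None,
) -> dict:
    """Run preprocess -> quenching -> binding/thermo (and optional stages).

    ``decays``, if given, must be ordered by quencher concentration; the first
    curve is the free protein.  ``cd_ellipticities`` maps sample labels to
    222 nm ellipticities in mdeg.  ``grids3d`` maps sample labels to
    (ex, em, grid) triples; intensity changes are reported relative to the
    first grid.
    """
    if not titrations:
        raise ValueError("at least one titration series is required")
    if record is None:
        record = RunRecord(config=config.model_dump())

    titrations = sorted(titrations, key=lambda s: s.temperature)
    if not all(s.is_corrected for s in titrations):
        record.warn("preprocess", "inner-filter correction skipped (no absorbance data)")

    # -- lifetimes (needed as mechanism evidence, so fitted first) ----------
    lifetime_section: dict = {"available": False}
    lifetime_change_fraction = None
    if decays:
        fits = [
            lt_mod.fit_decay(
                c,
                chi2_threshold=config.chi2_threshold,
                seed=config.seed,
            )
            for c in decays
        ]
        for curve, fit in zip(decays, fits):
            if fit.poor_fit:
                record.warn(
                    "lifetime",
                    f"reduced chi^2 {fit.chi2_reduced:.3f} above "
                    f"{config.chi2_threshold} at [Q] = {curve.quencher_conc:g}",
                )
        if len(fits) >= 2:
            lifetime_change_fraction = lt_mod.lifetime_change(
                fits[0].tau_avg, fits[-1].tau_avg
            )
        lifetime_section = {
            "available": True,
            "fits": [
                {
                    "quencher_conc_M": curve.quencher_conc,
                    "lifetimes_ns": list(fit.lifetimes),
                    "amplitudes": list(fit.amplitudes),
                    "tau_avg_ns": fit.tau_avg,
                    "chi2_reduced": fit.chi2_reduced,
                    "n_components": fit.n_components,
                }
                for curve, fit in zip(decays, fits)
            ],
            "lifetime_change_fraction": lifetime_change_fraction,
        }

    # -- quenching ----------------------------------------------------------
    qfits = [quenching.fit_stern_volmer(s, tau0=config.tau0) for s in titrations]
    for qf in qfits:
        for note in qf.warnings:
            record.warn("quenching", f"T = {qf.temperature:g} K: {note}")
    try:
        verdict = quenching.classify_mechanism(
            qfits,
            lifetime_change_fraction,
            kq_ceiling=config.kq_ceiling,
            lifetime_threshold=config.lifetime_invariance_threshold,
        )
        mechanism = {
            "label": verdict.label.value,
            "evidence": [
                {"rule": o.rule, "vote": o.vote.value, "detail": o.detail}
                for o in verdict.evidence
            ],
        }
    except quenching.InsufficientEvidenceError as exc:  # type: ignore[attr-defined]
        mechanism = {"label": None, "error": str(exc)}

    # -- binding + thermodynamics -------------------------------------------
    bfits = [binding_thermo.fit_double_log(s) for s in titrations]
    thermo = None
    if len({b.temperature for b in bfits}) >= 2:
        thermo = binding_thermo.analyze_thermodynamics(
            bfits, electrostatic_dH_ceiling=config.electrostatic_dH_ceiling
        )
    else:
        record.warn("binding_thermo", "single temperature: Van 't Hoff analysis skipped")

    table = []
    for qf, bf in zip(qfits, bfits):
        row = {
            "T_K": qf.temperature,
            "Ksv_L_per_mol": qf.Ksv,
            "Kq_L_per_mol_s": qf.Kq,
            "sv_intercept": qf.intercept,
            "sv_r_squared": qf.r_squared,
            "n_sites": bf.n_sites,
            "Ka_L_per_mol": bf.Ka,
            "dlog_r_squared": bf.r_squared,
        }
        if thermo is not None:
            row["delta_G_J_per_mol"] = thermo.delta_G_by_T[qf.temperature]
        table.append(row)

    result = {
        "units": {
            "T": "K", "Ksv": "L/mol", "Kq": "L/mol/s", "Ka": "L/mol",
            "delta_G": "J/mol", "delta_H": "J/mol", "delta_S": "J/mol/K",
            "tau": "ns", "wavelength": "nm", "ellipticity": "mdeg",
            "MRE": "deg*cm^2/dmol",
        },
        "table": table,
        "mechanism": mechanism,
        "thermodynamics": {
            "available": thermo is not None,
        },
        "lifetime": lifetime_section,
        "run_record": record.as_dict(),
    }
    if thermo is not None:
        result["thermodynamics"].update(
            {
                "delta_H_J_per_mol": thermo.delta_H,
                "delta_S_J_per_mol_K": thermo.delta_S,
                "vant_hoff_r_squared": thermo.vant_hoff_r_squared,
                "delta_G_by_T_J_per_mol": thermo.delta_G_by_T,
                "delta_G_rt_lnka_by_T_J_per_mol": thermo.delta_G_rt_lnka_by_T,
                "force_label": thermo.force_label.value,
            }
        )

    # -- displacement ---------------------------------------------------------
    if displacement_series:
        assignment, evidence = disp_mod.assign_site(
            displacement_series, drop_threshold=config.displacement_threshold
        )
        result["displacement"] = {
            "available": True,
            "assignment": assignment.value,
            "evidence": [
                {
                    "marker": e.marker_name,
                    "site": e.site.value,
                    "drop_points": e.drop_points,
                    "competes": e.competes,
                }
                for e in evidence
            ],
            "index_percent": {
                name: disp_mod.displacement_index(s).tolist()
                for name, s in displacement_series.items()
            },
        }
    else:
        result["displacement"] = {"available": False}

    # -- CD ------------------------------------------------------------------
    if cd_ellipticities:
        samples = {}
        for label, theta in cd_ellipticities.items():
            cd = CDSample(
                ellipticity_222=theta,
                protein_conc=config.protein_conc,
                n_residues=config.n_residues,
                path_length=config.path_length,
            )
            if cd.helix_fraction.clamped:
                record.warn("structure", f"CD sample {label!r}: helix fraction clamped")
            samples[label] = {
                "ellipticity_222_mdeg": theta,
                "mre_222": cd.mre_222,
                "helix_percent": cd.helix_fraction.value,
                "clamped": cd.helix_fraction.clamped,
            }
        result["cd"] = {"available": True, "samples": samples}
        labels = list(cd_ellipticities)
        if len(labels) >= 2:
            result["cd"]["helix_change_points"] = (
                samples[labels[-1]]["helix_percent"] - samples[labels[0]]["helix_percent"]
            )
    else:
        result["cd"] = {"available": False}

    # -- synchronous fluorescence ---------------------------------------------
    if synchronous:
        sync = {}
        for dl, series in synchronous.items():
            shift, change = sync_peak_shift(series)
            sync["%g" % dl] = {"peak_shift_nm": shift, "intensity_change_fraction": change}
        result["synchronous"] = {"available": True, "by_delta_lambda": sync}
    else:
        result["synchronous"] = {"available": False}

    # -- 3D fluorescence --------------------------------------------------------
    if grids3d:
        sections = {}
        reference = None
        for label, (ex, em, grid) in grids3d.items():
            peaks = extract_3d_peaks(ex, em, grid, ridge_tolerance=config.ridge_tolerance)
            entry = {
                p.label.value: {
                    "ex_nm": p.ex_wavelength,
                    "em_nm": p.em_wavelength,
                    "stokes_shift_nm": p.stokes_shift,
                    "intensity": p.intensity,
                }
                for p in peaks
            }
            if reference is None:
                reference = entry
            else:
                for name in ("peak_I", "peak_II"):
                    if name in entry and name in reference:
                        entry[name]["intensity_change_percent"] = (
                            (entry[name]["intensity"] - reference[name]["intensity"])
                            / reference[name]["intensity"] * 100.0
                        )
            sections[label] = entry
        result["fluorescence_3d"] = {"available": True, "samples": sections}
    else:
        result["fluorescence_3d"] = {"available": False}

    return _round_trip_safe(result)


def to_json(result: dict) -> str:
    """Deterministic JSON rendering (sorted keys, no timestamps)."""
    return json.dumps(result, indent=2, sort_keys=True)


def format_table(result: dict) -> str:
    """Human-readable per-temperature summary table."""
    thermo = result.get("thermodynamics", {})
    lines = [
        "T (K)   Ksv (1e4/M)  Kq (1e12/M/s)  n      Ka (1e5/M)  dG (kJ/mol)  dH (kJ/mol)  dS (J/mol/K)"
    ]
    for i, row in enumerate(result["table"]):
        dg = row.get("delta_G_J_per_mol")
        lines.append(
            "%-7g %-12.3f %-14.3f %-6.3f %-11.3f %-12s %-12s %-12s"
            % (
                row["T_K"],
                row["Ksv_L_per_mol"] / 1e4,
                row["Kq_L_per_mol_s"] / 1e12,
                row["n_sites"],
                row["Ka_L_per_mol"] / 1e5,
                "%.2f" % (dg / 1e3) if dg is not None else "-",
                "%.2f" % (thermo["delta_H_J_per_mol"] / 1e3) if i == 0 and thermo.get("available") else "",
                "%.2f" % thermo["delta_S_J_per_mol_K"] if i == 0 and thermo.get("available") else "",
            )
        )
    if result.get("mechanism", {}).get("label"):
        lines.append("quenching mechanism: %s" % result["mechanism"]["label"])
    if thermo.get("available"):
        lines.append("dominant forces: %s" % thermo["force_label"])
    if result.get("displacement", {}).get("available"):
        lines.append("binding site: %s" % result["displacement"]["assignment"])
    return "\n".join(lines)
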