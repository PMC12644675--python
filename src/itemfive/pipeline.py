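"""End-to-end orchestration: manifest + config -> tables and plots.

A run reads per-voltage-step peak lists listed in a manifest, extracts and
normalizes the monitored ions, assembles replicate-averaged survival-yield
curves, fits Boltzmann sigmoids, and derives the ambient-temperature
kinetic/thermodynamic quantities per analyte.  Every intermediate table is
persisted so the final numbers can be reconstructed from the bundle alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import spectra as sp
from . import survival as sv
from . import thermo as th
from .peptide import parse_sequence, oligomer_mz

log = logging.getLogger(__name__)

__all__ = ["load_config", "run_item5"]

DEFAULT_CONFIG = {
    "extraction": {"tolerance": 0.5, "noise_floor": 0.0},
    "fit": {"pin_plateaus": False, "weighted": False,
            "tangent_points": 5, "sy_bounds": [10.0, 90.0]},
    "collision": {"gas": "argon", "T_amb": 298.15, "charge": 5,
                  "dof_factor": 1.5, "residence_factor": 1.0},
    "educt": {"species": "trimer", "n_mer": 3, "charge": 5},
    "products": [{"species": "dimer", "n_mer": 2, "charge": 3},
                 {"species": "monomer", "n_mer": 1, "charge": 2}],
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    if "analytes" not in config:
        raise ValueError("config must define 'analytes' (name + sequence)")
    return config


def _targets_for(analyte_cfg: dict, config: dict) -> list[sp.TargetIon]:
    seq = parse_sequence(analyte_cfg["sequence"])
    tolerance = config["extraction"]["tolerance"]
    educt = analyte_cfg.get("educt", config["educt"])
    products = analyte_cfg.get("products", config["products"])
    targets = [sp.TargetIon(educt["species"],
                            oligomer_mz(seq, educt["n_mer"], educt["charge"]),
                            tolerance, "educt")]
    for prod in products:
        targets.append(sp.TargetIon(
            prod["species"], oligomer_mz(seq, prod["n_mer"], prod["charge"]),
            tolerance, "product"))
    return targets


def _conditions_for(analyte_cfg: dict, config: dict) -> th.CollisionConditions:
    seq = parse_sequence(analyte_cfg["sequence"])
    coll = config["collision"]
    educt = analyte_cfg.get("educt", config["educt"])
    return th.CollisionConditions(
        charge=educt["charge"],
        ion_mass=educt["n_mer"] * seq.monoisotopic_mass(),
        gas=coll.get("gas"),
        gas_mass=coll.get("gas_mass"),
        T_amb=coll["T_amb"],
        dof_factor=coll["dof_factor"],
        residence_factor=coll["residence_factor"],
    )


def run_item5(config: dict, manifest: pd.DataFrame | str | Path,
              out_dir: str | Path, make_plots: bool = True) -> dict:
    """Run the full dissociation analysis and persist the artifact bundle.

    ``manifest`` needs the columns path, analyte, delta_cv, replicate; paths
    are resolved relative to the manifest file when one is given.  Returns a
    dict with the per-analyte fits and ambient-temperature results.
    """
    base = Path(".")
    if not isinstance(manifest, pd.DataFrame):
        manifest_path = Path(manifest)
        base = manifest_path.parent
        manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"path", "analyte", "delta_cv", "replicate"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    analytes = {a["name"]: a for a in config["analytes"]}
    noise_floor = config["extraction"]["noise_floor"]

    tidy_rows = []
    normalized: dict[str, list[sp.NormalizedIntensities]] = {}
    for row in manifest.itertuples(index=False):
        if row.analyte not in analytes:
            raise ValueError(f"manifest analyte {row.analyte!r} not in config")
        path = base / row.path
        if not path.exists():
            raise FileNotFoundError(
                f"stage extract: missing peak list for analyte={row.analyte}, "
                f"dCV={row.delta_cv}, replicate={row.replicate}: {path}")
        spectrum = sp.read_peaklist(path, delta_cv=float(row.delta_cv),
                                    replicate_id=str(row.replicate))
        if noise_floor:
            spectrum = sp.denoise_baseline(spectrum, noise_floor)
        targets = _targets_for(analytes[row.analyte], config)
        norm = sp.extract_normalized(spectrum, targets)
        normalized.setdefault(row.analyte, []).append(norm)
        for t in targets:
            tidy_rows.append(dict(
                analyte=row.analyte, replicate=str(row.replicate),
                delta_cv=float(row.delta_cv), species=t.species,
                raw_intensity=norm.raw[t.species],
                percent=norm.fractions[t.species]))
    tidy = pd.DataFrame(tidy_rows).sort_values(
        ["analyte", "replicate", "delta_cv", "species"])
    tidy.to_csv(out_dir / "intensities.tsv", sep="\t", index=False)

    fit_cfg = config["fit"]
    curves, fits = {}, {}
    for name, items in normalized.items():
        educt_label = analytes[name].get("educt", config["educt"])["species"]
        curve = sv.assemble_curve(items, educt_label=educt_label, analyte=name)
        curves[name] = curve
        fits[name] = sv.fit_boltzmann(curve,
                                      pin_plateaus=fit_cfg["pin_plateaus"],
                                      weighted=fit_cfg["weighted"])

    # optional pre-pass: solve the instrument constants from a reference
    # analyte's published (dH#, T dS#) pair, then share them with all analytes
    calib = config["collision"].pop("calibration", None)
    if calib:
        ref = calib.get("analyte")
        if ref not in fits:
            raise ValueError(f"calibration analyte {ref!r} not in manifest")
        cond = th.calibrate_conditions(
            fits[ref], _conditions_for(analytes[ref], config),
            calib["dh"], calib["tds"],
            n_points=fit_cfg["tangent_points"],
            sy_bounds=tuple(fit_cfg["sy_bounds"]))
        config["collision"]["dof_factor"] = cond.dof_factor
        config["collision"]["residence_factor"] = cond.residence_factor

    fit_rows, thermo_rows, point_rows = [], [], []
    results: dict[str, dict] = {}
    for name in normalized:
        fit = fits[name]
        cond = _conditions_for(analytes[name], config)
        analysis = th.analyze_boltzmann_fit(
            fit, cond, n_points=fit_cfg["tangent_points"],
            sy_bounds=tuple(fit_cfg["sy_bounds"]))
        res = analysis.result
        fit_rows.append(dict(analyte=name, a1=fit.a1, a2=fit.a2, x0=fit.x0,
                             dx=fit.dx, r_squared=fit.r_squared))
        thermo_rows.append(dict(
            analyte=name, k_m0g=res.k_m0g, kd_m0g=res.kd_m0g,
            dg_m0g=res.dg_m0g, dh_m0g=res.dh_m0g, tds_m0g=res.tds_m0g,
            arrhenius_r2=analysis.arrhenius.r_squared,
            ellingham_r2=analysis.ellingham.r_squared))
        for dcv, sy, T, k, dg in analysis.points:
            point_rows.append(dict(analyte=name, delta_cv=dcv, sy_percent=sy,
                                   T_coll=T, k_sharp=k, dg_kj_mol=dg))
        results[name] = dict(fit=fit, analysis=analysis, conditions=cond)

    pd.DataFrame(fit_rows).to_csv(out_dir / "boltzmann_fits.tsv", sep="\t",
                                  index=False)
    pd.DataFrame(thermo_rows).to_csv(out_dir / "thermokinetics.tsv", sep="\t",
                                     index=False)
    pd.DataFrame(point_rows).to_csv(out_dir / "tangent_points.tsv", sep="\t",
                                    index=False)
    resolved = dict(config)
    resolved["collision"] = dict(config["collision"])
    (out_dir / "resolved_config.yaml").write_text(yaml.safe_dump(resolved))

    if make_plots:
        _plot_bundle(curves, results, out_dir)
    log.info("run complete: %d analyte(s) -> %s", len(results), out_dir)
    return results


def _plot_bundle(curves, results, out_dir: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    grid = np.linspace(0, 50, 300)
    for name, curve in curves.items():
        fit = results[name]["fit"]
        pts = ax.errorbar(curve.delta_cv, curve.sy_mean, yerr=curve.sy_sd,
                          fmt="o", ms=4, capsize=2, label=name)
        ax.plot(grid, fit(grid), "-", color=pts[0].get_color(), lw=1)
    ax.set_xlabel("collision voltage difference (V)")
    ax.set_ylabel("normalized educt intensity (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / "survival_yield.png", dpi=150)
    plt.close(fig)

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    for name, bundle in results.items():
        pts = bundle["analysis"].points
        T, k, dg = pts[:, 2], pts[:, 3], pts[:, 4]
        ax1.plot(1.0 / T, np.log(k), "o-", ms=4, label=name)
        ax2.plot(T, dg, "o-", ms=4, label=name)
    ax1.set_xlabel("1 / T_coll (1/K)")
    ax1.set_ylabel("ln k#")
    ax2.set_xlabel("T_coll (K)")
    ax2.set_ylabel("dG# (kJ/mol)")
    ax1.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_dir / "arrhenius_ellingham.png", dpi=150)
    plt.close(fig)
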