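"""Synthetic data generators with machine-readable ground truth.

Three generators emulate the inputs of a trimer-dissociation study:

* :func:`generate_dissociation_series` -- per-voltage-step peak lists whose
  educt fraction follows a known Boltzmann decay with complementary product
  rise, Gaussian peak shapes at sequence-derived m/z positions, and seeded
  replicate noise;
* :func:`generate_calibrant_table` -- a mobility calibrant table whose
  corrected drift-time/cross-section relation is a known power law;
* :func:`generate_symmetric_trimer` -- a three-fold symmetric coordinate
  model whose interchain C-alpha distances are known in closed form.

Every generator returns (or writes alongside its output) a truth manifest
sufficient to score downstream estimates without re-deriving parameters.

The defaults encode the reference study conditions: an 11-step voltage
schedule (0-50 V), two independent replicates, a 27-residue trimer-forming
peptide observed as trimer 5+ / dimer 3+ / monomer 2+, a midpoint near
13.5 V with a 2 V transition width, and 2 % replicate noise on the
normalized fractions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import biotite.structure as struc

from .ccs import CalibrantEntry
from .peptide import parse_sequence, oligomer_mz
from .spectra import Spectrum
from .survival import boltzmann
from .structure import StructureModel

__all__ = [
    "REFERENCE_SEQUENCE",
    "DEFAULT_SCHEDULE",
    "DissociationSeriesSpec",
    "generate_dissociation_series",
    "generate_calibrant_table",
    "generate_symmetric_trimer",
]

#: 27-residue trimerization-domain peptide used as the reference analyte.
REFERENCE_SEQUENCE = "H-GYIPEAPRDGQAYVRKDGEWVLLSTFL-OH"

#: Stepwise collision-voltage schedule of the emulated experiment (V).
DEFAULT_SCHEDULE = (0.0, 2.0, 5.0, 7.0, 10.0, 12.0, 15.0, 20.0, 30.0, 40.0, 50.0)

#: Monitored species as (label, n_mer, charge, role).
DEFAULT_SPECIES = (
    ("trimer", 3, 5, "educt"),
    ("dimer", 2, 3, "product"),
    ("monomer", 1, 2, "product"),
)


@dataclass
class DissociationSeriesSpec:
    """Fully specified synthetic dissociation experiment."""

    sequence: str = REFERENCE_SEQUENCE
    analyte: str = "ref_trimer"
    a1: float = 100.0
    a2: float = 0.0
    x0: float = 13.5
    dx: float = 2.0
    dcv_schedule: tuple = DEFAULT_SCHEDULE
    n_replicates: int = 2
    noise_sd: float = 2.0  # percent, on normalized fractions
    peak_width: float = 0.08  # Gaussian sigma, u/charge
    species: tuple = DEFAULT_SPECIES
    seed: int = 0

    def truth(self) -> dict:
        return asdict(self)


def _gaussian_peaks(center: float, area: float, sigma: float,
                    half_width: float = 2.0, step: float = 0.02):
    grid = np.arange(center - half_width, center + half_width + step / 2, step)
    profile = area * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    return grid, profile


def _dimer_share(educt_truth_percent: float) -> float:
    # phenomenological split of the dissociated signal: dimers peak
    # mid-transition, monomers dominate at high collision energy
    return 0.15 + 0.35 * educt_truth_percent / 100.0


def generate_dissociation_series(
    spec: DissociationSeriesSpec,
    out_dir: str | Path | None = None,
) -> tuple[list[Spectrum], dict]:
    """Generate peak lists for every (replicate, voltage step) of a spec.

    Returns the spectra and the truth manifest.  When ``out_dir`` is given,
    each spectrum is also written as a two-column text peak list next to a
    ``manifest.tsv`` (path, analyte, delta_cv, replicate) and ``truth.json``.
    Identical seeds produce byte-identical outputs.
    """
    seq = parse_sequence(spec.sequence)
    targets = {label: oligomer_mz(seq, n_mer, z)
               for label, n_mer, z, _ in spec.species}
    rng = np.random.default_rng(spec.seed)
    spectra: list[Spectrum] = []
    clipped = 0
    n_total = 0
    for rep in range(1, spec.n_replicates + 1):
        rep_id = f"rep{rep}"
        for dcv in spec.dcv_schedule:
            truth_educt = float(boltzmann(dcv, spec.a1, spec.a2, spec.x0, spec.dx))
            educt = truth_educt + rng.normal(0.0, spec.noise_sd)
            educt_clipped = float(np.clip(educt, 0.0, 100.0))
            if educt_clipped != educt:
                clipped += 1
            n_total += 1
            dissociated = 100.0 - educt_clipped
            w = _dimer_share(truth_educt)
            fractions = {
                "trimer": educt_clipped,
                "dimer": dissociated * w,
                "monomer": dissociated * (1.0 - w),
            }
            mz_all, int_all = [], []
            for label, _, _, _ in spec.species:
                grid, profile = _gaussian_peaks(targets[label],
                                                1000.0 * fractions[label],
                                                spec.peak_width)
                mz_all.append(grid)
                int_all.append(profile)
            spectra.append(Spectrum(np.concatenate(mz_all),
                                    np.concatenate(int_all),
                                    delta_cv=float(dcv), replicate_id=rep_id))
    if clipped == n_total and spec.noise_sd > 0:
        raise ValueError("noise so large that every point clipped to [0, 100]")

    truth = spec.truth()
    truth["target_mz"] = targets
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = ["path\tanalyte\tdelta_cv\treplicate"]
        for s in spectra:
            fname = f"{spec.analyte}_{s.replicate_id}_dcv{s.delta_cv:g}.txt"
            with (out_dir / fname).open("w") as fh:
                for mz, inten in zip(s.mz, s.intensity):
                    fh.write(f"{mz:.4f}\t{inten:.6f}\n")
            rows.append(f"{fname}\t{spec.analyte}\t{s.delta_cv:g}\t{s.replicate_id}")
        (out_dir / "manifest.tsv").write_text("\n".join(rows) + "\n")
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return spectra, truth


def generate_calibrant_table(
    truth_a: float = 400.0,
    truth_b: float = 0.55,
    n_calibrants: int = 8,
    noise: float = 0.0,
    seed: int = 0,
    drift_time_range: tuple[float, float] = (4.0, 14.0),
    out_path: str | Path | None = None,
) -> tuple[list[CalibrantEntry], dict]:
    """Synthetic mobility calibrant table following CCS' = a * t'^b.

    Drift times are evenly spaced over ``drift_time_range`` (EDC = 0 so the
    corrected and raw drift times coincide); the published-CCS column is
    back-computed from the truth power law with optional relative noise.
    """
    if n_calibrants < 2:
        raise ValueError("need at least 2 calibrants")
    rng = np.random.default_rng(seed)
    t = np.linspace(*drift_time_range, n_calibrants)
    charges = 5 + (np.arange(n_calibrants) % 6) * 2
    masses = np.linspace(8000.0, 67000.0, n_calibrants)
    from .ccs import reduced_mass

    entries = []
    for i in range(n_calibrants):
        ccs_prime = truth_a * t[i] ** truth_b
        if noise > 0:
            ccs_prime *= 1.0 + rng.normal(0.0, noise)
        published = ccs_prime * charges[i] / np.sqrt(reduced_mass(masses[i]))
        entries.append(CalibrantEntry(
            name=f"cal{i + 1}", charge=int(charges[i]),
            neutral_mass=float(masses[i]), published_ccs=float(published),
            drift_time=float(t[i])))
    truth = dict(a=truth_a, b=truth_b, noise=noise, seed=seed,
                 n_calibrants=n_calibrants)
    if out_path is not None:
        out_path = Path(out_path)
        lines = ["name\tcharge\tneutral_mass\tpublished_ccs\tdrift_time"]
        lines += [f"{e.name}\t{e.charge}\t{e.neutral_mass:.1f}"
                  f"\t{e.published_ccs:.4f}\t{e.drift_time:.4f}" for e in entries]
        out_path.write_text("\n".join(lines) + "\n")
        out_path.with_suffix(".truth.json").write_text(
            json.dumps(truth, indent=2) + "\n")
    return entries, truth


def generate_symmetric_trimer(
    n_residues: int = 27,
    ca_distance: float = 4.5,
    rise: float = 1.5,
    twist_deg: float = 10.0,
) -> tuple[StructureModel, dict]:
    """Three-fold symmetric synthetic trimer with closed-form geometry.

    One synthetic backbone (N, CA, C, O per glycine residue) is replicated
    by 120-degree rotations about the z axis.  Every C-alpha sits at radius
    ``ca_distance / sqrt(3)``, so each of the three interchain distances at
    every matched position equals ``ca_distance`` exactly and their sum is
    ``n_residues * 3 * ca_distance``.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    radius = ca_distance / np.sqrt(3.0)
    twist = np.deg2rad(twist_deg)

    def ring_point(r, phi, z):
        return np.array([r * np.cos(phi), r * np.sin(phi), z])

    base = []
    for i in range(n_residues):
        phi = i * twist
        z = i * rise
        base.append(("N", "N", ring_point(max(radius - 0.8, 0.2), phi - 0.25, z)))
        base.append(("CA", "C", ring_point(radius, phi, z)))
        base.append(("C", "C", ring_point(max(radius - 0.4, 0.2), phi + 0.25, z + 0.6)))
        base.append(("O", "O", ring_point(max(radius - 0.2, 0.2), phi + 0.45, z + 1.0)))

    n_atoms_chain = len(base)
    atoms = struc.AtomArray(3 * n_atoms_chain)
    coords = np.empty((3 * n_atoms_chain, 3))
    for c, (chain_id, angle) in enumerate(zip("ABC", (0.0, 2 * np.pi / 3,
                                                      4 * np.pi / 3))):
        rot = np.array([[np.cos(angle), -np.sin(angle), 0.0],
                        [np.sin(angle), np.cos(angle), 0.0],
                        [0.0, 0.0, 1.0]])
        for k, (atom_name, element, xyz) in enumerate(base):
            idx = c * n_atoms_chain + k
            coords[idx] = rot @ xyz
            atoms.chain_id[idx] = chain_id
            atoms.res_id[idx] = k // 4 + 1
            atoms.res_name[idx] = "GLY"
            atoms.atom_name[idx] = atom_name
            atoms.element[idx] = element
            atoms.hetero[idx] = False
    atoms.coord = coords
    model = StructureModel(atoms=atoms, name="synthetic_trimer")
    truth = dict(n_residues=n_residues, ca_distance=ca_distance, rise=rise,
                 twist_deg=twist_deg,
                 ca_distance_sum=n_residues * 3 * ca_distance)
    return model, truth
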