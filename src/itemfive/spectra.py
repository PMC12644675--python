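"""Peak-list ingestion, denoising, target-ion extraction and normalization.

The reference input dialect is a plain-text two-column m/z-intensity list
(whitespace-, tab- or comma-delimited) exported per collision-voltage step.
Target-ion intensities are extracted inside a closed +/- tolerance window
(default 0.5 u/charge) and species intensities are normalized so that the
monitored educt + product signals sum to 100 %.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "TargetIon",
    "NormalizedIntensities",
    "read_peaklist",
    "denoise_baseline",
    "extract_target_intensity",
    "normalize_species",
    "extract_normalized",
    "default_targets",
]


@dataclass
class Spectrum:
    """A centroided peak list at one collision-voltage step."""

    mz: np.ndarray
    intensity: np.ndarray
    delta_cv: float = 0.0
    replicate_id: str = ""

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have matching shapes")
        if self.mz.size and np.any(self.mz <= 0):
            raise ValueError("m/z values must be strictly positive")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return self.mz.size


@dataclass(frozen=True)
class TargetIon:
    """One monitored species: label, extraction window and educt/product role."""

    species: str
    mz: float
    tolerance: float = 0.5
    role: str = "product"

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.role not in ("educt", "product"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class NormalizedIntensities:
    """Species fractions (percent, summing to 100) at one voltage step."""

    delta_cv: float
    fractions: dict[str, float]
    replicate_id: str = ""
    raw: dict[str, float] = field(default_factory=dict)


_SPLIT = re.compile(r"[\s,;]+")


def read_peaklist(path, delta_cv: float = 0.0, replicate_id: str = "") -> Spectrum:
    """Read a two-column text peak list into a sorted :class:`Spectrum`.

    Non-numeric lines (headers, comments) are skipped and counted; a file
    with no numeric rows raises ``ValueError``.
    """
    path = Path(path)
    mzs, intens = [], []
    skipped = 0
    with path.open() as fh:
        for line in fh:
            parts = [p for p in _SPLIT.split(line.strip()) if p]
            if len(parts) < 2:
                if parts:
                    skipped += 1
                continue
            try:
                mz, inten = float(parts[0]), float(parts[1])
            except ValueError:
                skipped += 1
                continue
            mzs.append(mz)
            intens.append(inten)
    if skipped:
        log.info("%s: skipped %d malformed line(s)", path.name, skipped)
    if not mzs:
        raise ValueError(f"{path}: no numeric m/z-intensity rows found")
    return Spectrum(np.array(mzs), np.array(intens), delta_cv=delta_cv,
                    replicate_id=replicate_id)


def denoise_baseline(
    spectrum: Spectrum,
    noise_floor: float = 0.0,
    percentile: float | None = None,
) -> Spectrum:
    """Return a copy with peaks at or below the noise threshold removed.

    The threshold is either the absolute ``noise_floor`` or, if ``percentile``
    is given, that percentile of the nonzero intensities.  Removal uses a
    strict inequality (a peak is dropped only when strictly below the
    threshold), so equal-intensity peaks at the percentile all survive and a
    zero floor is the identity.
    """
    if noise_floor < 0:
        raise ValueError("noise threshold must be >= 0")
    threshold = noise_floor
    if percentile is not None:
        nonzero = spectrum.intensity[spectrum.intensity > 0]
        if nonzero.size:
            threshold = max(threshold, float(np.percentile(nonzero, percentile)))
    keep = spectrum.intensity >= threshold
    if not np.any(keep):
        log.warning("denoise threshold %.3g removed every peak", threshold)
    return Spectrum(spectrum.mz[keep], spectrum.intensity[keep],
                    delta_cv=spectrum.delta_cv, replicate_id=spectrum.replicate_id)


def extract_target_intensity(spectrum: Spectrum, target_mz: float,
                             tolerance: float = 0.5) -> float:
    """Summed intensity of all peaks with ``|mz - target| <= tolerance``.

    Absence of peaks in the window is data (returns 0.0), not an error.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    lo = np.searchsorted(spectrum.mz, target_mz - tolerance, side="left")
    hi = np.searchsorted(spectrum.mz, target_mz + tolerance, side="right")
    return float(spectrum.intensity[lo:hi].sum())


def normalize_species(raw: dict[str, float]) -> dict[str, float]:
    """Normalize raw species intensities so they sum to 100 %.

    Raises ``ValueError`` when every intensity is zero: that voltage step has
    no monitored signal and must be flagged missing rather than reported 0/0.
    """
    total = float(sum(raw.values()))
    if total <= 0:
        raise ValueError("all target intensities are zero; fractions undefined")
    return {label: 100.0 * value / total for label, value in raw.items()}


def extract_normalized(spectrum: Spectrum,
                       targets: list[TargetIon]) -> NormalizedIntensities:
    """Extract every target ion from a spectrum and normalize to 100 %."""
    raw = {t.species: extract_target_intensity(spectrum, t.mz, t.tolerance)
           for t in targets}
    fractions = normalize_species(raw)
    return NormalizedIntensities(delta_cv=spectrum.delta_cv, fractions=fractions,
                                 replicate_id=spectrum.replicate_id, raw=raw)


def default_targets(seq, tolerance: float = 0.5) -> list[TargetIon]:
    """Default monitored ions for a homo-trimer dissociation experiment.

    Educt: trimer 5+; products: dimer 3+ and monomer 2+.  Target m/z values
    are the calculated (sequence-derived) positions; observed centroids can
    be substituted by building the list manually.
    """
    from .peptide import oligomer_mz

    return [
        TargetIon("trimer", oligomer_mz(seq, 3, 5), tolerance, "educt"),
        TargetIon("dimer", oligomer_mz(seq, 2, 3), tolerance, "product"),
        TargetIon("monomer", oligomer_mz(seq, 1, 2), tolerance, "product"),
    ]
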