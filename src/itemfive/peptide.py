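"""Peptide sequence parsing and mass/formula computation.

Supports engineered peptides containing D-amino acids (written as lowercase
single-letter codes; mass-neutral stereochemistry), non-natural residues with
multi-letter codes in braces (``{Nal}`` = 3-(2-naphthyl)alanine,
``{Dip}`` = 3,3-diphenylalanine), and either a free-acid or a carboxamide
C-terminus.  Monoisotopic masses reproduce calculated n-mer m/z values for
multiply protonated non-covalent oligomer ions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from pyteomics.mass import Composition, calculate_mass, std_aa_comp

from .constants import PROTON_MASS

__all__ = [
    "ResidueTable",
    "PeptideSequence",
    "SequenceParseError",
    "parse_sequence",
    "oligomer_mz",
]

#: Residue (monomer-unit) formulas of the built-in non-natural amino acids:
#: backbone + side chain, minus water, as for the canonical residues.
NONNATURAL_FORMULAS = {
    "Nal": "C13H11NO",  # 3-(2-naphthyl)alanine
    "Dip": "C15H13NO",  # 3,3-diphenylalanine
}


class SequenceParseError(ValueError):
    """Raised when a sequence string contains an unresolvable token."""


class ResidueTable:
    """Mapping of residue tokens to elemental compositions and masses.

    The 20 canonical residues come from the standard residue composition
    table; lowercase tokens denote D-stereochemistry and map to the identical
    formula and mass as their uppercase counterparts.  Additional residues
    (e.g. user-supplied non-natural monomers) can be registered by formula.
    """

    def __init__(self, extra_formulas: dict[str, str] | None = None):
        self._comp: dict[str, Composition] = {}
        for token, comp in std_aa_comp.items():
            if len(token) == 1 and token.isalpha():
                self._comp[token] = Composition(comp)
        for token, formula in NONNATURAL_FORMULAS.items():
            self._comp[token] = Composition(formula=formula)
        if extra_formulas:
            for token, formula in extra_formulas.items():
                self._comp[token] = Composition(formula=formula)

    def __contains__(self, token: str) -> bool:
        return self._canonical(token) is not None

    def _canonical(self, token: str) -> str | None:
        if token in self._comp:
            return token
        # lowercase single letters and brace tokens: D-residue, mass-neutral
        if token.upper() in self._comp:
            return token.upper()
        if token.capitalize() in self._comp:
            return token.capitalize()
        return None

    def composition(self, token: str) -> Composition:
        canonical = self._canonical(token)
        if canonical is None:
            raise KeyError(token)
        return self._comp[canonical]

    def monoisotopic_mass(self, token: str) -> float:
        return calculate_mass(composition=self.composition(token))

    def average_mass(self, token: str) -> float:
        return calculate_mass(composition=self.composition(token), average=True)

    def tokens(self) -> list[str]:
        return sorted(self._comp)


_DEFAULT_TABLE = ResidueTable()

_WATER = Composition(formula="H2O")
# acid C-terminus -OH -> carboxamide -NH2
_AMIDE_ADJUST = Composition({"N": 1, "H": 1, "O": -1})


@dataclass(frozen=True)
class ResidueToken:
    """A single residue occurrence, keeping the D/L annotation for reporting."""

    token: str
    d_stereo: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.token.lower() if self.d_stereo else self.token


@dataclass
class PeptideSequence:
    """Parsed peptide: ordered residues plus terminal groups.

    ``c_terminus`` is ``"acid"`` (free carboxylic acid) or ``"amide"``
    (C-terminal carboxamide, -0.98402 u relative to the acid).
    """

    residues: list[ResidueToken]
    c_terminus: str = "acid"
    table: ResidueTable = field(default_factory=lambda: _DEFAULT_TABLE, repr=False)

    def __post_init__(self):
        if not self.residues:
            raise ValueError("a peptide needs at least one residue")
        if self.c_terminus not in ("acid", "amide"):
            raise ValueError(f"unknown C-terminus {self.c_terminus!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def composition(self) -> Composition:
        """Molecular formula as an element -> count mapping."""
        comp = Composition()
        for res in self.residues:
            comp += self.table.composition(res.token)
        comp += _WATER
        if self.c_terminus == "amide":
            comp += _AMIDE_ADJUST
        return Composition({el: n for el, n in comp.items() if n})

    def molecular_formula(self) -> dict[str, int]:
        return dict(self.composition())

    def atom_count(self) -> int:
        """Total number of atoms, hydrogens included."""
        return sum(self.composition().values())

    def monoisotopic_mass(self) -> float:
        return calculate_mass(composition=self.composition())

    def average_mass(self) -> float:
        return calculate_mass(composition=self.composition(), average=True)


_TERMINAL_N = re.compile(r"^H-")
_TERMINAL_C = re.compile(r"-(OH|NH2)$", re.IGNORECASE)


def parse_sequence(text: str, table: ResidueTable | None = None) -> PeptideSequence:
    """Parse a sequence string into a :class:`PeptideSequence`.

    Grammar: optional ``H-`` prefix (free amine N-terminus), an optional
    ``-OH``/``-NH2`` suffix (default acid), single-letter residue codes with
    lowercase marking D-stereochemistry, and brace-delimited multi-letter
    tokens such as ``{Nal}``.

    Raises
    ------
    SequenceParseError
        If the string is empty or contains an unknown token; the message
        names the offending token and its position.
    """
    table = table or _DEFAULT_TABLE
    if not text or not text.strip():
        raise SequenceParseError("empty sequence string")
    body = text.strip()
    body = _TERMINAL_N.sub("", body)
    c_terminus = "acid"
    m = _TERMINAL_C.search(body)
    if m:
        c_terminus = "amide" if m.group(1).upper() == "NH2" else "acid"
        body = body[: m.start()]
    if not body:
        raise SequenceParseError("sequence contains no residues")

    residues: list[ResidueToken] = []
    i = 0
    while i < len(body):
        ch = body[i]
        if ch == "{":
            end = body.find("}", i)
            if end < 0:
                raise SequenceParseError(f"unterminated brace token at position {i + 1}")
            token = body[i + 1 : end]
            i = end + 1
        elif ch.isalpha():
            token = ch
            i += 1
        else:
            raise SequenceParseError(f"unexpected character {ch!r} at position {i + 1}")
        if token not in table:
            raise SequenceParseError(
                f"unknown residue token {token!r} at position {len(residues) + 1}"
            )
        d_stereo = len(token) == 1 and token.islower()
        residues.append(ResidueToken(token=token, d_stereo=d_stereo))
    return PeptideSequence(residues=residues, c_terminus=c_terminus, table=table)


def oligomer_mz(
    seq: PeptideSequence,
    n_mer: int = 1,
    z: int = 1,
    adduct_masses: list[float] | None = None,
) -> float:
    """m/z of the multiply protonated non-covalent n-mer ion.

    Non-covalent assembly conserves mass: the neutral n-mer is exactly
    ``n_mer`` monomer masses.  Optional neutral adduct masses (e.g. sodium
    replacement shifts) are added to the neutral complex before protonation.
    """
    if n_mer < 1:
        raise ValueError("n_mer must be >= 1")
    if z < 1:
        raise ValueError("a neutral species has no m/z; charge must be >= 1")
    neutral = n_mer * seq.monoisotopic_mass()
    if adduct_masses:
        neutral += sum(adduct_masses)
    return (neutral + z * PROTON_MASS) / z
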