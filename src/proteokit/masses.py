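"""Element and residue mass tables plus peptide mass and m/z arithmetic.

The residue tables are loaded from a plain-text resource shipped with the
package (``data/residue_masses.tsv``) so the provenance of every constant is
auditable in one place.  A *residue* mass is the amino-acid mass minus one
water — the mass the residue contributes inside a peptide chain — so a
neutral peptide mass is the residue sum plus one water.

Modification positions follow the convention 0 = N-terminus, 1..n = residue
positions (1-based), n+1 = C-terminus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .errors import (
    InvalidChargeError,
    InvalidModificationError,
    InvalidResidueError,
    InvalidSequenceError,
)

# Monoisotopic masses of small neutral species and the proton, in Da,
# from the IUPAC standard atomic masses. Offsets between fragment-ion
# series are expressed with these.
PROTON = 1.007276467
WATER_MONO = 18.010565
WATER_AVG = 18.01528
H = 1.0078250319
H2 = 2 * H
NH3 = 17.026549
CO = 27.994915

N_TERM = 0  # modification position marking the N-terminus


@dataclass(frozen=True)
class Modification:
    """A fixed-mass attachment to a residue or terminus.

    Parameters
    ----------
    name : str
        Display name, e.g. ``"Oxidation"``.
    mass_shift : float
        Signed monoisotopic mass shift in Da.
    target : str
        One-letter residue code, ``"N-term"`` or ``"C-term"``.
    """

    name: str
    mass_shift: float
    target: str = "any"

    def __post_init__(self):
        import math

        if not math.isfinite(self.mass_shift):
            raise InvalidModificationError(
                f"modification {self.name!r} has non-finite mass shift"
            )
        if not (
            self.target in ("N-term", "C-term", "any")
            or (len(self.target) == 1 and self.target.isalpha())
        ):
            raise InvalidModificationError(
                f"modification target {self.target!r} is neither a residue "
                "code nor a terminus marker"
            )


@dataclass(frozen=True)
class MassTable:
    """Residue mass tables and physical constants.

    ``residue_mono`` and ``residue_avg`` map one-letter codes to residue
    masses in Da.  ``permissive`` extends the alphabet with U (selenocysteine)
    and O (pyrrolysine); by default these are rejected, as are the ambiguity
    codes B, Z and X, so bad input fails loudly instead of being averaged.
    """

    residue_mono: Mapping[str, float]
    residue_avg: Mapping[str, float]
    water_mono: float = WATER_MONO
    water_avg: float = WATER_AVG
    proton: float = PROTON

    def alphabet(self) -> frozenset[str]:
        return frozenset(self.residue_mono)

    def validate(self, sequence: str) -> str:
        """Check ``sequence`` against the residue alphabet.

        Returns the sequence unchanged; raises :class:`InvalidSequenceError`
        when empty and :class:`InvalidResidueError` (naming the character and
        its 1-based position) on the first unknown residue.
        """
        if not sequence:
            raise InvalidSequenceError("empty sequence")
        table = self.residue_mono
        for i, ch in enumerate(sequence):
            if ch not in table:
                raise InvalidResidueError(ch, i + 1)
        return sequence


def _load_tables() -> tuple[dict[str, float], dict[str, float], dict[str, float], dict[str, float]]:
    std_mono: dict[str, float] = {}
    std_avg: dict[str, float] = {}
    ext_mono: dict[str, float] = {}
    ext_avg: dict[str, float] = {}
    text = (
        resources.files("proteokit") / "data" / "residue_masses.tsv"
    ).read_text(encoding="utf-8")
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        code, mono, avg = parts[0], float(parts[1]), float(parts[2])
        if len(parts) > 3 and parts[3] == "extension":
            ext_mono[code], ext_avg[code] = mono, avg
        else:
            std_mono[code], std_avg[code] = mono, avg
    return std_mono, std_avg, ext_mono, ext_avg


_STD_MONO, _STD_AVG, _EXT_MONO, _EXT_AVG = _load_tables()

#: Default table: the 20 standard residues only.
STANDARD = MassTable(residue_mono=_STD_MONO, residue_avg=_STD_AVG)

#: Permissive table: standard residues plus selenocysteine (U) and
#: pyrrolysine (O) at their own masses.
PERMISSIVE = MassTable(
    residue_mono={**_STD_MONO, **_EXT_MONO},
    residue_avg={**_STD_AVG, **_EXT_AVG},
)


ModificationList = Sequence[tuple[int, Modification]]


def _check_mod_positions(sequence: str, modifications: ModificationList) -> None:
    n = len(sequence)
    for pos, mod in modifications:
        if not (0 <= pos <= n + 1):
            raise InvalidModificationError(
                f"modification {mod.name!r} at position {pos} outside "
                f"[0, {n + 1}] for a {n}-residue peptide"
            )


def monoisotopic_mass(
    sequence: str,
    modifications: ModificationList = (),
    table: MassTable = STANDARD,
) -> float:
    """Neutral monoisotopic peptide mass in Da.

    Sum of residue monoisotopic masses plus one water plus all modification
    mass shifts.  Modification positions: 0 = N-terminus, 1..n = residues,
    n+1 = C-terminus.
    """
    table.validate(sequence)
    _check_mod_positions(sequence, modifications)
    mono = table.residue_mono
    mass = table.water_mono + sum(mono[ch] for ch in sequence)
    return mass + sum(mod.mass_shift for _, mod in modifications)


def average_mass(
    sequence: str,
    modifications: ModificationList = (),
    table: MassTable = STANDARD,
) -> float:
    """Neutral average peptide mass in Da (abundance-weighted elements)."""
    table.validate(sequence)
    _check_mod_positions(sequence, modifications)
    avg = table.residue_avg
    mass = table.water_avg + sum(avg[ch] for ch in sequence)
    return mass + sum(mod.mass_shift for _, mod in modifications)


def mz(neutral_mass: float, charge: int, proton: float = PROTON) -> float:
    """m/z in Th of a neutral mass carrying ``charge`` protons."""
    if charge < 1:
        raise InvalidChargeError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * proton) / charge


def neutral_mass_from_mz(mz_value: float, charge: int, proton: float = PROTON) -> float:
    """Neutral mass in Da from an observed m/z; exact inverse of :func:`mz`."""
    if charge < 1:
        raise InvalidChargeError(f"charge must be >= 1, got {charge}")
    return mz_value * charge - charge * proton
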