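"""Theoretical fragment-ion generation and peak annotation.

Collision- or electron-induced backbone cleavage of a peptide of length n
yields N-terminal series (a, b, c) and C-terminal series (x, y, z) at
indices 1..n-1.  With prefix_i the sum of the first i residue masses and
suffix_i the sum of the last i, the singly protonated m/z values follow

    b_i = prefix_i + proton          y_i = suffix_i + water + proton
    a_i = b_i - CO                   x_i = y_i + CO - H2
    c_i = b_i + NH3                  z_i = y_i - NH3   (z• = z + H)

Higher charge states divide the neutral fragment mass plus z protons by z.
z ions default to the z-dot (z + 1 H) radical variant conventionally shown
for ETD spectra; pass ``z_dot=False`` for plain z.

Annotation matches each theoretical ion to at most one observed peak — the
peak minimising |observed - theoretical| within tolerance, ties broken by
higher intensity, then lower m/z.  Several ions may share one peak.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from . import masses as _m
from .errors import InvalidChargeError
from .masses import MassTable, Modification, ModificationList, STANDARD


class Series(str, Enum):
    A = "a"
    B = "b"
    C = "c"
    X = "x"
    Y = "y"
    Z = "z"


class NeutralLoss(str, Enum):
    NONE = "none"
    H2O = "H2O"
    NH3 = "NH3"


_LOSS_MASS = {NeutralLoss.NONE: 0.0, NeutralLoss.H2O: _m.WATER_MONO, NeutralLoss.NH3: _m.NH3}
# residues that can plausibly lose the small neutral in question
_LOSS_RESIDUES = {NeutralLoss.H2O: set("STED"), NeutralLoss.NH3: set("RKNQ")}

_N_TERMINAL = {Series.A, Series.B, Series.C}


@dataclass(frozen=True)
class Tolerance:
    """A match tolerance: an absolute window in Da or a relative one in ppm."""

    value: float
    unit: str = "Da"  # "Da" or "ppm"

    def __post_init__(self):
        if self.unit not in ("Da", "ppm"):
            raise ValueError(f"tolerance unit must be 'Da' or 'ppm', got {self.unit!r}")
        if self.value <= 0:
            raise ValueError("tolerance must be positive")

    def window(self, at_mz: float) -> float:
        """Half-width of the acceptance window in Th at ``at_mz``."""
        return self.value if self.unit == "Da" else self.value * at_mz / 1e6

    @classmethod
    def parse(cls, text: str) -> "Tolerance":
        """Parse e.g. ``"0.01Da"`` or ``"10ppm"`` (space optional)."""
        text = text.strip()
        for unit in ("ppm", "Da", "da"):
            if text.endswith(unit):
                return cls(float(text[: -len(unit)].strip()), "Da" if unit.lower() == "da" else "ppm")
        return cls(float(text), "Da")


@dataclass(frozen=True)
class FragmentIon:
    series: Series
    index: int
    charge: int
    neutral_loss: NeutralLoss
    mz: float

    @property
    def label(self) -> str:
        """Deterministic display label, e.g. ``y3+``, ``b2++-H2O``."""
        loss = "" if self.neutral_loss is NeutralLoss.NONE else f"-{self.neutral_loss.value}"
        return f"{self.series.value}{self.index}{'+' * self.charge}{loss}"


@dataclass(frozen=True)
class PeakAnnotation:
    """A theoretical ion matched to a spectrum peak, with signed m/z error."""

    peak_index: int
    ion: FragmentIon
    error_mz: float  # observed - theoretical, Th


def _mod_shifts(sequence: str, modifications: ModificationList) -> tuple[list[float], float, float]:
    """Per-residue modification shifts plus N- and C-terminal shifts."""
    n = len(sequence)
    per_residue = [0.0] * n
    n_term = c_term = 0.0
    for pos, mod in modifications:
        if pos == 0:
            n_term += mod.mass_shift
        elif pos == n + 1:
            c_term += mod.mass_shift
        else:
            per_residue[pos - 1] += mod.mass_shift
    return per_residue, n_term, c_term


def fragment(
    sequence: str,
    series_set: Iterable[Series] = (Series.B, Series.Y),
    max_charge: int = 1,
    losses: Iterable[NeutralLoss] = (),
    modifications: ModificationList = (),
    table: MassTable = STANDARD,
    z_dot: bool = True,
    chemically_aware: bool = True,
) -> list[FragmentIon]:
    """All theoretical fragment ions for the requested series and charges.

    Indices run 1..n-1 (a single-residue peptide has no backbone bond and
    yields an empty list).  When ``chemically_aware`` (default) neutral-loss
    ions are only generated for fragments containing a residue able to lose
    the neutral (H2O: S/T/E/D; NH3: R/K/N/Q); turn it off to attach every
    requested loss to every ion.
    """
    table.validate(sequence)
    if max_charge < 1:
        raise InvalidChargeError(f"max_charge must be >= 1, got {max_charge}")
    n = len(sequence)
    if n < 2:
        return []
    per_res, n_term_shift, c_term_shift = _mod_shifts(sequence, modifications)
    residue = [table.residue_mono[ch] + per_res[i] for i, ch in enumerate(sequence)]

    prefix = [0.0] * (n + 1)
    for i in range(n):
        prefix[i + 1] = prefix[i] + residue[i]
    total = prefix[n]

    # neutral fragment masses per series at index i
    def neutral(series: Series, i: int) -> float:
        if series in _N_TERMINAL:
            base = prefix[i] + n_term_shift
            if series is Series.B:
                return base
            if series is Series.A:
                return base - _m.CO
            return base + _m.NH3  # c
        base = (total - prefix[n - i]) + table.water_mono + c_term_shift
        if series is Series.Y:
            return base
        if series is Series.X:
            return base + _m.CO - _m.H2
        z = base - _m.NH3  # z
        return z + _m.H if z_dot else z

    loss_list = [NeutralLoss.NONE] + [
        l for l in losses if l is not NeutralLoss.NONE
    ]
    series_list = sorted(set(series_set), key=lambda s: s.value)
    ions: list[FragmentIon] = []
    for series in series_list:
        for i in range(1, n):
            frag_seq = sequence[:i] if series in _N_TERMINAL else sequence[n - i :]
            for loss in loss_list:
                if loss is not NeutralLoss.NONE and chemically_aware:
                    if not (_LOSS_RESIDUES[loss] & set(frag_seq)):
                        continue
                neutral_mass = neutral(series, i) - _LOSS_MASS[loss]
                for charge in range(1, max_charge + 1):
                    ions.append(
                        FragmentIon(
                            series=series,
                            index=i,
                            charge=charge,
                            neutral_loss=loss,
                            mz=(neutral_mass + charge * table.proton) / charge,
                        )
                    )
    return ions


def annotate(
    spectrum,
    ions: Sequence[FragmentIon],
    tolerance: Tolerance = Tolerance(0.01, "Da"),
) -> list[PeakAnnotation]:
    """Match theoretical ions to observed peaks.

    Each ion is matched to at most one peak: the peak minimising
    |observed - theoretical| within ``tolerance`` (evaluated at the
    theoretical m/z for ppm units); ties broken by higher intensity, then
    lower m/z.  Unmatched ions are simply absent from the result, whose
    order follows the peak index, then the ion label (so the output is
    invariant under permutation of the input ion list).
    """
    mz_arr = list(spectrum.mz)
    int_arr = list(spectrum.intensity)
    out: list[PeakAnnotation] = []
    for ion in ions:
        half = tolerance.window(ion.mz)
        lo = bisect.bisect_left(mz_arr, ion.mz - half)
        hi = bisect.bisect_right(mz_arr, ion.mz + half)
        best = None
        for k in range(lo, hi):
            err = abs(mz_arr[k] - ion.mz)
            key = (err, -int_arr[k], mz_arr[k])
            if best is None or key < best[0]:
                best = (key, k)
        if best is not None:
            k = best[1]
            out.append(PeakAnnotation(k, ion, mz_arr[k] - ion.mz))
    out.sort(key=lambda a: (a.peak_index, a.ion.label, a.ion.charge))
    return out
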