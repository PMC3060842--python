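"""Spectrum and chromatogram models, MGF I/O, rendering and linked zooming.

Both spectra and chromatograms are ordered (x, y) coordinate lists with
metadata.  Peak lists travel as MGF (Mascot Generic Format): BEGIN IONS /
END IONS blocks with TITLE / PEPMASS / CHARGE keys and "mz intensity" peak
lines.  Rendering targets static PNG/SVG files with deterministic output —
the testable contract of an interactive viewer's export function — and view
windows can be linked so that zooming one propagates to all linked views.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, TextIO

from .errors import MalformedMgfError, UnsupportedFormatError

# fixed MGF write formatting: m/z 4 decimals, intensity 2
_MZ_FMT = "{:.4f}"
_INT_FMT = "{:.2f}"


@dataclass
class Spectrum:
    """A mass spectrum: ascending m/z values with nonnegative intensities.

    ``level`` distinguishes survey scans (1) from fragmentation spectra (2),
    which may carry a precursor m/z and charge.
    """

    mz: list[float]
    intensity: list[float]
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None
    title: str = ""
    level: int = 2

    def __post_init__(self):
        if len(self.mz) != len(self.intensity):
            raise ValueError("mz and intensity lengths differ")
        if any(i < 0 for i in self.intensity):
            raise ValueError("negative intensity")
        # normalise to ascending m/z; stable so duplicate m/z keep file order
        if any(a > b for a, b in zip(self.mz, self.mz[1:])):
            order = sorted(range(len(self.mz)), key=lambda k: self.mz[k])
            self.mz = [self.mz[k] for k in order]
            self.intensity = [self.intensity[k] for k in order]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class Chromatogram:
    """An elution profile: strictly ascending times (s) with signal."""

    time: list[float]
    signal: list[float]
    label: str = ""

    def __post_init__(self):
        if len(self.time) != len(self.signal):
            raise ValueError("time and signal lengths differ")
        if any(a >= b for a, b in zip(self.time, self.time[1:])):
            raise ValueError("time must be strictly ascending")
        if any(s < 0 for s in self.signal):
            raise ValueError("negative signal")


_CHARGE_RE = re.compile(r"^([+-]?)(\d+)([+-]?)$")


def _parse_charge(text: str) -> int:
    """Parse an MGF CHARGE token: '2+', '+2', '2', '3-' → signed int."""
    m = _CHARGE_RE.match(text.strip())
    if not m:
        raise ValueError(f"bad charge {text!r}")
    sign = -1 if "-" in (m.group(1), m.group(3)) else 1
    return sign * int(m.group(2))


def read_mgf(source: TextIO) -> Iterator[Spectrum]:
    """Iterate spectra from an MGF stream.

    Peaks are sorted ascending by m/z on read.  An unclosed BEGIN IONS block
    or a non-numeric peak line raises :class:`MalformedMgfError` carrying the
    line number.
    """
    in_block = False
    block_start = 0
    mz: list[float] = []
    intensity: list[float] = []
    meta: dict[str, str] = {}
    lineno = 0
    for lineno, line in enumerate(source, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            if in_block:
                raise MalformedMgfError("nested BEGIN IONS", lineno)
            in_block, block_start = True, lineno
            mz, intensity, meta = [], [], {}
            continue
        if line == "END IONS":
            if not in_block:
                raise MalformedMgfError("END IONS without BEGIN IONS", lineno)
            in_block = False
            charge = None
            if "CHARGE" in meta:
                charge = _parse_charge(meta["CHARGE"].split(",")[0])
            pepmass = None
            if "PEPMASS" in meta:
                pepmass = float(meta["PEPMASS"].split()[0])
            yield Spectrum(
                mz=mz,
                intensity=intensity,
                precursor_mz=pepmass,
                precursor_charge=charge,
                title=meta.get("TITLE", ""),
            )
            continue
        if not in_block:
            continue  # headers outside blocks are permitted and ignored
        if "=" in line and not line[0].isdigit():
            key, _, value = line.partition("=")
            meta[key.strip().upper()] = value.strip()
            continue
        parts = line.split()
        try:
            mz.append(float(parts[0]))
            intensity.append(float(parts[1]) if len(parts) > 1 else 0.0)
        except (ValueError, IndexError):
            raise MalformedMgfError(f"bad peak line {line!r}", lineno) from None
    if in_block:
        raise MalformedMgfError("BEGIN IONS without END IONS", block_start)


def write_mgf(spectra: Iterable[Spectrum], sink: TextIO) -> None:
    """Write spectra as MGF; inverse of :func:`read_mgf` on its own output.

    Numeric formatting is fixed (m/z to 4 decimals, intensity to 2) so the
    round trip preserves values to printed precision.  A spectrum without a
    precursor omits the PEPMASS line.
    """
    for spectrum in spectra:
        sink.write("BEGIN IONS\n")
        if spectrum.title:
            sink.write(f"TITLE={spectrum.title}\n")
        if spectrum.precursor_mz is not None:
            sink.write(f"PEPMASS={_MZ_FMT.format(spectrum.precursor_mz)}\n")
        if spectrum.precursor_charge is not None:
            z = spectrum.precursor_charge
            sink.write(f"CHARGE={abs(z)}{'+' if z >= 0 else '-'}\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            sink.write(f"{_MZ_FMT.format(m)} {_INT_FMT.format(i)}\n")
        sink.write("END IONS\n")


# ---------------------------------------------------------------------------
# linked view windows


@dataclass
class ViewState:
    """An axis window, optionally a member of a linked zoom group."""

    x_min: float
    x_max: float
    linked_group: Optional["LinkedGroup"] = None

    def __post_init__(self):
        if not self.x_min < self.x_max:
            raise ValueError("x_min must be < x_max")

    def set_window(self, x_min: float, x_max: float) -> None:
        """Set this view's window; propagates to every linked view."""
        if not x_min < x_max:
            raise ValueError("x_min must be < x_max")
        if self.linked_group is not None:
            self.linked_group._propagate(x_min, x_max)
        else:
            self._apply(x_min, x_max)

    def _apply(self, x_min: float, x_max: float) -> bool:
        changed = (x_min, x_max) != (self.x_min, self.x_max)
        self.x_min, self.x_max = x_min, x_max
        return changed


class LinkedGroup:
    """A set of views whose windows move together.

    Propagation is loop-free: one ``set_window`` applies the window to each
    member exactly once, and re-setting an unchanged window fires no update
    (``update_count`` counts actual window changes, for diagnostics).
    """

    def __init__(self, views: Sequence[ViewState]):
        if len(views) < 2:
            raise ValueError("a linked group needs at least 2 views")
        self.views: list[ViewState] = list(views)
        self.update_count = 0
        for v in self.views:
            v.linked_group = self

    def _propagate(self, x_min: float, x_max: float) -> None:
        for v in self.views:
            if v._apply(x_min, x_max):
                self.update_count += 1

    def unlink(self, view: ViewState) -> None:
        # identity, not equality: linked views often share the same window
        self.views = [v for v in self.views if v is not view]
        view.linked_group = None


def link_views(views: Sequence[ViewState]) -> LinkedGroup:
    """Link >= 2 views so zooming any member zooms them all."""
    return LinkedGroup(views)


# ---------------------------------------------------------------------------
# rendering


def render(
    data: Spectrum | Chromatogram,
    annotations: Sequence = (),
    view: Optional[ViewState] = None,
    sink: str = "out.svg",
    format: Optional[str] = None,
) -> None:
    """Render a spectrum or chromatogram to a PNG or SVG file.

    Spectrum peaks are drawn as sticks; annotated peaks carry their fragment
    label.  Only data inside the view window is drawn; the intensity axis
    spans 0..1.05 x the maximum intensity in the window.  SVG output is
    byte-deterministic for identical inputs.  When two labels would overlap
    horizontally within 1% of the window width, the lower-intensity peak's
    label is shifted up one line.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fmt = (format or sink.rsplit(".", 1)[-1]).lower()
    if fmt not in ("png", "svg"):
        raise UnsupportedFormatError(f"unsupported image format {fmt!r}")

    with matplotlib.rc_context(
        {"svg.hashsalt": "proteokit", "figure.dpi": 100}
    ):
        fig, ax = plt.subplots(figsize=(8, 4))
        try:
            if isinstance(data, Chromatogram):
                _draw_chromatogram(ax, data, view)
            else:
                _draw_spectrum(ax, data, annotations, view)
            fig.savefig(sink, format=fmt, metadata=_deterministic_metadata(fmt))
        finally:
            plt.close(fig)


def _deterministic_metadata(fmt: str) -> dict:
    # strip the embed date so identical input gives identical bytes
    return {"Date": None} if fmt == "svg" else {}


def _window(data_x: Sequence[float], view: Optional[ViewState]) -> tuple[float, float]:
    if view is not None:
        return view.x_min, view.x_max
    if data_x:
        lo, hi = min(data_x), max(data_x)
        pad = 0.05 * (hi - lo or 1.0)
        return lo - pad, hi + pad
    return 0.0, 1.0


def _draw_spectrum(ax, spectrum: Spectrum, annotations, view) -> None:
    x_min, x_max = _window(spectrum.mz, view)
    inside = [
        (m, i)
        for m, i in zip(spectrum.mz, spectrum.intensity)
        if x_min <= m <= x_max
    ]
    y_max = max((i for _, i in inside), default=1.0) * 1.05 or 1.0
    for m, i in inside:
        ax.vlines(m, 0, i, colors="black", linewidths=0.8)
    _place_labels(ax, spectrum, annotations, x_min, x_max, y_max)
    ax.set_xlim(x_min, x_max)
    ax.set_ylim(0, y_max)
    ax.set_xlabel("m/z")
    ax.set_ylabel("intensity")
    if spectrum.title:
        ax.set_title(spectrum.title)


def _place_labels(ax, spectrum, annotations, x_min, x_max, y_max) -> None:
    # deterministic collision rule: sort by m/z; a label within 1% of the
    # window width of the previous one is raised one line if its peak is the
    # less intense of the pair
    items = []
    for ann in annotations:
        m = spectrum.mz[ann.peak_index]
        if x_min <= m <= x_max:
            items.append((m, spectrum.intensity[ann.peak_index], ann.ion.label))
    items.sort()
    line_height = 0.05 * y_max
    min_gap = 0.01 * (x_max - x_min)
    prev_x = None
    prev_rows = 0
    prev_intensity = 0.0
    for m, intensity, label in items:
        rows = 0
        if prev_x is not None and m - prev_x < min_gap and intensity <= prev_intensity:
            rows = prev_rows + 1
        ax.annotate(
            label,
            xy=(m, intensity),
            xytext=(m, intensity + (0.3 + rows) * line_height),
            ha="center",
            fontsize=8,
            color="darkred",
        )
        prev_x, prev_rows, prev_intensity = m, rows, intensity


def _draw_chromatogram(ax, chrom: Chromatogram, view) -> None:
    x_min, x_max = _window(chrom.time, view)
    pts = [(t, s) for t, s in zip(chrom.time, chrom.signal) if x_min <= t <= x_max]
    if pts:
        ax.plot([p[0] for p in pts], [p[1] for p in pts], color="steelblue", lw=1.0)
        y_max = max(p[1] for p in pts) * 1.05 or 1.0
    else:
        y_max = 1.0
    ax.set_xlim(x_min, x_max)
    ax.set_ylim(0, y_max)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("signal")
    if chrom.label:
        ax.set_title(chrom.label)
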