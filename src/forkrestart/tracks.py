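"""Binned, strand-specific genome tracks and bedGraph I/O.

A :class:`Track` is a fixed-width binned signal over a single reference
sequence, the canonical in-memory form for everything this package
computes on: raw ribonucleotide counts, polymerase usage fractions, and
the Pol delta/delta bias. Coordinates are 0-based half-open throughout;
bin ``i`` covers ``[start + i*bin_width, start + (i+1)*bin_width)``.

The four raw Pu-Seq libraries — {Pol delta mutant, Pol epsilon mutant}
x {Watson, Crick} — are bundled in a :class:`CountTetrad`.

On disk, tracks are UCSC 4-column bedGraph (tab-separated). fixedStep
wiggle is accepted read-only as a convenience dialect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ConfigError,
    TrackFormatError,
    UnsupportedInputError,
)

__all__ = ["Track", "CountTetrad", "TETRAD_ROLES", "read_bedgraph", "write_bedgraph", "load_tetrad"]

#: manifest keys naming the four Pu-Seq libraries
TETRAD_ROLES = ("delta_watson", "delta_crick", "epsilon_watson", "epsilon_crick")


@dataclass
class Track:
    """A fixed-width binned numeric signal over one reference sequence.

    Parameters
    ----------
    ref_name
        Reference sequence name.
    bin_width
        Bin width in base pairs (> 0).
    start
        Coordinate (bp) of the left edge of bin 0.
    values
        One value per bin.
    mask
        True where a bin is *invalid* (undefined ratio, etc.). Defaults to
        all-valid. Absent bins in count tracks are value 0, unmasked:
        observing no reads is informative for counts; masking appears only
        downstream where ratios become undefined.
    """

    ref_name: str
    bin_width: int
    start: int
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.bin_width <= 0:
            raise TrackFormatError(f"bin_width must be positive, got {self.bin_width}")
        if self.start < 0:
            raise TrackFormatError(f"start must be >= 0, got {self.start}")
        if self.values.ndim != 1 or self.values.size == 0:
            raise TrackFormatError("values must be a nonempty 1-D sequence")
        if self.mask.shape != self.values.shape:
            raise TrackFormatError("mask and values must have the same length")

    @property
    def n_bins(self) -> int:
        return int(self.values.size)

    @property
    def end(self) -> int:
        """Coordinate one past the last bin (bp)."""
        return self.start + self.n_bins * self.bin_width

    def bin_starts(self) -> np.ndarray:
        return self.start + np.arange(self.n_bins, dtype=np.int64) * self.bin_width

    def bin_centers(self) -> np.ndarray:
        return self.bin_starts() + self.bin_width / 2.0

    def bin_index(self, pos: float) -> int:
        """Index of the bin containing coordinate ``pos`` (0-based half-open)."""
        i = int((pos - self.start) // self.bin_width)
        if not 0 <= i < self.n_bins:
            raise IndexError(f"position {pos} outside track [{self.start}, {self.end})")
        return i

    def bin_coords(self, i: int) -> tuple[int, int]:
        """Half-open genomic interval of bin ``i``."""
        if not 0 <= i < self.n_bins:
            raise IndexError(i)
        a = self.start + i * self.bin_width
        return a, a + self.bin_width

    def same_binning(self, other: "Track") -> bool:
        return (
            self.ref_name == other.ref_name
            and self.bin_width == other.bin_width
            and self.start == other.start
            and self.n_bins == other.n_bins
        )

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Track":
        """New Track on the same binning with different values (and mask)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       mask=None if mask is None else np.asarray(mask, dtype=bool))


@dataclass
class CountTetrad:
    """The four raw Pu-Seq count tracks sharing one binning.

    ``d_*`` are from the Pol delta-mutant library, ``e_*`` from the Pol
    epsilon-mutant library, each on the Watson and Crick strands.
    """

    d_watson: Track
    d_crick: Track
    e_watson: Track
    e_crick: Track

    def __post_init__(self) -> None:
        ref = self.d_watson
        for role, t in self.items():
            if not ref.same_binning(t):
                raise AlignmentError(
                    f"track {role!r} does not share the tetrad binning "
                    f"(ref={t.ref_name}, bin_width={t.bin_width}, start={t.start}, n={t.n_bins})"
                )
            if np.any(t.values[~t.mask] < 0):
                raise TrackFormatError(f"track {role!r} has negative counts")

    def items(self) -> list[tuple[str, Track]]:
        return list(zip(TETRAD_ROLES, (self.d_watson, self.d_crick, self.e_watson, self.e_crick)))


def _read_fixedstep(text: str, bin_width: int) -> Track:
    """Minimal fixedStep wiggle reader (read-only convenience dialect)."""
    ref = None
    start = None
    step = None
    vals: list[float] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("track", "#", "browser")):
            continue
        if line.startswith("fixedStep"):
            if ref is not None:
                raise UnsupportedInputError("multiple fixedStep blocks are not supported")
            kv = dict(tok.split("=", 1) for tok in line.split()[1:])
            ref = kv["chrom"]
            start = int(kv["start"]) - 1  # wiggle is 1-based
            step = int(kv.get("step", bin_width))
            span = int(kv.get("span", step))
            if step != bin_width or span != bin_width:
                raise TrackFormatError(
                    f"fixedStep step/span {step}/{span} does not match bin_width {bin_width}"
                )
        else:
            if ref is None:
                raise TrackFormatError("data line before fixedStep header")
            vals.append(float(line))
    if ref is None or not vals:
        raise TrackFormatError("empty wiggle file")
    return Track(ref_name=ref, bin_width=bin_width, start=start, values=np.array(vals))


def read_bedgraph(path, bin_width: int) -> Track:
    """Read a 4-column bedGraph into a :class:`Track`.

    The file must cover a single reference with sorted, non-overlapping
    intervals of length exactly ``bin_width``, aligned to a common grid.
    Bins absent from the file are filled with value 0, unmasked.

    Raises
    ------
    TrackFormatError
        Unsorted or overlapping intervals, or interval length != bin_width.
    UnsupportedInputError
        More than one reference name.
    """
    with open(path, "rt") as fh:
        text = fh.read()
    stripped = text.lstrip()
    if stripped.startswith("fixedStep") or "\nfixedStep" in text:
        return _read_fixedstep(text, bin_width)

    data_lines = [
        ln for ln in text.splitlines()
        if ln.strip() and not ln.startswith(("track", "#", "browser"))
    ]
    if not data_lines:
        raise TrackFormatError(f"{path}: no data lines")
    try:
        df = pd.read_csv(
            io.StringIO("\n".join(data_lines)),
            sep=r"\s+",
            header=None,
            names=["ref", "ivl_start", "ivl_end", "value"],
            dtype={"ref": str, "ivl_start": np.int64, "ivl_end": np.int64, "value": float},
            float_precision="round_trip",
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise TrackFormatError(f"{path}: cannot parse as 4-column bedGraph: {exc}") from exc

    refs = df["ref"].unique()
    if len(refs) != 1:
        raise UnsupportedInputError(f"{path}: multiple reference names {sorted(refs)}")
    starts = df["ivl_start"].to_numpy()
    ends = df["ivl_end"].to_numpy()
    if np.any(ends - starts != bin_width):
        bad = int(np.argmax(ends - starts != bin_width))
        raise TrackFormatError(
            f"{path}: interval length {ends[bad] - starts[bad]} != bin_width {bin_width} "
            f"at line {bad + 1}"
        )
    if np.any(np.diff(starts) <= 0) or np.any(starts[1:] < ends[:-1]):
        raise TrackFormatError(f"{path}: intervals are unsorted or overlapping")
    if np.any((starts - starts[0]) % bin_width != 0):
        raise TrackFormatError(f"{path}: intervals are not aligned to a {bin_width} bp grid")

    origin = int(starts[0])
    idx = (starts - origin) // bin_width
    values = np.zeros(int(idx[-1]) + 1, dtype=float)
    values[idx] = df["value"].to_numpy()
    return Track(ref_name=str(refs[0]), bin_width=bin_width, start=origin, values=values)


def write_bedgraph(track: Track, path) -> None:
    """Write a Track as sorted 4-column bedGraph.

    Values are written with full (round-trip) precision, so
    ``read_bedgraph(write_bedgraph(t))`` reproduces unmasked values
    bit-exactly. Masked bins are omitted (bedGraph has no NA).
    """
    if track.n_bins == 0:  # pragma: no cover - Track forbids this
        raise TrackFormatError("refusing to write an empty track")
    keep = ~track.mask
    if not np.any(keep):
        raise TrackFormatError("refusing to write a fully masked track")
    starts = track.bin_starts()[keep]
    vals = track.values[keep]
    with open(path, "wt") as fh:
        for a, v in zip(starts, vals):
            fh.write(f"{track.ref_name}\t{a}\t{a + track.bin_width}\t{float(v)!r}\n")


def load_tetrad(manifest: Mapping[str, str], bin_width: int) -> CountTetrad:
    """Load the four Pu-Seq count tracks named by ``manifest``.

    ``manifest`` maps each of the roles ``delta_watson``, ``delta_crick``,
    ``epsilon_watson``, ``epsilon_crick`` to a bedGraph path. All four
    tracks must share reference, bin width, start and length; shorter
    tracks are NOT padded — a length mismatch is an alignment error.
    """
    missing = [r for r in TETRAD_ROLES if r not in manifest]
    if missing:
        raise ConfigError(f"manifest is missing role(s): {', '.join(missing)}")
    loaded = {role: read_bedgraph(manifest[role], bin_width) for role in TETRAD_ROLES}
    # extend every track to the union grid so equal-coverage files align,
    # but refuse files on different grids/references
    ref0 = loaded["delta_watson"]
    for role, t in loaded.items():
        if t.ref_name != ref0.ref_name:
            raise AlignmentError(
                f"{role}: reference {t.ref_name!r} != {ref0.ref_name!r}"
            )
        if t.start != ref0.start or t.n_bins != ref0.n_bins:
            raise AlignmentError(
                f"{role}: binning (start={t.start}, n={t.n_bins}) does not match "
                f"delta_watson (start={ref0.start}, n={ref0.n_bins})"
            )
    return CountTetrad(
        d_watson=loaded["delta_watson"],
        d_crick=loaded["delta_crick"],
        e_watson=loaded["epsilon_watson"],
        e_crick=loaded["epsilon_crick"],
    )
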