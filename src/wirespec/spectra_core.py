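"""Core domain types for line-scan Raman/SERS spectra and their I/O.

A :class:`SpectrumSet` is a matrix of intensities on a shared
:class:`WavenumberGrid` plus per-spectrum metadata (position along the
wire in micrometres, culture-model label, optional ground-truth region).
Serialization is a plain CSV dialect (comma separator, ``.`` decimal,
UTF-8, mandatory header) plus a minimal JCAMP-DX reader.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberGrid",
    "SpectrumSet",
    "SpectraFormatError",
    "default_grid",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_jcamp",
    "crop_window",
    "resample_to_grid",
]

#: Reserved metadata columns, in canonical CSV order.
META_COLUMNS = ("position_um", "model_label", "truth_region")

VALID_REGIONS = frozenset({"nucleus", "cytoplasm", "ecm"})

# Default acquisition window: 717-1827 cm^-1 with 1015 features.
DEFAULT_WINDOW = (717.0, 1827.0)
DEFAULT_N_FEATURES = 1015


class SpectraFormatError(ValueError):
    """Raised for malformed spectral files or inconsistent matrices."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly increasing wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise SpectraFormatError("grid needs at least two wavenumbers")
        if not np.all(np.isfinite(values)):
            raise SpectraFormatError("grid contains non-finite wavenumbers")
        if np.any(values <= 0):
            raise SpectraFormatError("wavenumbers must be positive")
        if np.any(np.diff(values) <= 0):
            raise SpectraFormatError("wavenumbers must be strictly increasing")

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return np.array_equal(self.values, other.values)

    @property
    def spacing(self) -> float:
        """Median grid spacing in cm^-1."""
        return float(np.median(np.diff(self.values)))

    def index_nearest(self, wavenumber: float) -> int:
        return int(np.argmin(np.abs(self.values - wavenumber)))


def default_grid(
    lo: float = DEFAULT_WINDOW[0],
    hi: float = DEFAULT_WINDOW[1],
    n: int = DEFAULT_N_FEATURES,
) -> WavenumberGrid:
    """Uniform grid over the closed acquisition window (717, 1827, 1015)."""
    return WavenumberGrid(np.linspace(lo, hi, n))


@dataclass
class SpectrumSet:
    """Matrix of spectra on a shared grid plus per-row metadata.

    Parameters
    ----------
    grid : WavenumberGrid
        Shared wavenumber axis; one column of ``intensities`` per value.
    intensities : ndarray of shape (n_spectra, n_wavenumbers)
        Intensities in arbitrary units, float64.
    position_um : ndarray or None
        Position of each spectrum along the wire, micrometres,
        non-decreasing within a scan.
    model_label : ndarray of str or None
        Culture-model label per spectrum (e.g. ``"2D"`` / ``"3D"``).
    truth_region : ndarray of str or None
        Optional generator ground truth, one of
        ``nucleus`` / ``cytoplasm`` / ``ecm``.
    """

    grid: WavenumberGrid
    intensities: np.ndarray
    position_um: np.ndarray | None = None
    model_label: np.ndarray | None = None
    truth_region: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.atleast_2d(
            np.asarray(self.intensities, dtype=np.float64)
        )
        n, p = self.intensities.shape
        if p != len(self.grid):
            raise SpectraFormatError(
                f"intensity matrix has {p} columns but grid has {len(self.grid)}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise SpectraFormatError("intensities contain missing/non-finite values")
        if self.position_um is not None:
            self.position_um = np.asarray(self.position_um, dtype=np.float64)
            if self.position_um.shape != (n,):
                raise SpectraFormatError("position_um length mismatch")
            if np.any(np.diff(self.position_um) < 0):
                raise SpectraFormatError("positions must be non-decreasing")
        if self.model_label is not None:
            self.model_label = np.asarray(self.model_label, dtype=object)
            if self.model_label.shape != (n,):
                raise SpectraFormatError("model_label length mismatch")
        if self.truth_region is not None:
            self.truth_region = np.asarray(self.truth_region, dtype=object)
            if self.truth_region.shape != (n,):
                raise SpectraFormatError("truth_region length mismatch")
            bad = set(self.truth_region) - VALID_REGIONS
            if bad:
                raise SpectraFormatError(f"unknown truth regions: {sorted(bad)}")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    def __len__(self) -> int:
        return self.n_spectra

    def equals(self, other: "SpectrumSet") -> bool:
        """Field-for-field equality (exact float comparison)."""
        if self.grid != other.grid:
            return False
        if not np.array_equal(self.intensities, other.intensities):
            return False
        for attr in ("position_um", "model_label", "truth_region"):
            a, b = getattr(self, attr), getattr(other, attr)
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b):
                return False
        return True

    def select(self, mask: np.ndarray) -> "SpectrumSet":
        """Subset of spectra given a boolean mask or index array."""
        return SpectrumSet(
            grid=self.grid,
            intensities=self.intensities[mask],
            position_um=None if self.position_um is None else self.position_um[mask],
            model_label=None if self.model_label is None else self.model_label[mask],
            truth_region=None
            if self.truth_region is None
            else self.truth_region[mask],
        )


def concat_sets(*sets: SpectrumSet) -> SpectrumSet:
    """Stack spectrum sets sharing an identical grid.

    Metadata fields present in every input are concatenated; fields
    missing from any input are dropped. Positions are not re-sorted, so
    the result is a labeled collection rather than a single scan.
    """
    if not sets:
        raise ValueError("need at least one set")
    grid = sets[0].grid
    for s in sets[1:]:
        if s.grid != grid:
            raise SpectraFormatError("cannot concatenate sets on different grids")

    def _cat(attr: str) -> np.ndarray | None:
        cols = [getattr(s, attr) for s in sets]
        if any(c is None for c in cols):
            return None
        return np.concatenate(cols)

    pos = _cat("position_um")
    if pos is not None and np.any(np.diff(pos) < 0):
        pos = None  # merged sets are not one monotone scan
    return SpectrumSet(
        grid=grid,
        intensities=np.vstack([s.intensities for s in sets]),
        position_um=pos,
        model_label=_cat("model_label"),
        truth_region=_cat("truth_region"),
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_spectra_csv(spectra: SpectrumSet, path) -> None:
    """Write a SpectrumSet to CSV.

    Layout: the reserved metadata columns (``position_um``,
    ``model_label``, ``truth_region``) come first, then one column per
    wavenumber with the wavenumber value as header. Uses ``repr``-exact
    float formatting so a read/write cycle is lossless.
    """
    data: dict[str, object] = {}
    data["position_um"] = (
        [""] * spectra.n_spectra
        if spectra.position_um is None
        else [repr(float(v)) for v in spectra.position_um]
    )
    data["model_label"] = (
        [""] * spectra.n_spectra
        if spectra.model_label is None
        else list(spectra.model_label)
    )
    data["truth_region"] = (
        [""] * spectra.n_spectra
        if spectra.truth_region is None
        else list(spectra.truth_region)
    )
    frame = pd.DataFrame(data)
    intensity_cols = {
        repr(float(wn)): [repr(float(v)) for v in spectra.intensities[:, j]]
        for j, wn in enumerate(spectra.grid.values)
    }
    frame = pd.concat([frame, pd.DataFrame(intensity_cols)], axis=1)
    frame.to_csv(path, index=False, encoding="utf-8")


def read_spectra_csv(path) -> SpectrumSet:
    """Read a CSV written by :func:`write_spectra_csv`.

    The header row carries the wavenumbers; the reserved metadata columns
    precede the intensity columns. Round-trips bit-exactly for values
    written with ``repr``.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    cols = list(frame.columns)
    n_meta = 0
    for c in cols:
        if c in META_COLUMNS:
            n_meta += 1
        else:
            break
    wn_cols = cols[n_meta:]
    if not wn_cols:
        raise SpectraFormatError("no wavenumber columns found")
    try:
        wavenumbers = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavenumber header: {exc}") from exc
    grid = WavenumberGrid(wavenumbers)  # validates monotonicity/positivity
    try:
        intensities = frame[wn_cols].to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric intensity value: {exc}") from exc

    def _meta(name: str) -> np.ndarray | None:
        if name not in frame.columns:
            return None
        col = frame[name].to_numpy(dtype=object)
        if all(v == "" for v in col):
            return None
        return col

    pos = _meta("position_um")
    if pos is not None:
        pos = np.array([float(v) for v in pos])
    return SpectrumSet(
        grid=grid,
        intensities=intensities,
        position_um=pos,
        model_label=_meta("model_label"),
        truth_region=_meta("truth_region"),
    )


# ---------------------------------------------------------------------------
# JCAMP-DX reader (minimal: XYDATA=(X++(Y..Y)) and XYPOINTS=(XY..XY), AFFN)
# ---------------------------------------------------------------------------

_LDR_RE = re.compile(r"^##\s*([^=]+?)\s*=\s*(.*)$")
_NUM_RE = re.compile(r"[+-]?\d+(?:\.\d*)?(?:[eE][+-]?\d+)?")


def _parse_jcamp_block(lines: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Extract (x, y) arrays from the label-data-records of one block."""
    meta: dict[str, str] = {}
    data_mode: str | None = None
    xs: list[float] = []
    ys: list[float] = []
    for line in lines:
        line = line.split("$$")[0].rstrip()  # strip comments
        if not line:
            continue
        m = _LDR_RE.match(line)
        if m:
            key = m.group(1).upper().replace(" ", "")
            val = m.group(2).strip()
            if key in ("XYDATA", "XYPOINTS", "PEAKTABLE"):
                data_mode = "xyxy" if "XY..XY" in val.upper() else "xpp"
                continue
            data_mode = None
            meta[key] = val
            continue
        if data_mode is None:
            continue
        nums = [float(t) for t in _NUM_RE.findall(line)]
        if not nums:
            continue
        if data_mode == "xyxy":
            if len(nums) % 2:
                raise SpectraFormatError("odd token count in (XY..XY) line")
            xs.extend(nums[0::2])
            ys.extend(nums[1::2])
        else:  # (X++(Y..Y)): first number is the line's abscissa
            x0 = nums[0]
            yvals = nums[1:]
            if not yvals:
                continue
            deltax = _jcamp_deltax(meta)
            xs.extend(x0 + deltax * np.arange(len(yvals)))
            ys.extend(yvals)
    if not xs:
        raise SpectraFormatError("JCAMP block without XYDATA/XYPOINTS")
    x = np.asarray(xs, dtype=np.float64) * float(meta.get("XFACTOR", 1.0))
    y = np.asarray(ys, dtype=np.float64) * float(meta.get("YFACTOR", 1.0))
    order = np.argsort(x)
    return x[order], y[order]


def _jcamp_deltax(meta: dict[str, str]) -> float:
    if "DELTAX" in meta:
        return float(meta["DELTAX"])
    try:
        first = float(meta["FIRSTX"])
        last = float(meta["LASTX"])
        npts = int(float(meta["NPOINTS"]))
    except KeyError as exc:
        raise SpectraFormatError(
            "cannot infer DELTAX: need DELTAX or FIRSTX/LASTX/NPOINTS"
        ) from exc
    if npts < 2:
        raise SpectraFormatError("NPOINTS must be >= 2")
    return (last - first) / (npts - 1)


def read_jcamp(path) -> SpectrumSet:
    """Read a single- or multi-block JCAMP-DX file.

    Each ``##TITLE`` starts a block; one spectrum per block. If the
    blocks carry different abscissas, all spectra are linearly
    interpolated onto a common grid spanning the overlap of the block
    ranges, at the finest block spacing.
    """
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        lines = fh.read().splitlines()
    blocks: list[list[str]] = []
    current: list[str] | None = None
    for line in lines:
        m = _LDR_RE.match(line.split("$$")[0].rstrip())
        if m and m.group(1).upper().replace(" ", "") == "TITLE":
            if current:
                blocks.append(current)
            current = []
        if current is not None:
            current.append(line)
    if current:
        blocks.append(current)
    if not blocks:
        raise SpectraFormatError("no JCAMP blocks (##TITLE) found")

    parsed = [_parse_jcamp_block(b) for b in blocks]
    x0 = parsed[0][0]
    if all(np.array_equal(x, x0) for x, _ in parsed):
        grid = WavenumberGrid(x0)
        return SpectrumSet(grid=grid, intensities=np.vstack([y for _, y in parsed]))
    # differing abscissas: common grid over the overlapping range
    lo = max(x.min() for x, _ in parsed)
    hi = min(x.max() for x, _ in parsed)
    if hi <= lo:
        raise SpectraFormatError("JCAMP blocks have disjoint wavenumber ranges")
    step = min(float(np.median(np.diff(x))) for x, _ in parsed)
    n = max(2, int(np.floor((hi - lo) / step)) + 1)
    grid = WavenumberGrid(np.linspace(lo, lo + step * (n - 1), n))
    rows = [np.interp(grid.values, x, y) for x, y in parsed]
    return SpectrumSet(grid=grid, intensities=np.vstack(rows))


# ---------------------------------------------------------------------------
# Window cropping and resampling
# ---------------------------------------------------------------------------

def crop_window(spectra: SpectrumSet, lo: float, hi: float) -> SpectrumSet:
    """Retain wavenumber columns with ``lo <= nu <= hi`` (closed interval)."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    mask = (spectra.grid.values >= lo) & (spectra.grid.values <= hi)
    if not mask.any():
        raise SpectraFormatError(f"no grid points inside [{lo}, {hi}]")
    return SpectrumSet(
        grid=WavenumberGrid(spectra.grid.values[mask]),
        intensities=spectra.intensities[:, mask],
        position_um=spectra.position_um,
        model_label=spectra.model_label,
        truth_region=spectra.truth_region,
    )


def resample_to_grid(spectra: SpectrumSet, grid: WavenumberGrid) -> SpectrumSet:
    """Linearly interpolate every spectrum onto ``grid``.

    The target grid must lie inside the source range; extrapolation is
    refused.
    """
    src = spectra.grid.values
    if grid.values[0] < src[0] or grid.values[-1] > src[-1]:
        raise ValueError(
            f"target grid [{grid.values[0]}, {grid.values[-1]}] exceeds "
            f"source range [{src[0]}, {src[-1]}] (no extrapolation)"
        )
    if grid == spectra.grid:
        rows = spectra.intensities.copy()
    else:
        rows = np.vstack(
            [np.interp(grid.values, src, row) for row in spectra.intensities]
        )
    return SpectrumSet(
        grid=grid,
        intensities=rows,
        position_um=spectra.position_um,
        model_label=spectra.model_label,
        truth_region=spectra.truth_region,
    )
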