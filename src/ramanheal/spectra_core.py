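"""Core spectrum containers and plain-text I/O.

A Raman spectrum is a pair of equal-length vectors: Raman shifts
(wavenumbers, cm^-1, strictly increasing) and intensities (arbitrary
counts).  Cohorts of spectra sharing a common wavenumber grid live in a
:class:`SpectrumSet` together with per-spectrum sample metadata (treatment
group, observation day, mouse and measurement point).

File formats are deliberately plain:

* one spectrum per two-column whitespace/comma-delimited text file, with
  optional ``# key=value`` header lines carrying metadata;
* cohorts as long-form CSV with columns
  ``group, day, mouse_id, point_id, wavenumber, intensity``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "WOUND_GROUPS",
    "DEFAULT_DAYS",
    "ACQUISITION_RANGE",
    "SpectrumFormatError",
    "GridMismatchError",
    "SampleMeta",
    "RamanSpectrum",
    "SpectrumSet",
    "read_spectrum",
    "write_spectrum",
    "read_cohort",
    "write_cohort",
    "resample_to_grid",
    "common_grid",
]

#: Treatment arms: untreated diabetic control, low-dose photodynamic therapy
#: with 5-aminolevulinic acid or methylene blue at 1 or 4 J/cm^2, plus intact
#: healthy skin used as the reference state.
WOUND_GROUPS = ("control", "ALA1", "ALA4", "MB1", "MB4")
GROUPS = WOUND_GROUPS + ("healthy",)

#: Observation days after wounding used throughout by default.
DEFAULT_DAYS = (1, 3, 7, 14)

#: Acquisition range of the spectrometer, cm^-1.
ACQUISITION_RANGE = (100.0, 3500.0)


class SpectrumFormatError(ValueError):
    """A spectrum or cohort file could not be parsed."""


class GridMismatchError(ValueError):
    """Spectra do not share a wavenumber grid and resampling was disabled."""


@dataclass(frozen=True)
class SampleMeta:
    """Provenance of one measured (or simulated) spectrum.

    Healthy-skin spectra carry no observation day (``day is None``); wound
    spectra carry the day after wounding as a positive integer.
    """

    group: str
    day: int | None = None
    mouse_id: str = "unspecified"
    point_id: str = "unspecified"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )
        if self.group == "healthy":
            if self.day is not None:
                raise ValueError("healthy samples carry no observation day")
        else:
            if self.day is None:
                raise ValueError(f"wound sample in group {self.group!r} needs a day")
            if int(self.day) != self.day or self.day <= 0:
                raise ValueError(f"day must be a positive integer, got {self.day!r}")

    def matches(self, group: str | None = None, day: int | None = None) -> bool:
        if group is not None and self.group != group:
            return False
        if day is not None and self.day != day:
            return False
        return True


@dataclass(frozen=True)
class RamanSpectrum:
    """One spectrum: strictly increasing wavenumber axis plus intensities."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: SampleMeta = field(default_factory=lambda: SampleMeta("healthy"))

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)
        if w.ndim != 1 or y.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if w.size != y.size:
            raise ValueError(
                f"axis length {w.size} != intensity length {y.size}"
            )
        if w.size < 2:
            raise ValueError("a spectrum needs at least two channels")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        lo, hi = ACQUISITION_RANGE
        if w[0] < lo or w[-1] > hi:
            raise ValueError(
                f"wavenumbers outside acquisition range [{lo}, {hi}] cm^-1"
            )

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, intensities: np.ndarray) -> "RamanSpectrum":
        return RamanSpectrum(self.wavenumbers, intensities, self.meta)

    def crop(self, lo: float, hi: float) -> "RamanSpectrum":
        """Restrict to the closed wavenumber interval [lo, hi]."""
        mask = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        if mask.sum() < 2:
            raise ValueError(f"range [{lo}, {hi}] covers fewer than 2 channels")
        return RamanSpectrum(self.wavenumbers[mask], self.intensities[mask], self.meta)


@dataclass(frozen=True)
class SpectrumSet:
    """A cohort of spectra on one shared wavenumber grid.

    ``matrix`` has one row per spectrum, one column per grid channel;
    ``metas`` holds one :class:`SampleMeta` per row.
    """

    grid: np.ndarray
    matrix: np.ndarray
    metas: tuple[SampleMeta, ...]

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        m = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "metas", tuple(self.metas))
        if not np.all(np.diff(g) > 0):
            raise ValueError("grid must be strictly increasing")
        if m.shape[1] != g.size:
            raise ValueError(
                f"matrix has {m.shape[1]} columns but grid has {g.size} channels"
            )
        if m.shape[0] != len(self.metas):
            raise ValueError(
                f"{m.shape[0]} spectra but {len(self.metas)} metadata entries"
            )

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def spectra(self) -> Iterator[RamanSpectrum]:
        for row, meta in zip(self.matrix, self.metas):
            yield RamanSpectrum(self.grid, row, meta)

    def indices(
        self,
        group: str | None = None,
        day: int | None = None,
        where: Callable[[SampleMeta], bool] | None = None,
    ) -> np.ndarray:
        keep = []
        for i, meta in enumerate(self.metas):
            if not meta.matches(group, day):
                continue
            if where is not None and not where(meta):
                continue
            keep.append(i)
        return np.asarray(keep, dtype=int)

    def select(
        self,
        group: str | None = None,
        day: int | None = None,
        where: Callable[[SampleMeta], bool] | None = None,
    ) -> "SpectrumSet":
        idx = self.indices(group, day, where)
        if idx.size == 0:
            raise ValueError(f"no spectra match group={group!r} day={day!r}")
        return self.take(idx)

    def take(self, idx: Sequence[int]) -> "SpectrumSet":
        idx = np.asarray(idx, dtype=int)
        return SpectrumSet(self.grid, self.matrix[idx], [self.metas[i] for i in idx])

    def crop(self, lo: float, hi: float) -> "SpectrumSet":
        mask = (self.grid >= lo) & (self.grid <= hi)
        if mask.sum() < 2:
            raise ValueError(f"range [{lo}, {hi}] covers fewer than 2 channels")
        return SpectrumSet(self.grid[mask], self.matrix[:, mask], self.metas)

    def to_long(self) -> pd.DataFrame:
        """Long-form table with one row per (spectrum, channel)."""
        frames = []
        for row, meta in zip(self.matrix, self.metas):
            frames.append(
                pd.DataFrame(
                    {
                        "group": meta.group,
                        "day": meta.day if meta.day is not None else pd.NA,
                        "mouse_id": meta.mouse_id,
                        "point_id": meta.point_id,
                        "wavenumber": self.grid,
                        "intensity": row,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_spectra(
        cls,
        spectra: Iterable[RamanSpectrum],
        grid: np.ndarray | None = None,
        resample: bool = False,
    ) -> "SpectrumSet":
        spectra = list(spectra)
        if not spectra:
            raise ValueError("cannot build a SpectrumSet from zero spectra")
        if grid is None:
            grid = spectra[0].wavenumbers
            if not all(np.array_equal(s.wavenumbers, grid) for s in spectra):
                if not resample:
                    raise GridMismatchError(
                        "spectra are on different grids; pass resample=True "
                        "or a target grid"
                    )
                grid = common_grid(spectra)
        rows = []
        for s in spectra:
            if np.array_equal(s.wavenumbers, grid):
                rows.append(s.intensities)
            elif resample:
                rows.append(resample_to_grid(s, grid).intensities)
            else:
                raise GridMismatchError(
                    "spectrum grid differs from target and resample=False"
                )
        return cls(np.asarray(grid, dtype=float), np.vstack(rows), [s.meta for s in spectra])


# ---------------------------------------------------------------------------
# grid handling


def common_grid(spectra: Iterable[RamanSpectrum], step: float = 1.0) -> np.ndarray:
    """Shared 1 cm^-1 (by default) grid over the intersection of all spans."""
    spectra = list(spectra)
    lo = max(s.wavenumbers[0] for s in spectra)
    hi = min(s.wavenumbers[-1] for s in spectra)
    if hi - lo < step:
        raise ValueError("spectra spans do not overlap enough for a common grid")
    start = np.ceil(lo / step) * step
    n = int(np.floor((hi - start) / step + 1e-9)) + 1
    return start + step * np.arange(n)


def resample_to_grid(s: RamanSpectrum, grid: np.ndarray) -> RamanSpectrum:
    """Linearly interpolate a spectrum onto ``grid``.

    Values at abscissae shared with the original axis are unchanged; the
    target grid must lie within the span of the data (no extrapolation).
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] < s.wavenumbers[0] or grid[-1] > s.wavenumbers[-1]:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] extends beyond data span "
            f"[{s.wavenumbers[0]}, {s.wavenumbers[-1]}]; refusing to extrapolate"
        )
    if np.array_equal(grid, s.wavenumbers):
        return s
    y = np.interp(grid, s.wavenumbers, s.intensities)
    return RamanSpectrum(grid, y, s.meta)


# ---------------------------------------------------------------------------
# single-spectrum text I/O

_META_KEYS = ("group", "day", "mouse_id", "point_id")


def read_spectrum(path: str | Path) -> RamanSpectrum:
    """Read one spectrum from two-column text.

    ``#``-prefixed header lines of the form ``key=value`` populate the sample
    metadata; data rows are ``wavenumber intensity`` separated by whitespace
    and/or a comma.  Rows may appear in any order; the result is sorted
    ascending in wavenumber.
    """
    header: dict[str, str] = {}
    w, y = [], []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(\w+)\s*=\s*(.*)$", line)
                if m:
                    header[m.group(1)] = m.group(2).strip()
                continue
            parts = re.split(r"[,\s]+", line)
            if len(parts) < 2:
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: expected two columns, got {line!r}"
                )
            try:
                w.append(float(parts[0]))
                y.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: non-numeric row {line!r}"
                ) from exc
    if len(w) < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 data rows")
    order = np.argsort(w, kind="stable")
    meta = _meta_from_header(header)
    return RamanSpectrum(np.asarray(w)[order], np.asarray(y)[order], meta)


def _meta_from_header(header: dict[str, str]) -> SampleMeta:
    kwargs: dict = {}
    if "group" in header:
        kwargs["group"] = header["group"]
    else:
        kwargs["group"] = "healthy"
    day = header.get("day", "")
    if day not in ("", "None", "NA"):
        kwargs["day"] = int(day)
    for key in ("mouse_id", "point_id"):
        if key in header:
            kwargs[key] = header[key]
    return SampleMeta(**kwargs)


def write_spectrum(path: str | Path, s: RamanSpectrum) -> None:
    """Write one spectrum as two-column text with a metadata header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# group={s.meta.group}\n")
        if s.meta.day is not None:
            fh.write(f"# day={s.meta.day}\n")
        fh.write(f"# mouse_id={s.meta.mouse_id}\n")
        fh.write(f"# point_id={s.meta.point_id}\n")
        for wi, yi in zip(s.wavenumbers, s.intensities):
            fh.write(f"{wi:.17g} {yi:.17g}\n")


# ---------------------------------------------------------------------------
# cohort CSV I/O

_COHORT_COLUMNS = ["group", "day", "mouse_id", "point_id", "wavenumber", "intensity"]


def read_cohort(path: str | Path | io.IOBase, resample: bool = False) -> SpectrumSet:
    """Read a long-form cohort CSV into a :class:`SpectrumSet`.

    Each unique (group, day, mouse_id, point_id) combination defines one
    spectrum.  All spectra must share one grid unless ``resample=True``, in
    which case they are linearly interpolated onto the intersection grid.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SpectrumFormatError(f"cohort CSV lacks columns {missing}")
    if df.empty:
        raise SpectrumFormatError("cohort CSV contains no data rows")
    bad = set(df["group"].unique()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")

    spectra = []
    for (group, day, mouse, point), sub in df.groupby(
        ["group", "day", "mouse_id", "point_id"], dropna=False, sort=True
    ):
        day_val = None if pd.isna(day) else int(day)
        meta = SampleMeta(group=str(group), day=day_val, mouse_id=str(mouse), point_id=str(point))
        sub = sub.sort_values("wavenumber")
        spectra.append(
            RamanSpectrum(sub["wavenumber"].to_numpy(), sub["intensity"].to_numpy(), meta)
        )
    # deterministic ordering: group (canonical order), day, mouse, point
    spectra.sort(
        key=lambda s: (
            GROUPS.index(s.meta.group),
            -1 if s.meta.day is None else s.meta.day,
            s.meta.mouse_id,
            s.meta.point_id,
        )
    )
    return SpectrumSet.from_spectra(spectra, resample=resample)


def write_cohort(path: str | Path | io.IOBase, sset: SpectrumSet) -> None:
    """Write a cohort as long-form CSV with deterministic column order."""
    df = sset.to_long()
    df.to_csv(path, index=False, float_format="%.17g", columns=_COHORT_COLUMNS)
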