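"""Electrode montages on a sparse 2D grid.

Multichannel EEG has no native image structure; to expose the spatial
arrangement of the scalp electrodes to a convolutional model, each named
channel of an extended 10-20 montage is assigned to one cell of a small
integer grid (9x9 for the packaged 62-channel layout, anterior row first,
left hemisphere in low column indices).  A single time sample then lifts to
a *sparse frame*: a grid holding one amplitude per occupied cell and a mask
marking which cells carry data.  Unoccupied cells carry no value — 0 uV is a
legitimate amplitude, so absence is encoded in the mask, never as a fill
number.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "ElectrodeMap",
    "RawRecording",
    "SparseFrame",
    "MontageError",
    "load_montage",
    "frame_from_sample",
    "BUILTIN_MONTAGES",
]


class MontageError(ValueError):
    """Raised for an invalid channel-to-grid assignment."""


BUILTIN_MONTAGES = {"seed62": "seed62_9x9.tsv"}


@dataclass(frozen=True)
class ElectrodeMap:
    """Injective assignment of named channels to cells of a 2D grid.

    Parameters
    ----------
    channel_names
        Ordered channel labels (e.g. ``FP1``, ``FPZ``, ... ``CB2``).
    grid_coords
        Per-channel 0-based ``(row, col)`` pairs, same order as
        ``channel_names``; row 0 is anterior.
    grid_shape
        ``(rows, cols)`` of the grid, default ``(9, 9)``.
    """

    channel_names: tuple[str, ...]
    grid_coords: tuple[tuple[int, int], ...]
    grid_shape: tuple[int, int] = (9, 9)
    _index: dict[str, int] = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        if len(self.channel_names) != len(self.grid_coords):
            raise MontageError(
                f"{len(self.channel_names)} channel names but "
                f"{len(self.grid_coords)} grid coordinates"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            dupes = {n for n in self.channel_names if self.channel_names.count(n) > 1}
            raise MontageError(f"duplicate channel names: {sorted(dupes)}")
        rows, cols = self.grid_shape
        seen: dict[tuple[int, int], str] = {}
        for name, (r, c) in zip(self.channel_names, self.grid_coords):
            if not (0 <= r < rows and 0 <= c < cols):
                raise MontageError(
                    f"channel {name} at ({r}, {c}) lies outside the "
                    f"{rows}x{cols} grid"
                )
            if (r, c) in seen:
                raise MontageError(
                    f"channels {seen[r, c]} and {name} both mapped to cell ({r}, {c})"
                )
            seen[r, c] = name
        object.__setattr__(
            self, "_index", {n: i for i, n in enumerate(self.channel_names)}
        )

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def coord_of(self, name: str) -> tuple[int, int]:
        try:
            return self.grid_coords[self._index[name]]
        except KeyError:
            raise KeyError(f"unknown channel name: {name!r}") from None

    def coords_array(self) -> np.ndarray:
        """(n_channels, 2) integer array of (row, col)."""
        return np.asarray(self.grid_coords, dtype=np.intp)

    def mask(self) -> np.ndarray:
        """Boolean grid, True at occupied cells."""
        m = np.zeros(self.grid_shape, dtype=bool)
        rc = self.coords_array()
        m[rc[:, 0], rc[:, 1]] = True
        return m

    def content_hash(self) -> str:
        """Stable hex digest of the mapping (used to tag encoded artifacts)."""
        import hashlib

        payload = "\n".join(
            f"{n}\t{r}\t{c}" for n, (r, c) in zip(self.channel_names, self.grid_coords)
        ) + f"\n{self.grid_shape[0]}x{self.grid_shape[1]}"
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_file(self, path: str | Path) -> None:
        """Write the plain-text mapping file (NAME<TAB>row<TAB>col)."""
        with open(path, "w") as fh:
            fh.write(f"# grid {self.grid_shape[0]} {self.grid_shape[1]}\n")
            for name, (r, c) in zip(self.channel_names, self.grid_coords):
                fh.write(f"{name}\t{r}\t{c}\n")


def _parse_montage_text(text: str) -> ElectrodeMap:
    names: list[str] = []
    coords: list[tuple[int, int]] = []
    grid_shape = (9, 9)
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.strip()
        if line.startswith("# grid "):
            parts = line.split()
            grid_shape = (int(parts[2]), int(parts[3]))
            continue
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 3:
            raise MontageError(f"line {lineno}: expected NAME<TAB>row<TAB>col, got {line!r}")
        names.append(parts[0])
        coords.append((int(parts[1]), int(parts[2])))
    if not names:
        raise MontageError("montage file defines no channels")
    return ElectrodeMap(tuple(names), tuple(coords), grid_shape)


def load_montage(spec: str | Path) -> ElectrodeMap:
    """Load a montage by built-in name or from a mapping file.

    ``spec`` may be a packaged montage name (``"seed62"``: 62 channels on a
    9x9 grid) or the path of a plain-text mapping file with one
    ``NAME<TAB>row<TAB>col`` line per channel (``#`` comments allowed; an
    optional ``# grid R C`` line overrides the default 9x9 shape).
    """
    spec_str = str(spec)
    if spec_str in BUILTIN_MONTAGES:
        text = (
            resources.files("eegcube.data")
            .joinpath(BUILTIN_MONTAGES[spec_str])
            .read_text()
        )
        return _parse_montage_text(text)
    path = Path(spec)
    if not path.exists():
        raise KeyError(
            f"unknown montage {spec_str!r}: not a builtin "
            f"({sorted(BUILTIN_MONTAGES)}) and no such file"
        )
    return _parse_montage_text(path.read_text())


@dataclass
class RawRecording:
    """One trial of multichannel EEG: a channels x samples matrix in uV.

    Row order must match the :class:`ElectrodeMap` used downstream.  The
    label is an integer emotion class, constant over the trial.
    """

    data: np.ndarray
    fs: float
    label: int = -1
    subject_id: int = 0
    session_id: int = 0
    trial_id: int = 0
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2D (channels x samples), got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    def reordered(self, montage: ElectrodeMap) -> "RawRecording":
        """Return a copy with rows permuted into the montage's channel order.

        Requires ``channel_names``; raises if any montage channel is absent.
        """
        if self.channel_names is None:
            raise ValueError("recording carries no channel names to reorder by")
        index = {n.upper(): i for i, n in enumerate(self.channel_names)}
        try:
            order = [index[n.upper()] for n in montage.channel_names]
        except KeyError as exc:
            raise KeyError(f"recording lacks montage channel {exc.args[0]!r}") from None
        return RawRecording(
            self.data[order],
            self.fs,
            label=self.label,
            subject_id=self.subject_id,
            session_id=self.session_id,
            trial_id=self.trial_id,
            channel_names=montage.channel_names,
        )


@dataclass
class SparseFrame:
    """One time sample on the electrode grid: values plus an occupancy mask."""

    values: np.ndarray
    mask: np.ndarray
    t_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")


def frame_from_sample(
    recording: RawRecording, t: int, montage: ElectrodeMap
) -> SparseFrame:
    """Lift sample ``t`` of a recording onto the montage grid.

    Cell ``montage.grid_coords[n]`` receives channel ``n``'s amplitude at
    sample ``t``; all other cells are masked out (their numeric content is
    NaN and must never be read).
    """
    if recording.n_channels != montage.n_channels:
        raise ValueError(
            f"recording has {recording.n_channels} channels, montage maps "
            f"{montage.n_channels}"
        )
    if not (0 <= t < recording.n_samples):
        raise IndexError(
            f"sample index {t} out of range [0, {recording.n_samples})"
        )
    values = np.full(montage.grid_shape, np.nan)
    rc = montage.coords_array()
    values[rc[:, 0], rc[:, 1]] = recording.data[:, t]
    return SparseFrame(values, montage.mask(), t_index=t)
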