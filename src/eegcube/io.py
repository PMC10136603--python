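"""Reading EEG trials from EDF, MATLAB MAT and CSV containers."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .montage import RawRecording

__all__ = ["read_edf", "read_mat", "read_csv", "read_recordings"]


def read_edf(path: str | Path, label: int = -1, **ids) -> RawRecording:
    """Read a multichannel EDF file into a single :class:`RawRecording`.

    Uses mne's native EDF reader; all channels are returned in file order
    with their EDF labels, amplitudes converted to microvolts.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    data = raw.get_data() * 1e6  # mne loads EEG in volts
    return RawRecording(
        data,
        fs=float(raw.info["sfreq"]),
        label=label,
        channel_names=tuple(raw.ch_names),
        **ids,
    )


def read_mat(
    path: str | Path,
    trial_key: str | None = None,
    label: int = -1,
    fs: float = 200.0,
    **ids,
) -> RawRecording | dict[str, RawRecording]:
    """Read MAT trials (one channels x samples matrix per variable).

    Recognized auxiliary variables: ``channel_names`` (cell/char array),
    ``fs`` (scalar), ``label``/``labels`` (scalar or one per trial).  With
    ``trial_key`` given, returns that single trial; otherwise a dict of all
    trial matrices keyed by variable name.
    """
    from scipy.io import loadmat

    raw = loadmat(str(path), squeeze_me=True)
    names = raw.pop("channel_names", None)
    if names is not None:
        names = tuple(str(n).strip() for n in np.atleast_1d(names))
    fs = float(np.squeeze(raw.pop("fs", fs)))
    labels = raw.pop("labels", raw.pop("label", label))
    trial_vars = {
        k: v
        for k, v in raw.items()
        if not k.startswith("__") and isinstance(v, np.ndarray) and v.ndim == 2
    }
    if not trial_vars:
        raise ValueError(f"{path}: no 2D trial matrices found")

    def build(key: str, lab) -> RawRecording:
        return RawRecording(
            trial_vars[key], fs=fs, label=int(lab), channel_names=names, **ids
        )

    if trial_key is not None:
        if trial_key not in trial_vars:
            raise KeyError(f"{path}: no trial variable {trial_key!r}")
        lab = labels if np.ndim(labels) == 0 else np.atleast_1d(labels)[
            sorted(trial_vars).index(trial_key)
        ]
        return build(trial_key, lab)
    keys = sorted(trial_vars)
    labs = (
        [labels] * len(keys) if np.ndim(labels) == 0 else list(np.atleast_1d(labels))
    )
    return {k: build(k, lab) for k, lab in zip(keys, labs)}


def read_csv(
    path: str | Path, fs: float = 200.0, label: int = -1, **ids
) -> RawRecording:
    """Read a CSV trial: rows = channels; optional first column of names."""
    import pandas as pd

    df = pd.read_csv(path, header=None)
    names = None
    first = df.iloc[:, 0]
    if first.dtype == object:
        names = tuple(str(n).strip() for n in first)
        df = df.iloc[:, 1:]
    return RawRecording(
        df.to_numpy(dtype=np.float64), fs=fs, label=label, channel_names=names, **ids
    )


def read_recordings(path: str | Path, **kwargs) -> list[RawRecording]:
    """Dispatch on file suffix (.edf / .mat / .csv) and return trials."""
    suffix = Path(path).suffix.lower()
    if suffix == ".edf":
        return [read_edf(path, **kwargs)]
    if suffix == ".mat":
        out = read_mat(path, **kwargs)
        return [out] if isinstance(out, RawRecording) else [out[k] for k in sorted(out)]
    if suffix == ".csv":
        return [read_csv(path, **kwargs)]
    raise ValueError(f"unsupported EEG container: {suffix!r} (expected .edf/.mat/.csv)")
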