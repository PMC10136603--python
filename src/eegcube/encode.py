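"""Spatio-temporal encoding of EEG into dense 3D blocks.

Each time sample of a trial is lifted onto the electrode grid
(:func:`~eegcube.montage.frame_from_sample`), the unoccupied cells are
filled by Gaussian radial-basis-function interpolation, the dense frame is
resized (bilinear, align-corners) from the native grid — 9x9 for the
packaged montage — to the model's spatial resolution (64x64 by default),
and ``w`` consecutive frames are stacked into one spatio-temporal block
``S = [f_t, ..., f_{t+w-1}]``.  The model input is the block replicated on
three leading channels, mirroring the RGB input layout the backbone expects.

RBF interpolation is scattered-data interpolation
``s(x) = sum_i w_i * phi(||x - x_i||)`` with the Gaussian kernel
``phi(r) = exp(-(eps*r)^2)``; the weights solve the square kernel system at
the electrode cells, so the interpolant reproduces the measured amplitudes
at those cells exactly (node exactness).  The kernel system depends only on
the occupancy pattern and ``eps``, so its solve is computed once per montage
and reused for every frame as a single matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .montage import ElectrodeMap, RawRecording, SparseFrame

__all__ = [
    "DenseFrame",
    "Block",
    "ModelInput",
    "FrameEncoder",
    "interpolate_frame",
    "resize_frame",
    "build_blocks",
    "triplicate",
    "n_blocks",
    "save_blocks",
    "load_blocks",
    "BlockArray",
]

RESIZE_CONVENTION = "bilinear-align-corners"


class InterpolationError(RuntimeError):
    """Raised when the RBF kernel system is singular or ill-conditioned."""


@dataclass
class DenseFrame:
    """A fully-populated H x W frame at one time sample."""

    values: np.ndarray
    t_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dense frame contains non-finite values")


@dataclass
class Block:
    """w x H x W stack of dense frames, time-major, with provenance."""

    frames: np.ndarray
    fs: float
    label: int = -1
    subject_id: int = 0
    session_id: int = 0
    trial_id: int = 0
    start_sample: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"block must be w x H x W, got shape {self.frames.shape}")

    @property
    def w(self) -> int:
        return self.frames.shape[0]


@dataclass
class ModelInput:
    """3 x w x H x W tensor: the block copied onto three input channels."""

    tensor: np.ndarray


def _gaussian(r2: np.ndarray, epsilon: float) -> np.ndarray:
    return np.exp(-(epsilon**2) * r2)


def _pairwise_sq(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


def _interp_operator(
    node_coords: np.ndarray, grid_shape: tuple[int, int], epsilon: float
) -> np.ndarray:
    """(rows*cols) x n_nodes matrix mapping node values to the dense grid."""
    nodes = node_coords.astype(np.float64)
    K = _gaussian(_pairwise_sq(nodes, nodes), epsilon)
    cond = np.linalg.cond(K)
    if not np.isfinite(cond) or cond > 1e12:
        raise InterpolationError(
            f"Gaussian RBF kernel matrix is ill-conditioned (cond={cond:.3g}) "
            f"for epsilon={epsilon}; increase epsilon or reduce node density"
        )
    rr, cc = np.mgrid[0 : grid_shape[0], 0 : grid_shape[1]]
    eval_pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    Phi = _gaussian(_pairwise_sq(eval_pts, nodes), epsilon)
    try:
        return np.linalg.solve(K.T, Phi.T).T
    except np.linalg.LinAlgError as exc:
        raise InterpolationError(f"singular RBF kernel system: {exc}") from exc


def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1D bilinear resampling matrix under the align-corners convention.

    Output sample j sits at source position ``j*(n_in-1)/(n_out-1)`` and is
    the convex combination of its two bracketing input samples, so constants
    are reproduced and the output never overshoots the input range.
    """
    if n_out < 2 or n_in < 1:
        raise ValueError(f"degenerate resize: {n_in} -> {n_out}")
    M = np.zeros((n_out, n_in))
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    src = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    lo = np.minimum(src.astype(np.intp), n_in - 2)
    frac = src - lo
    M[np.arange(n_out), lo] = 1.0 - frac
    M[np.arange(n_out), lo + 1] = frac
    return M


class FrameEncoder:
    """Cached interpolate-then-resize operator for one montage.

    The composition of the RBF solve and the bilinear resize is linear in
    the channel amplitudes, so it collapses to a single
    ``(H'*W') x n_channels`` matrix applied per time sample.
    """

    def __init__(
        self,
        montage: ElectrodeMap,
        epsilon: float = 1.0,
        out_shape: tuple[int, int] = (64, 64),
    ) -> None:
        if epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {epsilon}")
        if min(out_shape) < 2:
            raise ValueError(f"output shape must be at least 2x2, got {out_shape}")
        self.montage = montage
        self.epsilon = float(epsilon)
        self.out_shape = tuple(out_shape)
        self._interp = _interp_operator(
            montage.coords_array(), montage.grid_shape, self.epsilon
        )
        self._rows = _resize_matrix(montage.grid_shape[0], out_shape[0])
        self._cols = _resize_matrix(montage.grid_shape[1], out_shape[1])

    def encode_samples(self, channel_values: np.ndarray) -> np.ndarray:
        """Encode a (n_samples, n_channels) array to (n_samples, H', W')."""
        dense = channel_values @ self._interp.T  # (n, rows*cols)
        dense = dense.reshape(-1, *self.montage.grid_shape)
        return np.einsum("ij,njk,lk->nil", self._rows, dense, self._cols)


_ENCODER_CACHE: dict[tuple, np.ndarray] = {}


def interpolate_frame(
    frame: SparseFrame,
    montage: ElectrodeMap | None = None,
    kernel: str = "gaussian",
    epsilon: float = 1.0,
) -> DenseFrame:
    """Fill a sparse frame's empty cells by Gaussian RBF interpolation.

    The nodes are the frame's occupied cells; at every node the interpolant
    equals the input value (to solver precision).  ``montage``, when given,
    is only used to validate that the frame's occupancy matches it.
    """
    if kernel != "gaussian":
        raise ValueError(f"unsupported RBF kernel {kernel!r} (only 'gaussian')")
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    mask = frame.mask
    n_nodes = int(mask.sum())
    if n_nodes == 0:
        raise ValueError("cannot interpolate a frame with zero occupied cells")
    if montage is not None and not np.array_equal(mask, montage.mask()):
        raise ValueError("frame occupancy does not match the montage")
    key = (mask.tobytes(), mask.shape, float(epsilon))
    if key not in _ENCODER_CACHE:
        node_coords = np.argwhere(mask)
        _ENCODER_CACHE[key] = _interp_operator(node_coords, mask.shape, epsilon)
    op = _ENCODER_CACHE[key]
    values = frame.values[mask]
    dense = (op @ values).reshape(mask.shape)
    return DenseFrame(dense, t_index=frame.t_index)


def resize_frame(frame: DenseFrame, out_shape: tuple[int, int]) -> DenseFrame:
    """Bilinear align-corners resize of a dense frame to ``out_shape``."""
    h, w = frame.values.shape
    R = _resize_matrix(h, out_shape[0])
    C = _resize_matrix(w, out_shape[1])
    return DenseFrame(R @ frame.values @ C.T, t_index=frame.t_index)


def n_blocks(n_samples: int, w: int, stride: int) -> int:
    """Number of full windows: floor((N - w)/stride) + 1, or 0 if N < w."""
    if w < 1 or stride < 1:
        raise ValueError("window and stride must be >= 1")
    if n_samples < w:
        return 0
    return (n_samples - w) // stride + 1


def build_blocks(
    recording: RawRecording,
    montage: ElectrodeMap,
    w: int,
    stride: int | None = None,
    epsilon: float = 1.0,
    out_shape: tuple[int, int] = (64, 64),
    normalize: bool = True,
    encoder: FrameEncoder | None = None,
) -> list[Block]:
    """Encode a recording into non-overlapping (or strided) 3D blocks.

    Block ``i`` covers samples ``[i*stride, i*stride + w)``; trailing
    samples that do not fill a window are dropped.  With ``normalize``
    (default), the recording is z-scored over all channels and samples
    before interpolation so that block amplitudes are bounded regardless of
    the recording's native scale.
    """
    if stride is None:
        stride = w
    if recording.n_channels != montage.n_channels:
        raise ValueError(
            f"recording has {recording.n_channels} channels, montage maps "
            f"{montage.n_channels}"
        )
    count = n_blocks(recording.n_samples, w, stride)
    if count == 0:
        return []
    if encoder is None:
        encoder = FrameEncoder(montage, epsilon=epsilon, out_shape=out_shape)
    data = recording.data
    if normalize:
        sd = data.std()
        data = (data - data.mean()) / (sd if sd > 0 else 1.0)
    used = (count - 1) * stride + w
    frames = encoder.encode_samples(data[:, :used].T)  # (used, H', W')
    blocks = []
    for i in range(count):
        s = i * stride
        blocks.append(
            Block(
                frames[s : s + w],
                fs=recording.fs,
                label=recording.label,
                subject_id=recording.subject_id,
                session_id=recording.session_id,
                trial_id=recording.trial_id,
                start_sample=s,
            )
        )
    return blocks


def triplicate(block: Block | np.ndarray) -> ModelInput:
    """Copy a w x H x W block onto three identical leading channels."""
    frames = block.frames if isinstance(block, Block) else np.asarray(block)
    return ModelInput(np.broadcast_to(frames, (3, *frames.shape)).copy())


@dataclass
class BlockArray:
    """A batch of encoded blocks with aligned per-block metadata."""

    blocks: np.ndarray  # (n, w, H, W)
    labels: np.ndarray
    subject: np.ndarray
    session: np.ndarray
    trial: np.ndarray
    start: np.ndarray
    fs: float
    epsilon: float = 1.0
    montage_hash: str = ""

    def __len__(self) -> int:
        return self.blocks.shape[0]

    def subset(self, idx: np.ndarray) -> "BlockArray":
        return BlockArray(
            self.blocks[idx],
            self.labels[idx],
            self.subject[idx],
            self.session[idx],
            self.trial[idx],
            self.start[idx],
            self.fs,
            self.epsilon,
            self.montage_hash,
        )

    @classmethod
    def from_blocks(cls, blocks: Sequence[Block], epsilon: float = 1.0,
                    montage_hash: str = "") -> "BlockArray":
        if not blocks:
            raise ValueError("empty block sequence")
        return cls(
            np.stack([b.frames for b in blocks]).astype(np.float32),
            np.array([b.label for b in blocks], dtype=np.int64),
            np.array([b.subject_id for b in blocks], dtype=np.int64),
            np.array([b.session_id for b in blocks], dtype=np.int64),
            np.array([b.trial_id for b in blocks], dtype=np.int64),
            np.array([b.start_sample for b in blocks], dtype=np.int64),
            fs=blocks[0].fs,
            epsilon=epsilon,
            montage_hash=montage_hash,
        )


def save_blocks(path, arr: BlockArray) -> None:
    """Persist encoded blocks to HDF5 with their provenance attributes."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("blocks", data=arr.blocks, compression="gzip")
        for name in ("labels", "subject", "session", "trial", "start"):
            f.create_dataset(name, data=getattr(arr, name))
        f.attrs["fs"] = arr.fs
        f.attrs["w"] = arr.blocks.shape[1]
        f.attrs["epsilon"] = arr.epsilon
        f.attrs["resize"] = RESIZE_CONVENTION
        f.attrs["montage_hash"] = arr.montage_hash


def load_blocks(path) -> BlockArray:
    import h5py

    with h5py.File(path, "r") as f:
        return BlockArray(
            f["blocks"][...],
            f["labels"][...],
            f["subject"][...],
            f["session"][...],
            f["trial"][...],
            f["start"][...],
            fs=float(f.attrs["fs"]),
            epsilon=float(f.attrs["epsilon"]),
            montage_hash=str(f.attrs.get("montage_hash", "")),
        )
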