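"""From raw multichannel EEG to the two spatial feature representations.

The pipeline: band-pass filter each channel into the five canonical EEG
rhythms (delta through gamma), cut the recording into fixed-length windows,
and summarise each (channel, band, window) by its differential entropy (DE)
under a Gaussian model, ``0.5 * ln(2*pi*e*sigma^2)`` nats. The resulting
62 x 5 DE matrix is then re-expressed two ways:

* a *spatial activity map* — each electrode's band DE placed at its cell of a
  9 x 9 scalp grid (a topographic image, consumed by a convolutional branch);
* a *spatial topology graph* — electrodes as graph nodes carrying the 5-band
  DE vector, wired by a configurable adjacency (consumed by an attention
  branch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "BandScheme",
    "ElectrodeLayout",
    "RawRecording",
    "DEFeatureMatrix",
    "SpatialActivityMap",
    "SpatialTopologyGraph",
    "InvalidBandError",
    "TooShortError",
    "MissingChannelError",
    "LayoutCollisionError",
    "DegenerateSignalError",
    "bandpass_filter",
    "segment_windows",
    "differential_entropy",
    "compute_de_features",
    "build_activity_map",
    "build_adjacency",
    "build_topology_graph",
]


class InvalidBandError(ValueError):
    """Band edges fall outside (0, Nyquist) or are inverted."""


class TooShortError(ValueError):
    """Recording shorter than the operation requires."""


class MissingChannelError(KeyError):
    """Recording lacks channels the layout requires."""


class LayoutCollisionError(ValueError):
    """Two electrodes mapped to the same grid cell."""


class DegenerateSignalError(ValueError):
    """Zero-variance window: differential entropy diverges to -inf."""


DEFAULT_BANDS = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 14.0),
    ("beta", 14.0, 31.0),
    ("gamma", 31.0, 50.0),
)


@dataclass(frozen=True)
class BandScheme:
    """Ordered, non-overlapping frequency bands (Hz)."""

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS

    def __post_init__(self):
        if len(self.bands) != 5:
            raise ValueError("a band scheme has exactly 5 bands")
        prev_high = 0.0
        for name, lo, hi in self.bands:
            if not (0 < lo < hi):
                raise InvalidBandError(f"band {name}: need 0 < low < high, got {lo}-{hi}")
            if lo < prev_high:
                raise InvalidBandError(f"band {name} overlaps its predecessor")
            prev_high = hi

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    def __len__(self) -> int:
        return len(self.bands)


@dataclass(frozen=True)
class ElectrodeLayout:
    """62-electrode montage: names, 9 x 9 grid cells, planar scalp coords."""

    names: tuple[str, ...]
    grid_coords: tuple[tuple[int, int], ...]
    planar_xy: tuple[tuple[float, float], ...]
    height: int = 9
    width: int = 9
    version: str = "unversioned"

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("electrode names must be unique")
        if len(set(self.grid_coords)) != len(self.grid_coords):
            raise LayoutCollisionError("two electrodes share a grid cell")
        for r, c in self.grid_coords:
            if not (0 <= r < self.height and 0 <= c < self.width):
                raise ValueError(f"grid coordinate ({r},{c}) outside {self.height}x{self.width}")

    @classmethod
    def default(cls) -> "ElectrodeLayout":
        """The packaged 62-channel 10-20 montage on a 9 x 9 grid."""
        with resources.files("eegdann.data").joinpath("layout_9x9_v1.tsv").open() as fh:
            tab = pd.read_csv(fh, sep="\t")
        return cls(
            names=tuple(tab["name"]),
            grid_coords=tuple(zip(tab["row"].astype(int), tab["col"].astype(int))),
            planar_xy=tuple(zip(tab["x"].astype(float), tab["y"].astype(float))),
            version="layout_9x9_v1",
        )

    def __len__(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise MissingChannelError(name) from None


@dataclass
class RawRecording:
    """Channels x time matrix in microvolts with acquisition metadata."""

    samples: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str = ""
    trial_id: str = ""
    label: int | None = None
    window_index: int | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names must align with sample rows")
        if not np.isfinite(self.samples).all():
            raise ValueError("recording contains NaN/inf samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def _replace_samples(self, samples: np.ndarray) -> "RawRecording":
        return RawRecording(
            samples=samples,
            fs=self.fs,
            channel_names=list(self.channel_names),
            subject_id=self.subject_id,
            trial_id=self.trial_id,
            label=self.label,
            window_index=self.window_index,
        )


@dataclass
class DEFeatureMatrix:
    """Per-window electrodes x bands differential-entropy matrix (nats)."""

    values: np.ndarray
    window_index: int
    window_seconds: float = 4.0
    subject_id: str = ""
    trial_id: str = ""
    label: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("DE matrix must be 2-D (electrodes x bands)")
        if not np.isfinite(self.values).all():
            raise ValueError("DE matrix contains non-finite entries")


@dataclass
class SpatialActivityMap:
    """H x W x B topographic DE tensor; empty cells are exactly zero."""

    tensor: np.ndarray
    layout: ElectrodeLayout

    def __post_init__(self):
        self.tensor = np.asarray(self.tensor, dtype=np.float64)
        if self.tensor.ndim != 3:
            raise ValueError("activity map must be H x W x B")


@dataclass
class SpatialTopologyGraph:
    """Electrode graph: 62 x B node features + symmetric adjacency."""

    node_features: np.ndarray
    adjacency: np.ndarray
    edge_rule: str = "knn"
    edge_param: float | None = None

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=np.float64)
        self.adjacency = np.asarray(self.adjacency, dtype=np.float64)
        n = self.node_features.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square and match node count")
        if not np.allclose(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if (self.adjacency < 0).any():
            raise ValueError("adjacency must be non-negative")

    def neighbors(self, i: int) -> np.ndarray:
        """Indices j with an edge to node i (self-loop included)."""
        return np.flatnonzero(self.adjacency[i] > 0)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _butter_sos(low_hz: float, high_hz: float, fs: float, order: int):
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    recording: RawRecording, low_hz: float, high_hz: float, order: int = 5
) -> RawRecording:
    """Zero-phase Butterworth band-pass of every channel.

    Forward-backward application (``sosfiltfilt``) cancels the group delay so
    windows cut after filtering stay aligned with the raw time axis.
    """
    nyq = recording.fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise InvalidBandError(
            f"band {low_hz}-{high_hz} Hz invalid for fs={recording.fs} (Nyquist {nyq})"
        )
    sos = _butter_sos(low_hz, high_hz, recording.fs, order)
    # sosfiltfilt needs > 3 * (2*n_sections + 1) samples of warm-up
    padlen = 3 * (2 * sos.shape[0] + 1)
    if recording.n_samples <= padlen:
        raise TooShortError(
            f"recording has {recording.n_samples} samples; filter warm-up needs > {padlen}"
        )
    filtered = signal.sosfiltfilt(sos, recording.samples, axis=1)
    return recording._replace_samples(filtered)


def segment_windows(recording: RawRecording, window_seconds: float = 4.0) -> list[RawRecording]:
    """Cut into consecutive non-overlapping windows; the remainder is dropped."""
    win = int(round(window_seconds * recording.fs))
    if win <= 0:
        raise ValueError("window must span at least one sample")
    n = recording.n_samples // win
    if n == 0:
        raise TooShortError(
            f"recording of {recording.n_samples} samples is shorter than one "
            f"{window_seconds}-s window ({win} samples)"
        )
    out = []
    for i in range(n):
        w = recording._replace_samples(recording.samples[:, i * win : (i + 1) * win].copy())
        w.window_index = i
        out.append(w)
    return out


def differential_entropy(window_samples: np.ndarray, ddof: int = 0) -> float:
    """Gaussian differential entropy ``0.5*ln(2*pi*e*sigma^2)`` in nats.

    ``sigma^2`` is the sample variance of the band-filtered window. Exact for
    Gaussian signals; for band-limited EEG it is the standard closed-form
    surrogate for the band's log power.
    """
    x = np.asarray(window_samples, dtype=np.float64).ravel()
    if x.size < 2:
        raise TooShortError("differential entropy needs at least 2 samples")
    var = x.var(ddof=ddof)
    if var <= 0:
        raise DegenerateSignalError("zero-variance window has no finite differential entropy")
    return 0.5 * np.log(2.0 * np.pi * np.e * var)


def compute_de_features(
    recording: RawRecording,
    scheme: BandScheme | None = None,
    layout: ElectrodeLayout | None = None,
    window_seconds: float = 4.0,
    filter_order: int = 5,
) -> list[DEFeatureMatrix]:
    """Per 4-s window, the layout-ordered electrodes x bands DE matrix.

    Each channel is filtered once per band over the full recording, then the
    filtered traces are windowed, so every window sees the same filter
    transient handling.
    """
    scheme = scheme or BandScheme()
    layout = layout or ElectrodeLayout.default()
    upper = {n.upper(): i for i, n in enumerate(recording.channel_names)}
    missing = [n for n in layout.names if n.upper() not in upper]
    if missing:
        raise MissingChannelError(f"recording lacks layout channels: {missing}")
    row_order = [upper[n.upper()] for n in layout.names]
    ordered = recording._replace_samples(recording.samples[row_order])
    ordered.channel_names = list(layout.names)

    per_band = [
        bandpass_filter(ordered, lo, hi, order=filter_order).samples
        for (_, lo, hi) in scheme.bands
    ]
    win = int(round(window_seconds * recording.fs))
    n_win = ordered.n_samples // win
    if n_win == 0:
        raise TooShortError("recording shorter than one window")
    out = []
    for w in range(n_win):
        sl = slice(w * win, (w + 1) * win)
        vals = np.empty((len(layout), len(scheme)))
        for b, band_sig in enumerate(per_band):
            seg = band_sig[:, sl]
            var = seg.var(axis=1)
            if (var <= 0).any():
                raise DegenerateSignalError(f"zero-variance channel in window {w}")
            vals[:, b] = 0.5 * np.log(2.0 * np.pi * np.e * var)
        out.append(
            DEFeatureMatrix(
                values=vals,
                window_index=w,
                window_seconds=window_seconds,
                subject_id=recording.subject_id,
                trial_id=recording.trial_id,
                label=recording.label,
            )
        )
    return out


def build_activity_map(features: DEFeatureMatrix, layout: ElectrodeLayout) -> SpatialActivityMap:
    """Scatter the DE matrix onto the scalp grid, one plane per band."""
    ne, nb = features.values.shape
    if ne != len(layout):
        raise ValueError(f"feature rows ({ne}) != layout electrodes ({len(layout)})")
    tensor = np.zeros((layout.height, layout.width, nb))
    for e, (r, c) in enumerate(layout.grid_coords):
        tensor[r, c, :] = features.values[e, :]
    return SpatialActivityMap(tensor=tensor, layout=layout)


def recover_features(amap: SpatialActivityMap) -> np.ndarray:
    """Inverse lookup of :func:`build_activity_map` (injectivity check)."""
    lay = amap.layout
    return np.stack([amap.tensor[r, c, :] for (r, c) in lay.grid_coords])


def build_adjacency(
    layout: ElectrodeLayout, rule: str = "knn", param: float | None = 4
) -> np.ndarray:
    """Electrode adjacency on planar scalp coordinates.

    ``knn``: connect each electrode to its ``param`` nearest neighbours,
    symmetrised by OR. ``radius``: connect pairs closer than ``param``.
    ``full``: complete graph. All rules add unit self-loops.
    """
    n = len(layout)
    xy = np.asarray(layout.planar_xy)
    if rule == "full":
        return np.ones((n, n))
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    adj = np.zeros((n, n))
    if rule == "knn":
        k = int(param) if param is not None else 4
        if k < 0:
            raise ValueError("knn parameter k must be >= 0")
        for i in range(n):
            order = np.argsort(d[i], kind="stable")
            neigh = [j for j in order if j != i][:k]
            adj[i, neigh] = 1.0
        adj = np.maximum(adj, adj.T)  # symmetrize by OR
    elif rule == "radius":
        if param is None or param <= 0:
            raise ValueError("radius must be > 0")
        adj = ((d <= param) & (d > 0)).astype(float)
    else:
        raise ValueError(f"unknown adjacency rule {rule!r}")
    np.fill_diagonal(adj, 1.0)
    return adj


def build_topology_graph(
    features: DEFeatureMatrix, layout: ElectrodeLayout, adjacency: np.ndarray
) -> SpatialTopologyGraph:
    """Attach the layout-ordered DE matrix as node features of the graph."""
    adjacency = np.asarray(adjacency, dtype=np.float64)
    if features.values.shape[0] != len(layout):
        raise ValueError("feature rows must match layout electrodes")
    if adjacency.shape != (len(layout), len(layout)):
        raise ValueError("adjacency shape must match layout")
    return SpatialTopologyGraph(
        node_features=features.values.copy(), adjacency=adjacency.copy()
    )
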