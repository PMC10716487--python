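"""Photon-resolved data model.

A measurement is a list of detected photons, each tagged with

* a *channel* — which detector element fired (``0–24`` for the 5×5 SPAD
  array in row-major order, centre element at index 12; ``25`` for the
  auxiliary single-element detector),
* an *absolute time* — delay from the experiment start, integer nanoseconds,
* optionally a *microtime* (start–stop time) — delay from the preceding
  laser excitation pulse, the basis of TCSPC lifetime analysis.

Everything downstream (correlation, lifetime fitting, image reconstruction)
consumes this one container.  Channel merging turns the array into nested
virtual detection volumes (central element, sum 3×3, sum 5×5), which is what
makes spot-variation FCS possible from a single acquisition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import h5py
import numpy as np

__all__ = [
    "DetectorGeometry",
    "LaserConfig",
    "ScanMetadata",
    "PhotonStream",
    "IntensityTrace",
    "VOLUME_CHANNELS",
    "merge_channels",
    "bin_intensity",
    "fold_microtime",
    "write_event_list",
    "read_event_list",
]

#: channel sets of the named virtual detection volumes (5×5 row-major array)
VOLUME_CHANNELS: dict[str, tuple[int, ...]] = {
    "central": (12,),
    "sum3x3": (6, 7, 8, 11, 12, 13, 16, 17, 18),
    "sum5x5": tuple(range(25)),
    "single_element": (25,),
}

#: microtime sentinel in the on-disk uint32 picosecond column
_MICROTIME_UNSET = np.uint32(0xFFFFFFFF)

_FORMAT_VERSION = 1


class FormatError(ValueError):
    """Raised when an event-list file is malformed."""


@dataclass
class DetectorGeometry:
    """5×5 SPAD array geometry projected into the sample plane.

    ``waists`` maps the named detection volumes to their calibrated 1/e²
    lateral waists (nm); ``eccentricities`` maps them to the axial elongation
    *k* (1/e² PSF half-height = k·ω₀).  Defaults are the calibration values
    for the three nested volumes (276/330/390 nm; k = 4.5 for the central
    element, 4.1 for the summed volumes).
    """

    n_rows: int = 5
    n_cols: int = 5
    pitch_sample_nm: float = 138.0
    waists: dict = field(
        default_factory=lambda: {
            "central": 276.0,
            "sum3x3": 330.0,
            "sum5x5": 390.0,
            "single_element": 330.0,
        }
    )
    eccentricities: dict = field(
        default_factory=lambda: {
            "central": 4.5,
            "sum3x3": 4.1,
            "sum5x5": 4.1,
            "single_element": 4.1,
        }
    )

    def __post_init__(self) -> None:
        w = self.waists
        order = ["central", "sum3x3", "sum5x5"]
        vals = [w[k] for k in order if k in w]
        if any(v <= 0 for v in w.values()):
            raise ValueError("waists must be positive")
        if vals != sorted(vals):
            raise ValueError("waists must be non-decreasing central -> sum5x5")
        if any(k <= 1 for k in self.eccentricities.values()):
            raise ValueError("eccentricities must exceed 1")

    @property
    def n_channels(self) -> int:
        # array elements plus the single-element detector
        return self.n_rows * self.n_cols + 1

    @property
    def central_channel(self) -> int:
        return (self.n_rows // 2) * self.n_cols + self.n_cols // 2


@dataclass
class LaserConfig:
    """Pulsed-laser timing and IRF parameters.

    ``rep_period_ns`` — laser repetition period (default 25 ns, i.e. 40 MHz);
    ``irf_sigma_ns``/``irf_offset_ns`` — Gaussian instrument response width
    and centre; ``wavelengths_nm`` — excitation wavelength per color tag.
    """

    rep_period_ns: float = 25.0
    irf_sigma_ns: float = 0.1
    irf_offset_ns: float = 2.0
    wavelengths_nm: dict = field(default_factory=lambda: {"green": 485.0, "red": 561.0})

    def __post_init__(self) -> None:
        if self.rep_period_ns <= 0:
            raise ValueError("rep_period_ns must be positive")
        if self.irf_sigma_ns < 0:
            raise ValueError("irf_sigma_ns must be non-negative")


@dataclass
class ScanMetadata:
    """Scan trajectory of the detection volume.

    ``mode`` is one of ``point`` (parked beam), ``circular`` (circle of
    radius ``radius_nm`` and period ``period_us``, used for calibration FCS)
    or ``raster`` (``n_x``×``n_y`` pixels, row-major, unidirectional, with
    ``pixel_dwell_us`` per pixel).  For raster scans the pixel/line/frame
    clocks are derived from the absolute times and the dwell time.
    """

    mode: str = "point"
    pixel_dwell_us: float = 100.0
    n_x: int = 1
    n_y: int = 1
    pixel_size_nm: float = 50.0
    radius_nm: float = 0.0
    period_us: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("point", "circular", "raster"):
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if self.mode == "raster" and self.n_x * self.n_y < 1:
            raise ValueError("raster scan requires n_x*n_y >= 1")
        if self.mode == "circular" and self.radius_nm <= 0:
            raise ValueError("circular scan requires radius_nm > 0")


@dataclass
class PhotonStream:
    """Ordered photon event list plus acquisition metadata.

    ``channels`` (uint8), ``t_abs_ns`` (uint64, non-decreasing) and
    ``microtimes_ns`` (float64, NaN where unset) are parallel arrays — one
    entry per photon.
    """

    channels: np.ndarray
    t_abs_ns: np.ndarray
    microtimes_ns: Optional[np.ndarray]
    geometry: DetectorGeometry = field(default_factory=DetectorGeometry)
    laser: LaserConfig = field(default_factory=LaserConfig)
    scan: Optional[ScanMetadata] = None
    duration_s: float = 0.0
    #: name of the virtual volume this stream was merged into, if any
    volume: Optional[str] = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.uint8)
        self.t_abs_ns = np.asarray(self.t_abs_ns, dtype=np.uint64)
        if self.microtimes_ns is not None:
            self.microtimes_ns = np.asarray(self.microtimes_ns, dtype=np.float64)
            if self.microtimes_ns.shape != self.t_abs_ns.shape:
                raise ValueError("microtimes and t_abs must have equal length")
        if self.channels.shape != self.t_abs_ns.shape:
            raise ValueError("channels and t_abs must have equal length")
        if self.channels.size and self.channels.max() >= self.geometry.n_channels:
            raise ValueError("channel index outside declared geometry")
        if self.t_abs_ns.size and np.any(np.diff(self.t_abs_ns.astype(np.int64)) < 0):
            raise ValueError("absolute times must be non-decreasing")
        if self.duration_s <= 0 and self.t_abs_ns.size:
            self.duration_s = float(self.t_abs_ns[-1]) * 1e-9
        if self.t_abs_ns.size and self.duration_s * 1e9 < float(self.t_abs_ns[-1]) - 0.5:
            raise ValueError("duration_s shorter than the last photon time")

    def __len__(self) -> int:
        return int(self.t_abs_ns.size)

    @property
    def has_microtimes(self) -> bool:
        return self.microtimes_ns is not None

    def count_rate_hz(self) -> float:
        return len(self) / self.duration_s if self.duration_s > 0 else 0.0

    def equals(self, other: "PhotonStream") -> bool:
        """Record-for-record and metadata equality (microtimes to ps)."""
        if len(self) != len(other):
            return False
        if not np.array_equal(self.channels, other.channels):
            return False
        if not np.array_equal(self.t_abs_ns, other.t_abs_ns):
            return False
        if self.has_microtimes != other.has_microtimes:
            return False
        if self.has_microtimes and not np.allclose(
            self.microtimes_ns, other.microtimes_ns, atol=1e-3, equal_nan=True
        ):
            return False
        return (
            asdict(self.geometry) == asdict(other.geometry)
            and asdict(self.laser) == asdict(other.laser)
            and (
                (self.scan is None and other.scan is None)
                or (
                    self.scan is not None
                    and other.scan is not None
                    and asdict(self.scan) == asdict(other.scan)
                )
            )
            and abs(self.duration_s - other.duration_s) < 1e-12
            and self.volume == other.volume
        )


@dataclass
class IntensityTrace:
    """Binned intensity time trace of a photon selection."""

    bin_width_us: float
    counts: np.ndarray
    t0_us: float = 0.0
    volume: Optional[str] = None

    def __post_init__(self) -> None:
        if self.bin_width_us < 0.5:
            raise ValueError("bin width must be >= 0.5 us")
        self.counts = np.asarray(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        t = self.t0_us + (np.arange(self.counts.size) + 0.5) * self.bin_width_us
        np.savetxt(
            path,
            np.column_stack([t, self.counts]),
            delimiter=",",
            header="t_us,counts",
            comments="",
            fmt=["%.3f", "%d"],
        )


# ---------------------------------------------------------------------------
# operations


def merge_channels(stream: PhotonStream, volume: str) -> PhotonStream:
    """Merge the photons of a named virtual detection volume.

    Returns a new stream containing the time-ordered union of all photons
    whose channel belongs to the volume's channel set; the waist metadata of
    the result is the named volume's calibrated waist.
    """
    if volume not in VOLUME_CHANNELS:
        raise KeyError(f"unknown volume {volume!r}; choose from {sorted(VOLUME_CHANNELS)}")
    chans = VOLUME_CHANNELS[volume]
    mask = np.isin(stream.channels, np.asarray(chans, dtype=np.uint8))
    return PhotonStream(
        channels=stream.channels[mask],
        t_abs_ns=stream.t_abs_ns[mask],
        microtimes_ns=stream.microtimes_ns[mask] if stream.has_microtimes else None,
        geometry=stream.geometry,
        laser=stream.laser,
        scan=stream.scan,
        duration_s=stream.duration_s,
        volume=volume,
    )


def bin_intensity(stream: PhotonStream, bin_width_us: float, volume: Optional[str] = None) -> IntensityTrace:
    """Bin photon absolute times into an intensity trace.

    ``counts[i]`` is the number of photons with t_abs in ``[i·w, (i+1)·w)``.
    """
    if bin_width_us <= 0:
        raise ValueError("bin width must be positive")
    if bin_width_us < 0.5:
        raise ValueError("bin width must be >= 0.5 us")
    sel = merge_channels(stream, volume) if volume is not None else stream
    w_ns = bin_width_us * 1e3
    n_bins = max(1, int(np.ceil(stream.duration_s * 1e6 / bin_width_us)))
    idx = (sel.t_abs_ns / w_ns).astype(np.int64)
    idx = np.minimum(idx, n_bins - 1)  # photon exactly at duration boundary
    counts = np.bincount(idx, minlength=n_bins)
    return IntensityTrace(bin_width_us=bin_width_us, counts=counts, volume=volume or sel.volume)


def fold_microtime(stream: PhotonStream) -> PhotonStream:
    """Fold microtimes into one laser period (modulo the repetition period).

    TCSPC electronics can report start–stop times spanning several laser
    periods; folding them by ``rep_period_ns`` places every microtime in
    ``[0, T_rep)``.  Idempotent.
    """
    if not stream.has_microtimes:
        raise ValueError("stream has no microtimes to fold")
    t_rep = stream.laser.rep_period_ns
    folded = np.mod(stream.microtimes_ns, t_rep)
    return PhotonStream(
        channels=stream.channels,
        t_abs_ns=stream.t_abs_ns,
        microtimes_ns=folded,
        geometry=stream.geometry,
        laser=stream.laser,
        scan=stream.scan,
        duration_s=stream.duration_s,
        volume=stream.volume,
    )


# ---------------------------------------------------------------------------
# persistence (HDF5 columnar container)


def write_event_list(stream: PhotonStream, path) -> None:
    """Write a stream to the columnar event-list container.

    Layout: datasets ``channel`` (uint8), ``t_abs`` (uint64, ns) and
    ``microtime`` (uint32, ps ticks; 0xFFFFFFFF = unset / absent column),
    with geometry/laser/scan metadata as JSON header attributes.
    """
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "spffs-event-list"
        f.attrs["version"] = _FORMAT_VERSION
        f.attrs["geometry"] = json.dumps(asdict(stream.geometry))
        f.attrs["laser"] = json.dumps(asdict(stream.laser))
        f.attrs["scan"] = json.dumps(asdict(stream.scan)) if stream.scan else ""
        f.attrs["duration_s"] = stream.duration_s
        f.attrs["volume"] = stream.volume or ""
        f.create_dataset("channel", data=stream.channels, dtype=np.uint8)
        f.create_dataset("t_abs", data=stream.t_abs_ns, dtype=np.uint64)
        if stream.has_microtimes:
            ps = np.where(
                np.isnan(stream.microtimes_ns),
                _MICROTIME_UNSET,
                np.round(np.nan_to_num(stream.microtimes_ns) * 1e3).astype(np.uint32),
            ).astype(np.uint32)
            f.create_dataset("microtime", data=ps, dtype=np.uint32)


def read_event_list(path) -> PhotonStream:
    """Read a stream written by :func:`write_event_list`."""
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "spffs-event-list":
            raise FormatError(f"{path}: missing spffs-event-list format tag")
        for col in ("channel", "t_abs"):
            if col not in f:
                raise FormatError(f"{path}: missing required column {col!r}")
        try:
            geometry = DetectorGeometry(**json.loads(f.attrs["geometry"]))
            laser = LaserConfig(**json.loads(f.attrs["laser"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed metadata header ({exc})") from exc
        scan_json = f.attrs.get("scan", "")
        scan = ScanMetadata(**json.loads(scan_json)) if scan_json else None
        channels = f["channel"][:]
        t_abs = f["t_abs"][:]
        if channels.shape != t_abs.shape:
            raise FormatError(f"{path}: channel/t_abs column length mismatch")
        if channels.size and channels.max() >= geometry.n_channels:
            bad = int(np.argmax(channels >= geometry.n_channels))
            raise FormatError(
                f"{path}: record {bad}: channel {int(channels[bad])} outside geometry"
            )
        microtimes = None
        if "microtime" in f:
            ps = f["microtime"][:]
            microtimes = np.where(ps == _MICROTIME_UNSET, np.nan, ps.astype(np.float64) * 1e-3)
        return PhotonStream(
            channels=channels,
            t_abs_ns=t_abs,
            microtimes_ns=microtimes,
            geometry=geometry,
            laser=laser,
            scan=scan,
            duration_s=float(f.attrs["duration_s"]),
            volume=str(f.attrs.get("volume", "")) or None,
        )
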