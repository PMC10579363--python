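"""Time-tagged photon streams for pulsed-interleaved-excitation (PIE) smFRET.

A :class:`PhotonStream` holds the macrotime record of one well: integer clock
ticks plus a per-photon PIE channel label.  Channels follow the usual ALEX/PIE
convention:

``DD``
    donor-excitation, donor-emission photons,
``DA``
    donor-excitation, acceptor-emission photons (FRET-sensitized),
``AA``
    acceptor-excitation, acceptor-emission photons (direct probe of the
    acceptor, used for stoichiometry).

Streams are stored on disk in a Photon-HDF5-style layout
(``photon_data/timestamps``, ``photon_data/detectors``, plus setup metadata)
so they stay interoperable with the wider single-molecule ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

__all__ = ["CHANNELS", "DD", "DA", "AA", "PhotonStream"]

#: integer channel codes used in the ``channel`` array
DD, DA, AA = 0, 1, 2
CHANNELS = ("DD", "DA", "AA")


@dataclass
class PhotonStream:
    """Photon record of a single well.

    Parameters
    ----------
    timestamps : ndarray of int64
        Macrotimes in clock ticks, strictly increasing.
    channel : ndarray of int8
        Per-photon PIE channel code (0=DD, 1=DA, 2=AA).
    clock_period : float
        Seconds per clock tick (default 12.5 ns, a typical TCSPC macrotime
        resolution).
    duration : float
        Acquisition duration in seconds.
    well_id : str
        Plate coordinate, e.g. ``"A01"``.
    """

    timestamps: np.ndarray
    channel: np.ndarray
    clock_period: float = 12.5e-9
    duration: float = 0.0
    well_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.channel = np.asarray(self.channel, dtype=np.int8)
        if self.timestamps.shape != self.channel.shape:
            raise ValueError("timestamps and channel must have equal length")
        if self.timestamps.size and np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if not np.all(np.isin(self.channel, [DD, DA, AA])):
            raise ValueError("channel codes must be in {0, 1, 2}")
        if self.clock_period <= 0:
            raise ValueError("clock_period must be positive")
        if self.timestamps.size:
            t_last = float(self.timestamps[-1]) * self.clock_period
            if self.duration < t_last:
                self.duration = t_last

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def times(self) -> np.ndarray:
        """Photon arrival times in seconds."""
        return self.timestamps * self.clock_period

    def counts_per_channel(self) -> np.ndarray:
        """Total (DD, DA, AA) photon counts."""
        return np.bincount(self.channel, minlength=3)[:3]

    def shifted(self, ticks: int) -> "PhotonStream":
        """Return a copy with all timestamps offset by ``ticks``."""
        return PhotonStream(
            self.timestamps + int(ticks),
            self.channel.copy(),
            clock_period=self.clock_period,
            duration=self.duration + ticks * self.clock_period,
            well_id=self.well_id,
        )

    # ------------------------------------------------------------------
    # Photon-HDF5-style persistence
    def to_hdf5(self, path) -> None:
        """Write the stream in a Photon-HDF5-style layout."""
        with h5py.File(path, "w") as f:
            pd_ = f.create_group("photon_data")
            pd_.create_dataset("timestamps", data=self.timestamps)
            pd_.create_dataset("detectors", data=self.channel)
            spec = pd_.create_group("measurement_specs")
            spec.attrs["measurement_type"] = "smFRET-PIE"
            spec.attrs["detectors_labels"] = ",".join(CHANNELS)
            setup = f.create_group("setup")
            setup.attrs["clock_period_s"] = self.clock_period
            setup.attrs["acquisition_duration_s"] = self.duration
            setup.attrs["excitation_alternated"] = True
            f.attrs["well_id"] = self.well_id

    @classmethod
    def from_hdf5(cls, path) -> "PhotonStream":
        with h5py.File(path, "r") as f:
            return cls(
                timestamps=f["photon_data/timestamps"][()],
                channel=f["photon_data/detectors"][()],
                clock_period=float(f["setup"].attrs["clock_period_s"]),
                duration=float(f["setup"].attrs["acquisition_duration_s"]),
                well_id=str(f.attrs.get("well_id", "")),
            )
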