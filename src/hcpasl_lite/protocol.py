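"""SMS PCASL acquisition timing and geometry.

The acquisition is a 2D EPI readout with simultaneous multi-slice (SMS)
excitation: ``mb_factor`` slices are excited together, so the volume is
covered in ``band_size = n_slices / mb_factor`` sequential excitations and
the slice stack splits into ``mb_factor`` contiguous bands of ``band_size``
slices.  Slice ``s`` sits at within-band position ``p(s) = s mod band_size``
and is excited ``delta(s) = p(s) * slice_readout_time`` seconds after the
start of the readout.  ``delta`` drives both banding mechanisms (saturation
recovery and the residual empirical gradient) and the per-voxel effective
post-labelling delay, so this class is the single source of truth for the
slice -> band -> time mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VOLUME_ORDERS = ("pld-grouped-cl",)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing and geometry of an SMS multi-delay PCASL acquisition.

    Parameters
    ----------
    label_duration
        PCASL labelling duration tau in seconds.
    plds
        Post-labelling delays in seconds, strictly increasing.
    repeats
        Number of label-control pairs acquired at each PLD.
    n_slices
        Total number of slices (third voxel axis).
    mb_factor
        Multiband factor, i.e. number of simultaneously excited slice bands.
    slice_readout_time
        Time per slice excitation within a band, seconds.
    te
        Echo time in seconds.
    calib_tr
        Repetition time of the proton-density calibration images, seconds.
    volume_order
        Scheme mapping timeseries index -> (PLD index, label/control flag).
        ``"pld-grouped-cl"``: volumes grouped by PLD, each repeat acquired
        as a control followed by its label.
    """

    label_duration: float = 1.5
    plds: tuple[float, ...] = (0.2, 0.7, 1.2, 1.7, 2.2)
    repeats: tuple[int, ...] = (6, 6, 6, 10, 15)
    n_slices: int = 60
    mb_factor: int = 6
    slice_readout_time: float = 0.059
    te: float = 0.019
    calib_tr: float = 8.0
    volume_order: str = "pld-grouped-cl"

    def __post_init__(self):
        object.__setattr__(self, "plds", tuple(float(p) for p in self.plds))
        object.__setattr__(self, "repeats", tuple(int(r) for r in self.repeats))
        if len(self.plds) != len(self.repeats):
            raise ValueError("plds and repeats must have equal length")
        if any(r < 1 for r in self.repeats):
            raise ValueError("all repeats must be >= 1")
        if any(b <= a for a, b in zip(self.plds, self.plds[1:])):
            raise ValueError("plds must be strictly increasing")
        if self.n_slices % self.mb_factor != 0:
            raise ValueError("n_slices must be divisible by mb_factor")
        if self.volume_order not in VOLUME_ORDERS:
            raise ValueError(f"unknown volume_order {self.volume_order!r}")
        if self.label_duration <= 0 or self.slice_readout_time < 0:
            raise ValueError("non-physical timing parameters")

    # -- geometry -----------------------------------------------------------

    @property
    def band_size(self) -> int:
        return self.n_slices // self.mb_factor

    def band_of(self, slice_idx):
        return np.asarray(slice_idx) // self.band_size

    def within_band_position(self, slice_idx):
        """Within-band position p(s) = s mod band_size (acquisition order)."""
        return np.asarray(slice_idx) % self.band_size

    def slice_offset(self, slice_idx):
        """Slice-timing offset delta(s) in seconds.

        Accepts fractional slice indices: the offset is interpolated
        linearly between the offsets of the neighbouring integer slices,
        which is what a voxel that moved between slices experiences.
        """
        s = np.asarray(slice_idx, dtype=float)
        if np.any(s < 0) or np.any(s > self.n_slices - 1):
            raise IndexError("slice index out of range")
        profile = self.slice_offsets()
        return np.interp(s, np.arange(self.n_slices), profile)

    def slice_offsets(self) -> np.ndarray:
        """delta(s) for every integer slice, shape (n_slices,)."""
        p = np.arange(self.n_slices) % self.band_size
        return p * self.slice_readout_time

    def sat_time(self, pld: float, slice_idx):
        """Interval from pre-saturation to excitation: tau + PLD + delta(s)."""
        return self.label_duration + pld + self.slice_offset(slice_idx)

    # -- timeseries layout --------------------------------------------------

    @property
    def n_volumes(self) -> int:
        """Total number of ASL volumes: 2 x sum(repeats)."""
        return 2 * sum(self.repeats)

    def volume_annotations(self) -> list[tuple[int, bool]]:
        """Per-volume (pld_index, is_label) following ``volume_order``."""
        ann = []
        for p, rep in enumerate(self.repeats):
            for _ in range(rep):
                ann.append((p, False))  # control
                ann.append((p, True))  # label
        return ann

    def volume_plds(self) -> np.ndarray:
        return np.array([self.plds[p] for p, _ in self.volume_annotations()])

    def label_flags(self) -> np.ndarray:
        return np.array([lab for _, lab in self.volume_annotations()])

    # -- sidecar I/O --------------------------------------------------------

    def to_sidecar(self, **extra) -> dict:
        d = {
            "LabelingDuration": self.label_duration,
            "PostLabelingDelays": list(self.plds),
            "Repeats": list(self.repeats),
            "NumberOfSlices": self.n_slices,
            "MultibandAccelerationFactor": self.mb_factor,
            "SliceReadoutTime": self.slice_readout_time,
            "EchoTime": self.te,
            "CalibrationRepetitionTime": self.calib_tr,
            "VolumeOrder": self.volume_order,
        }
        d.update(extra)
        return d

    @classmethod
    def from_sidecar(cls, d: dict) -> "AcquisitionProtocol":
        return cls(
            label_duration=d["LabelingDuration"],
            plds=tuple(d["PostLabelingDelays"]),
            repeats=tuple(d["Repeats"]),
            n_slices=d["NumberOfSlices"],
            mb_factor=d["MultibandAccelerationFactor"],
            slice_readout_time=d["SliceReadoutTime"],
            te=d.get("EchoTime", 0.019),
            calib_tr=d.get("CalibrationRepetitionTime", 8.0),
            volume_order=d.get("VolumeOrder", "pld-grouped-cl"),
        )


def default_protocol() -> AcquisitionProtocol:
    """The HCP Lifespan SMS PCASL protocol used throughout this package."""
    return AcquisitionProtocol()
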