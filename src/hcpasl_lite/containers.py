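"""In-memory containers passed between processing stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .protocol import AcquisitionProtocol


@dataclass
class ASLTimeseries:
    """4D label/control series with per-volume annotations.

    ``data`` has shape (X, Y, Z, T) with the slice axis third and 0-based
    slice indexing.  ``motion_trace`` is a (T, 3) array of per-volume rigid
    translations in voxels (the displacement applied to the anatomy at
    acquisition; all zeros or None means a still subject).  ``corrections``
    records which intensity corrections have been applied, used both for
    provenance and to guard against accidental double-correction.
    """

    data: np.ndarray
    protocol: AcquisitionProtocol
    motion_trace: np.ndarray | None = None
    corrections: tuple[str, ...] = ()

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("ASL data must be 4D (X, Y, Z, T)")
        if self.data.shape[2] != self.protocol.n_slices:
            raise ValueError("third axis must equal protocol n_slices")
        if self.data.shape[3] != self.protocol.n_volumes:
            raise ValueError(
                f"expected {self.protocol.n_volumes} volumes, got {self.data.shape[3]}"
            )
        if self.motion_trace is not None:
            self.motion_trace = np.asarray(self.motion_trace, dtype=float)
            if self.motion_trace.shape != (self.data.shape[3], 3):
                raise ValueError("motion_trace must be (n_volumes, 3)")

    @property
    def shape(self):
        return self.data.shape[:3]

    def control_indices(self) -> np.ndarray:
        return np.where(~self.protocol.label_flags())[0]

    def label_indices(self) -> np.ndarray:
        return np.where(self.protocol.label_flags())[0]

    def with_data(self, data, extra_correction: str | None = None) -> "ASLTimeseries":
        corr = self.corrections
        if extra_correction is not None:
            corr = corr + (extra_correction,)
        return replace(self, data=np.asarray(data, dtype=float), corrections=corr)


@dataclass
class DifferenceData:
    """Per-PLD perfusion-weighted difference volumes.

    ``dm``/``dm_se`` have shape (n_pld, X, Y, Z); ``dm_se`` is the OLS
    standard error of the difference estimate and feeds the kinetic fits as
    the observation noise scale.  ``effective_pld`` is the slice-timing
    adjusted PLD per voxel per PLD (nominal PLD + delta(slice)).
    """

    dm: np.ndarray
    dm_se: np.ndarray
    effective_pld: np.ndarray
    n_used: np.ndarray
    valid_mask: np.ndarray
    plds: tuple[float, ...]

    def __post_init__(self):
        if not (self.dm.shape == self.dm_se.shape == self.effective_pld.shape):
            raise ValueError("dm, dm_se and effective_pld shapes must agree")
        # tolerance covers float32 round trips through NIfTI
        if np.any(self.effective_pld < np.asarray(self.plds).reshape(-1, 1, 1, 1) - 1e-5):
            raise ValueError("effective PLD below nominal PLD")

    @property
    def n_plds(self) -> int:
        return self.dm.shape[0]

    @property
    def shape(self):
        return self.dm.shape[1:]


@dataclass
class PerfusionMaps:
    """CBF/ATT/aBV volumes plus provenance flags.

    ``perfusion`` is in arbitrary units until ``calibrated`` is set, after
    which it is in ml/100g/min.  ``converged`` marks voxels where the
    optimiser met its tolerance.
    """

    perfusion: np.ndarray
    att: np.ndarray
    mask: np.ndarray
    abv: np.ndarray | None = None
    att_art: np.ndarray | None = None
    converged: np.ndarray | None = None
    calibrated: bool = False
    pvec: bool = False
    extras: dict = field(default_factory=dict)

    def clipped_perfusion(self) -> np.ndarray:
        """Perfusion with negative values clipped to zero (for reporting)."""
        return np.clip(self.perfusion, 0.0, None)
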