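"""In-memory containers for MS acquisitions: survey scans and fragment
spectra."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Scan", "FragmentSpectrum"]


@dataclass
class Scan:
    """One MS1 or MS2 acquisition.

    ``mz`` is strictly increasing and the same length as ``intensity``.
    ``centroided`` distinguishes stick spectra from profile data (which
    :func:`nanorapids.features.detect_mass_peaks` centroids by
    intensity-weighted local maximum).  MS2 scans carry precursor
    metadata.
    """

    ms_level: int
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    centroided: bool = True
    scan_id: int = 0
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    precursor_intensity: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz array must be strictly increasing")
        if self.intensity.size and self.intensity.min() < 0:
            raise ValueError("intensities must be >= 0")
        if self.ms_level not in (1, 2):
            raise ValueError("ms_level must be 1 or 2")


@dataclass
class FragmentSpectrum:
    """An MS2 peak list tied to a precursor ion."""

    precursor_mz: float
    peaks: np.ndarray  # shape (n, 2): mz ascending, intensity > 0
    charge: int = 1
    feature_id: int | None = None
    rt: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        self.peaks = np.atleast_2d(np.asarray(self.peaks, dtype=float))
        if self.peaks.size == 0:
            self.peaks = np.empty((0, 2))
        if self.peaks.shape[1] != 2:
            raise ValueError("peaks must be (n, 2) [mz, intensity]")
        order = np.argsort(self.peaks[:, 0], kind="stable")
        self.peaks = self.peaks[order]
        if self.peaks.size and self.peaks[:, 1].min() <= 0:
            raise ValueError("fragment intensities must be > 0")
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]

    def __len__(self) -> int:
        return self.peaks.shape[0]

    @classmethod
    def from_scan(cls, scan: Scan, feature_id: int | None = None
                  ) -> "FragmentSpectrum":
        keep = scan.intensity > 0
        peaks = np.column_stack([scan.mz[keep], scan.intensity[keep]])
        return cls(
            precursor_mz=float(scan.precursor_mz or 0.0),
            peaks=peaks,
            charge=scan.precursor_charge or 1,
            feature_id=feature_id,
            rt=scan.rt,
        )
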