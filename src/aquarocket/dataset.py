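"""In-memory containers for NIR spectral data and per-spectrum sample metadata.

A :class:`SpectralDataset` couples a strictly increasing wavelength grid (nm)
with an ``n_spectra x n_wavelengths`` value matrix and one
:class:`SampleMeta` record per row.  Every pretreatment operator in this
package maps a ``SpectralDataset`` to a new ``SpectralDataset``, so the grid,
the values and the metadata always travel together and stay consistent.

The acquisition convention modelled here is a handheld spectrometer scanning
sealed salad bags: 3 bags per treatment, both bag sides, several replicate
scans per side, on a fixed storage-day schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import Iterable, Sequence

import numpy as np

#: Modified-atmosphere treatments: A = air (21% O2 / 78% N2),
#: B = 30% O2 / 70% N2, C = 10% CO2 / 5% O2 / 85% N2.
TREATMENTS = ("A", "B", "C")

#: Storage-day sampling schedule used throughout the study conditions.
DEFAULT_DAYS = (0, 1, 4, 7, 11, 13)

#: Marker used by group-averaging for a metadata field pooled over.
POOLED = "pooled"

MODE_REFLECTANCE = "reflectance"
MODE_ABSORBANCE = "absorbance"


class SpectralDataError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata of one acquired spectrum.

    ``treatment`` is one of A/B/C (or :data:`POOLED` after group averaging),
    ``day`` the storage day, ``bag`` the bag identifier, ``side`` front/back,
    and ``replicate`` the scan index (after averaging it holds the number of
    member spectra).
    """

    treatment: str
    day: int
    bag: str = "1"
    side: str = "front"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS and self.treatment != POOLED:
            raise SpectralDataError(
                f"unknown treatment code {self.treatment!r}; expected one of "
                f"{TREATMENTS} or {POOLED!r}"
            )
        if self.day < 0:
            raise SpectralDataError(f"storage day must be non-negative, got {self.day}")
        if self.side not in ("front", "back", POOLED):
            raise SpectralDataError(f"unknown bag side {self.side!r}")
        if self.replicate < 1:
            raise SpectralDataError(f"replicate must be >= 1, got {self.replicate}")

    def key(self, keys: Sequence[str]) -> tuple:
        """Return the tuple of the requested metadata fields."""
        return tuple(getattr(self, k) for k in keys)


def instrument_grid(lo: float = 900.0, hi: float = 1600.0, n: int = 125) -> np.ndarray:
    """The evenly spaced instrument wavelength grid, endpoints inclusive.

    The portable spectrometer records 125 points over 900-1600 nm
    (spacing ~5.645 nm); only the endpoints and the count are fixed, so an
    even grid is used.
    """
    return np.linspace(lo, hi, n)


@dataclass
class SpectralDataset:
    """Wavelength grid + value matrix + one metadata record per spectrum."""

    wavelengths: np.ndarray
    values: np.ndarray
    mode: str
    samples: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        wl = self.wavelengths
        if wl.ndim != 1 or wl.size == 0:
            raise SpectralDataError("wavelength grid must be a non-empty 1-D vector")
        if not np.all(np.diff(wl) > 0):
            raise SpectralDataError("wavelengths must be strictly increasing")
        if self.values.shape != (len(self.samples), wl.size):
            raise SpectralDataError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {wl.size} wavelengths"
            )
        if self.mode not in (MODE_REFLECTANCE, MODE_ABSORBANCE):
            raise SpectralDataError(f"unknown mode {self.mode!r}")
        if self.mode == MODE_REFLECTANCE and self.values.size:
            if np.any(self.values <= 0) or np.any(self.values > 1):
                raise SpectralDataError("reflectance values must lie in (0, 1]")
        if not np.all(np.isfinite(self.values)):
            raise SpectralDataError("spectral values must be finite")

    # -- conveniences ---------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def replace(self, **changes) -> "SpectralDataset":
        """Return a copy with the given fields replaced (re-validated)."""
        ds = _dc_replace(self, **changes)
        return ds

    def copy(self) -> "SpectralDataset":
        return SpectralDataset(
            self.wavelengths.copy(), self.values.copy(), self.mode, list(self.samples)
        )

    def wavelength_spacing(self, rtol: float = 2e-3) -> float:
        """Mean grid spacing; raises if the grid is not uniform within rtol.

        The default tolerance absorbs the rounding of wide-CSV wavelength
        headers (nm printed with 2 decimals, ~0.1% spacing jitter) while
        still rejecting genuinely irregular grids.
        """
        d = np.diff(self.wavelengths)
        if d.size and (d.max() - d.min()) > rtol * d.mean():
            raise SpectralDataError("wavelength grid is not uniform")
        return float(d.mean()) if d.size else 0.0

    def meta_frame(self):
        """Sample metadata as a pandas DataFrame (one row per spectrum)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "treatment": [s.treatment for s in self.samples],
                "day": [s.day for s in self.samples],
                "bag": [s.bag for s in self.samples],
                "side": [s.side for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )


def stack(datasets: Iterable[SpectralDataset]) -> SpectralDataset:
    """Vertically concatenate datasets sharing grid and mode."""
    datasets = list(datasets)
    if not datasets:
        raise SpectralDataError("no datasets to stack")
    first = datasets[0]
    for ds in datasets[1:]:
        if not np.array_equal(ds.wavelengths, first.wavelengths):
            raise SpectralDataError("cannot stack datasets on different grids")
        if ds.mode != first.mode:
            raise SpectralDataError("cannot stack datasets with different modes")
    return SpectralDataset(
        first.wavelengths.copy(),
        np.vstack([ds.values for ds in datasets]),
        first.mode,
        [s for ds in datasets for s in ds.samples],
    )
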