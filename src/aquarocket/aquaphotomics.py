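"""Water absorbance band (WAB) selection and aquagram construction.

The first overtone of water (1300-1600 nm) contains 12 characteristic
absorbance ranges, the water matrix coordinates (WAMACs) C1-C12, each 6-20
nm wide.  Within each coordinate a specific water absorbance band (WAB) is
"activated" by a perturbation of the aqueous system: free water molecules
(S0), water with 1-4 hydrogen bonds (S1-S4), solvation shells, and
combination bands (nu1, nu2, nu3).

An aquagram plots, on a radar chart with one axis per WAB, the group-mean
normalized absorbance

    z(lambda) = (A(lambda) - mu(lambda)) / sigma(lambda)

at the selected bands; the resulting polygon is the water absorbance
spectral pattern (WASP) of the group.  Band values are taken on the
normalized second-derivative scale without a sign flip; pass
``flip_sign=True`` to :func:`render_aquagram` for the negated convention
common elsewhere in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataset import SpectralDataset
from . import spectra_io


class AquaphotomicsError(ValueError):
    pass


@dataclass(frozen=True)
class WAB:
    """One water absorbance band: wavelength (nm), its WAMAC label and the
    water-species assignment."""

    wavelength: float
    wamac: str
    assignment: str

    def __post_init__(self) -> None:
        if not 1300.0 <= self.wavelength <= 1600.0:
            raise AquaphotomicsError(
                f"WAB at {self.wavelength} nm lies outside the first overtone "
                "of water (1300-1600 nm)"
            )
        if self.wamac not in {f"C{i}" for i in range(1, 13)}:
            raise AquaphotomicsError(f"unknown WAMAC label {self.wamac!r}")


@dataclass(frozen=True)
class WABSet:
    """Ordered set of 12 WABs, one per WAMAC C1..C12."""

    wabs: tuple[WAB, ...]

    def __post_init__(self) -> None:
        if len(self.wabs) != 12:
            raise AquaphotomicsError(f"a WABSet needs exactly 12 bands, got {len(self.wabs)}")
        wl = [w.wavelength for w in self.wabs]
        if not all(a < b for a, b in zip(wl, wl[1:])):
            raise AquaphotomicsError("WAB wavelengths must be strictly increasing")
        labels = [w.wamac for w in self.wabs]
        if labels != [f"C{i}" for i in range(1, 13)]:
            raise AquaphotomicsError("WAMAC labels must be C1..C12 in order")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array([w.wavelength for w in self.wabs])

    @property
    def labels(self) -> list[str]:
        return [w.wamac for w in self.wabs]

    def __iter__(self):
        return iter(self.wabs)

    def __getitem__(self, i: int) -> WAB:
        return self.wabs[i]


# canonical band table: wavelength, WAMAC, water-species assignment
_DEFAULT_WABS: tuple[tuple[float, str, str], ...] = (
    (1342.0, "C1", "ν3"),
    (1366.0, "C2", "water solvation shell, OH-(H2O)n, n = 1, 2, 4"),
    (1373.0, "C3", "ν1 + ν3"),
    (1385.0, "C4", "water solvation shell, OH-(H2O)1,4 and superoxide, O2-(H2O)4"),
    (1416.0, "C5", "free water molecules (S0)"),
    (1428.0, "C6", "water hydration, H-OH bend and O...O"),
    (1441.0, "C7", "water molecules with 1 hydrogen bond (S1)"),
    (1453.0, "C8", "ν2 + ν3, Water solvation shell, OH-(H2O)4,5"),
    (1466.0, "C9", "water molecules with 2 hydrogen bonds (S2)"),
    (1478.0, "C10", "water molecules with 3 hydrogen bonds (S3)"),
    (1490.0, "C11", "water molecules with 4 hydrogen bonds (S4)"),
    (1509.0, "C12", "ν1, ν2, strongly bound water"),
)


def default_wabs() -> WABSet:
    """The canonical 12-band set for leafy-vegetable storage monitoring."""
    return WABSet(tuple(WAB(*row) for row in _DEFAULT_WABS))


def default_wamac_ranges(half_width: float = 6.0) -> list[tuple[float, float]]:
    """Candidate nm interval per WAMAC: +/- ``half_width`` around each
    canonical band (WAMACs are 6-20 nm wide; 6 nm keeps the 12 intervals
    disjoint on a ~5.6 nm grid)."""
    return [(w - half_width, w + half_width) for w, _, _ in _DEFAULT_WABS]


def _align_loading(loading, wavelengths: np.ndarray) -> Optional[np.ndarray]:
    """Accept a loading vector aligned to the grid, or (wl, vec) to interpolate."""
    if loading is None:
        return None
    if isinstance(loading, tuple):
        wl, vec = loading
        return np.interp(wavelengths, np.asarray(wl, float), np.asarray(vec, float))
    vec = np.asarray(loading, dtype=float)
    if vec.ndim == 2:  # loading matrix: use the first component
        vec = vec[:, 0]
    if vec.shape != wavelengths.shape:
        raise AquaphotomicsError(
            "loading vector length does not match the wavelength grid; pass "
            "(wavelengths, vector) to interpolate"
        )
    return vec


def select_wabs(
    norm_ds: SpectralDataset,
    pca_loadings=None,
    pls_loadings=None,
    ranges: Optional[Sequence[tuple[float, float]]] = None,
    group_keys: Sequence[str] = ("treatment", "day"),
) -> WABSet:
    """Pick one WAB per WAMAC range from a normalized dataset.

    Candidates inside each range are scored by a rank-sum over the available
    criteria: the normalized-spectrum extremum (largest group-mean |z|) and,
    where provided, |PCA loading| and |PLS loading|.  The weighting of the
    criteria is an open methodological point; the rank-sum combination is a
    documented neutral choice.  Ties break to the lower wavelength, making
    the selection deterministic and stable under sample duplication.
    """
    if ranges is None:
        ranges = default_wamac_ranges()
    if len(ranges) != 12:
        raise AquaphotomicsError(f"need 12 WAMAC ranges, got {len(ranges)}")
    wl = norm_ds.wavelengths
    means = spectra_io.average_by(norm_ds, tuple(group_keys))
    spectrum_score = np.max(np.abs(means.values), axis=0)
    criteria = [spectrum_score]
    for loading in (pca_loadings, pls_loadings):
        vec = _align_loading(loading, wl)
        if vec is not None:
            criteria.append(np.abs(vec))
    chosen: list[WAB] = []
    prev = -np.inf
    for (lo, hi), (default_wl, wamac, assignment) in zip(ranges, _DEFAULT_WABS):
        idx = np.flatnonzero((wl >= lo) & (wl <= hi))
        if idx.size == 0:
            raise AquaphotomicsError(
                f"WAMAC {wamac} range [{lo}, {hi}] nm contains no grid wavelength"
            )
        # neighbouring WAMAC ranges may overlap (e.g. C2/C3 are 7 nm apart);
        # keep the selected wavelengths strictly increasing across coordinates
        idx = idx[wl[idx] > prev]
        if idx.size == 0:
            raise AquaphotomicsError(
                f"WAMAC {wamac} range [{lo}, {hi}] nm has no grid wavelength "
                "above the previous coordinate's selection"
            )
        # rank 1 = strongest criterion value; 'min' keeps ties symmetric
        rank_sum = np.zeros(idx.size)
        for crit in criteria:
            rank_sum += rankdata(-crit[idx], method="min")
        best = idx[np.argmin(rank_sum)]  # argmin takes the first = lowest wavelength
        prev = float(wl[best])
        chosen.append(WAB(prev, wamac, assignment))
    return WABSet(tuple(chosen))


@dataclass(frozen=True)
class AquagramResult:
    """Group labels x 12 normalized WAB values (the WASPs)."""

    groups: tuple[tuple, ...]          # e.g. (("A", 0), ("A", 1), ...)
    group_keys: tuple[str, ...]
    values: np.ndarray                 # n_groups x 12
    wabs: WABSet

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.groups), 12):
            raise AquaphotomicsError(
                f"aquagram values must be n_groups x 12, got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise AquaphotomicsError("aquagram values must be finite")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{w.wamac}_{w.wavelength:g}nm" for w in self.wabs]
        df = pd.DataFrame(self.values, columns=cols)
        for i, key in enumerate(self.group_keys):
            df.insert(i, key, [g[i] for g in self.groups])
        return df


def compute_aquagram(
    norm_ds: SpectralDataset,
    wabs: Optional[WABSet] = None,
    group_keys: Sequence[str] = ("treatment", "day"),
) -> AquagramResult:
    """Group-mean normalized absorbance at each WAB.

    ``norm_ds`` must be on the column-standardized scale.  Because the
    instrument grid (~5.6 nm spacing) does not contain the canonical band
    wavelengths exactly, the value at a WAB is the linear interpolation
    between the two flanking grid points; it equals the grid value exactly
    when a WAB coincides with a grid point.
    """
    if wabs is None:
        wabs = default_wabs()
    wl = norm_ds.wavelengths
    target = wabs.wavelengths
    if target.min() < wl.min() or target.max() > wl.max():
        raise AquaphotomicsError(
            f"WAB wavelengths [{target.min():g}, {target.max():g}] nm fall outside "
            f"the grid span [{wl.min():g}, {wl.max():g}] nm"
        )
    means = spectra_io.average_by(norm_ds, tuple(group_keys))
    rows = np.vstack([np.interp(target, wl, row) for row in means.values])
    groups = tuple(s.key(tuple(group_keys)) for s in means.samples)
    return AquagramResult(groups=groups, group_keys=tuple(group_keys), values=rows, wabs=wabs)


def render_aquagram(
    aq: AquagramResult,
    path,
    panel_key: Optional[str] = "treatment",
    flip_sign: bool = False,
    title: Optional[str] = None,
) -> None:
    """Render the WASPs as radar charts.

    Twelve axes ordered C1 -> C12 clockwise from the top, one closed
    polyline per group; all panels of a run share radial limits so patterns
    are comparable across treatments.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not aq.groups:
        raise AquaphotomicsError("no groups to render")
    values = -aq.values if flip_sign else aq.values
    # clockwise from the top
    theta = np.pi / 2 - 2 * np.pi * np.arange(12) / 12
    theta_closed = np.concatenate([theta, theta[:1]])
    lim = max(1e-6, float(np.abs(values).max())) * 1.1

    if panel_key is not None and panel_key in aq.group_keys:
        pi = aq.group_keys.index(panel_key)
        panels = list(dict.fromkeys(g[pi] for g in aq.groups))
    else:
        pi, panels = None, [None]

    fig, axes = plt.subplots(
        1, len(panels), figsize=(5 * len(panels), 5), subplot_kw={"projection": "polar"}
    )
    axes = np.atleast_1d(axes)
    for ax, panel in zip(axes, panels):
        member_idx = [
            i for i, g in enumerate(aq.groups) if pi is None or g[pi] == panel
        ]
        for i in member_idx:
            row = values[i]
            label = ", ".join(str(v) for v in aq.groups[i])
            ax.plot(theta_closed, np.concatenate([row, row[:1]]), label=label, lw=1.2)
        ax.set_xticks(theta)
        ax.set_xticklabels([w.wamac for w in aq.wabs])
        ax.set_ylim(-lim, lim)
        if panel is not None:
            ax.set_title(str(panel))
        ax.legend(loc="upper right", bbox_to_anchor=(1.35, 1.1), fontsize=7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
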