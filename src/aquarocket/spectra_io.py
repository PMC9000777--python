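"""Reading, writing and restructuring of spectral datasets.

Two plain-text CSV dialects are supported:

``wide_csv``
    One row per spectrum.  Reserved metadata columns ``treatment, day, bag,
    side, replicate, mode`` come first, followed by one column per
    wavelength, headers being the nm values printed with at most two
    decimals.

``long_csv``
    One row per (spectrum, wavelength):
    ``treatment, day, bag, side, replicate, mode, wavelength, value``.

Acquisition-level corrections live here too: reflectance -> absorbance
(A = log10(1/R)), subtraction of an averaged packaging-film reference
spectrum, wavelength-range truncation, and replicate averaging down to
bag/side/checkpoint means.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import (
    MODE_ABSORBANCE,
    MODE_REFLECTANCE,
    POOLED,
    SampleMeta,
    SpectralDataError,
    SpectralDataset,
)

META_COLUMNS = ("treatment", "day", "bag", "side", "replicate", "mode")
GROUP_KEYS = ("treatment", "day", "bag", "side")

_DIALECTS = ("wide_csv", "long_csv")


def _check_dialect(dialect: str) -> None:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")


def _meta_from_row(row) -> SampleMeta:
    try:
        return SampleMeta(
            treatment=str(row["treatment"]),
            day=int(row["day"]),
            bag=str(row["bag"]),
            side=str(row["side"]),
            replicate=int(row["replicate"]),
        )
    except (KeyError, TypeError, ValueError, SpectralDataError) as exc:
        raise SpectralDataError(f"unparseable sample metadata: {exc}") from exc


def read_spectra(path, dialect: str = "wide_csv") -> SpectralDataset:
    """Read a spectral dataset from ``path`` in the given CSV dialect."""
    _check_dialect(dialect)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise SpectralDataError(f"no spectra in {path}")
    if dialect == "wide_csv":
        return _from_wide(df)
    return _from_long(df)


def _from_wide(df: pd.DataFrame) -> SpectralDataset:
    wl_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not wl_cols:
        raise SpectralDataError("no wavelength columns found")
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectralDataError(f"non-numeric wavelength header: {exc}") from exc
    if not np.all(np.diff(wavelengths) > 0):
        raise SpectralDataError("wavelength header is not strictly increasing")
    values = df[wl_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise SpectralDataError("ragged or non-numeric spectral rows")
    samples = [_meta_from_row(row) for _, row in df.iterrows()]
    mode = _read_mode(df)
    return SpectralDataset(wavelengths, values, mode, samples)


def _read_mode(df: pd.DataFrame) -> str:
    if "mode" not in df.columns:
        return MODE_ABSORBANCE
    modes = set(df["mode"].astype(str))
    if len(modes) != 1:
        raise SpectralDataError(f"mixed modes in file: {sorted(modes)}")
    return modes.pop()


def _from_long(df: pd.DataFrame) -> SpectralDataset:
    required = {"treatment", "day", "bag", "side", "replicate", "wavelength", "value"}
    missing = required - set(df.columns)
    if missing:
        raise SpectralDataError(f"long CSV missing columns: {sorted(missing)}")
    mode = _read_mode(df)
    id_cols = ["treatment", "day", "bag", "side", "replicate"]
    # preserve first-appearance sample order
    keys = df[id_cols].astype(str).agg("\x1f".join, axis=1)
    order = keys.drop_duplicates().tolist()
    wavelengths = np.sort(df["wavelength"].unique().astype(float))
    if not np.all(np.diff(wavelengths) > 0):
        raise SpectralDataError("duplicate wavelengths in long CSV")
    samples: list[SampleMeta] = []
    rows = []
    grouped = dict(tuple(df.groupby(keys.values, sort=False)))
    for key in order:
        sub = grouped[key].sort_values("wavelength")
        if len(sub) != wavelengths.size or not np.allclose(
            sub["wavelength"].to_numpy(dtype=float), wavelengths
        ):
            raise SpectralDataError(f"ragged long CSV: sample {key!r} misses wavelengths")
        samples.append(_meta_from_row(sub.iloc[0]))
        rows.append(sub["value"].to_numpy(dtype=float))
    return SpectralDataset(wavelengths, np.vstack(rows), mode, samples)


def write_spectra(ds: SpectralDataset, path, dialect: str = "wide_csv") -> None:
    """Write ``ds`` so that :func:`read_spectra` round-trips it."""
    _check_dialect(dialect)
    ds.validate()
    if ds.n_spectra == 0:
        raise SpectralDataError("refusing to write a dataset with 0 spectra")
    meta = ds.meta_frame()
    meta["mode"] = ds.mode
    if dialect == "wide_csv":
        wl_cols = [_format_wavelength(w) for w in ds.wavelengths]
        out = pd.concat(
            [meta, pd.DataFrame(ds.values, columns=wl_cols, index=meta.index)], axis=1
        )
        out.to_csv(path, index=False)
    else:
        n, p = ds.values.shape
        long = meta.loc[meta.index.repeat(p)].reset_index(drop=True)
        long["wavelength"] = np.tile(ds.wavelengths, n)
        long["value"] = ds.values.ravel()
        long.to_csv(path, index=False)


def _format_wavelength(w: float) -> str:
    """Wide-CSV wavelength header: nm with at most 2 decimals when that is
    lossless, otherwise full precision (round-tripping beats cosmetics)."""
    s = f"{w:.2f}".rstrip("0").rstrip(".")
    return s if float(s) == w else repr(float(w))


def reflectance_to_absorbance(ds: SpectralDataset) -> SpectralDataset:
    """Convert reflectance fractions to absorbance, A = log10(1/R)."""
    if ds.mode != MODE_REFLECTANCE:
        raise SpectralDataError(f"dataset is in mode {ds.mode!r}, not reflectance")
    bad = np.argwhere(ds.values <= 0)
    if bad.size:
        i, j = bad[0]
        raise SpectralDataError(
            f"nonpositive reflectance for sample {i} at {ds.wavelengths[j]:.2f} nm"
        )
    return ds.replace(values=-np.log10(ds.values), mode=MODE_ABSORBANCE)


def absorbance_to_reflectance(ds: SpectralDataset) -> SpectralDataset:
    """Inverse of :func:`reflectance_to_absorbance` (R = 10**(-A))."""
    if ds.mode != MODE_ABSORBANCE:
        raise SpectralDataError(f"dataset is in mode {ds.mode!r}, not absorbance")
    return ds.replace(values=np.power(10.0, -ds.values), mode=MODE_REFLECTANCE)


def subtract_reference(ds: SpectralDataset, ref: SpectralDataset) -> SpectralDataset:
    """Subtract the mean of ``ref``'s spectra (e.g. averaged PET packaging
    film scans) from every sample spectrum.  Grids and modes must match."""
    if not np.array_equal(ds.wavelengths, ref.wavelengths):
        raise SpectralDataError("reference is on a different wavelength grid")
    if ds.mode != ref.mode:
        raise SpectralDataError(
            f"mode mismatch: dataset {ds.mode!r} vs reference {ref.mode!r}"
        )
    out = ds.values - ref.values.mean(axis=0)
    # subtraction can leave reflectance outside (0, 1]; result is treated as
    # a corrected signal and stored in absorbance-style unconstrained mode
    mode = ds.mode if ds.mode == MODE_ABSORBANCE else MODE_ABSORBANCE
    if ds.mode == MODE_REFLECTANCE:
        mode = MODE_ABSORBANCE if np.any(out <= 0) or np.any(out > 1) else MODE_REFLECTANCE
    return ds.replace(values=out, mode=mode)


def truncate(ds: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Keep wavelengths with ``lo <= lambda <= hi`` (e.g. the 1300-1600 nm
    first overtone of water)."""
    if not lo < hi:
        raise ValueError(f"invalid range: lo={lo} must be < hi={hi}")
    mask = (ds.wavelengths >= lo) & (ds.wavelengths <= hi)
    if not mask.any():
        raise SpectralDataError(f"no wavelengths in [{lo}, {hi}] nm")
    return ds.replace(wavelengths=ds.wavelengths[mask], values=ds.values[:, mask])


def average_by(ds: SpectralDataset, keys: Sequence[str]) -> SpectralDataset:
    """Average spectra over groups of identical metadata ``keys``.

    One output spectrum per distinct key combination (first-appearance
    order); values are arithmetic means over member rows.  ``replicate`` is
    set to the member count; metadata fields not in ``keys`` keep their value
    when constant within a group and become ``"pooled"`` otherwise.
    """
    keys = tuple(keys)
    if not keys:
        raise ValueError("keys must be a non-empty subset of " + str(GROUP_KEYS))
    unknown = set(keys) - set(GROUP_KEYS)
    if unknown:
        raise ValueError(f"unknown grouping keys: {sorted(unknown)}")
    groups: dict[tuple, list[int]] = {}
    for i, s in enumerate(ds.samples):
        groups.setdefault(s.key(keys), []).append(i)
    rows, samples = [], []
    for key, idx in groups.items():
        members = [ds.samples[i] for i in idx]
        rows.append(ds.values[idx].mean(axis=0))
        fields = {}
        for f in GROUP_KEYS:
            vals = {getattr(m, f) for m in members}
            if len(vals) == 1:
                fields[f] = vals.pop()
            elif f == "day":
                raise SpectralDataError(
                    "cannot pool spectra across storage days without grouping by day"
                )
            else:
                fields[f] = POOLED
        samples.append(SampleMeta(replicate=len(members), **fields))
    return ds.replace(values=np.vstack(rows), samples=samples)


def checkpoint_means(ds: SpectralDataset) -> SpectralDataset:
    """Mean spectrum per (treatment, day) checkpoint, averaging sides within
    bags first and then bags, so unbalanced replicate counts do not bias the
    checkpoint mean."""
    per_side = average_by(ds, ("treatment", "day", "bag", "side"))
    per_bag = average_by(per_side, ("treatment", "day", "bag"))
    return average_by(per_bag, ("treatment", "day"))


def bag_means(ds: SpectralDataset) -> SpectralDataset:
    """Mean spectrum per (treatment, day, bag), sides averaged first."""
    per_side = average_by(ds, ("treatment", "day", "bag", "side"))
    return average_by(per_side, ("treatment", "day", "bag"))
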