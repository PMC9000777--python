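"""Synthetic spectra, leakage records and E-nose tables with the structure
the analysis pipeline assumes.

The generator emulates a modified-atmosphere storage experiment on bagged
rocket salad:

* **Spectra.**  Absorbance is a sum of Gaussian water bands: the three broad
  absorptions near 970, 1160 and 1435 nm plus fine structure at the 12
  canonical water absorbance bands of the first overtone.  Storage is
  modelled as a conserved bound -> free redistribution of water species: the
  amplitude lost at the strongly hydrogen-bonded bands (1490, 1509 nm)
  equals the amplitude gained at the free/weakly bonded bands (1416,
  1428 nm), scaled by a latent damage score.  Multiplicative slope and
  additive offset scatter are drawn per bag side; independent Gaussian noise
  is added per spectrum; reflectance is emitted as R = 10**(-A).

* **Damage.**  The latent damage score of a bag is
  ``rate(treatment) * logistic(day)``; the logistic is flat over the first
  storage week and rises afterwards, reproducing the observed leakage-index
  time course.  Treatment rates order C > A > B (the CO2-rich atmosphere
  deteriorates fastest, the oxygen-enriched one slowest).

* **Leakage.**  I_LD = intercept + slope * damage + noise, clipped to
  (0, 100]; (IC, FC) pairs are back-solved with a fixed plausible FC scale
  so ``compute_ild(ic, fc)`` reproduces the linked I_LD exactly.

* **E-nose.**  The three broad-range sensors (W5S, W1S, W2S) drift upward
  with damage; the seven compound-specific sensors stay stationary around
  their baselines; noise is multiplicative lognormal.

Every generated dataset comes with a :class:`ScenarioTruth` carrying the
latent damage scores, realized band amplitudes and scatter coefficients, so
tests can verify recovery claims without re-running the pipeline.  All
randomness flows from a single scenario seed through named substreams, so
the three generators emit mutually consistent datasets (the same latent
damage drives spectra, leakage and sensor drift).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
import json

import numpy as np

from .dataset import (
    DEFAULT_DAYS,
    MODE_REFLECTANCE,
    SampleMeta,
    SpectralDataset,
    instrument_grid,
)
from .damage_stats import SENSORS, BROAD_RANGE_SENSORS, LeakageRecord


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class Band:
    """One Gaussian absorbance component.

    ``day_coeff`` is the signed amplitude change per unit latent damage;
    positive for bands that grow during storage (free water), negative for
    bands that fade (strongly bound water).
    """

    center: float        # nm
    width: float         # Gaussian sigma, nm
    amplitude: float     # base amplitude, AU
    day_coeff: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ScenarioError(f"band width must be positive, got {self.width}")
        if self.amplitude <= 0:
            raise ScenarioError(f"band amplitude must be positive, got {self.amplitude}")


def default_bands(drift: float = 0.030) -> tuple[Band, ...]:
    """Water-band layout with a conserved bound->free redistribution.

    The amplitude gained at 1416/1428 nm per unit damage equals the
    amplitude lost at 1490/1509 nm, modelling a shift between water species
    rather than a change in total water.
    """
    broad = (
        Band(975.0, 40.0, 0.35),
        Band(1160.0, 35.0, 0.25),
        Band(1435.0, 45.0, 0.60),
    )
    fine_centers = (1342.0, 1366.0, 1373.0, 1385.0, 1416.0, 1428.0,
                    1441.0, 1453.0, 1466.0, 1478.0, 1490.0, 1509.0)
    coeffs = {1416.0: +drift, 1428.0: +drift, 1490.0: -drift, 1509.0: -drift}
    fine = tuple(
        Band(c, 8.0, 0.06, coeffs.get(c, 0.0)) for c in fine_centers
    )
    return broad + fine


@dataclass(frozen=True)
class SpectralScenario:
    """Full description of one simulated storage experiment."""

    grid: tuple[float, float, int] = (900.0, 1600.0, 125)
    bands: tuple[Band, ...] = field(default_factory=default_bands)
    scatter_slope_sd: float = 0.04   # multiplicative scatter, per bag side
    scatter_offset_sd: float = 0.015  # additive scatter (AU), per bag side
    noise_sd: float = 0.002          # per-spectrum Gaussian noise, AU
    baseline: float = 0.15           # flat absorbance floor keeping A > 0
    treatment_rates: dict = field(
        default_factory=lambda: {"A": 1.0, "B": 0.7, "C": 1.5}
    )
    days: tuple[int, ...] = DEFAULT_DAYS
    n_bags: int = 3
    n_sides: int = 2
    n_reps: int = 10
    damage_midpoint: float = 8.0     # day at which the logistic is halfway
    damage_scale: float = 1.8        # days; steepness of the rise
    bag_damage_sd: float = 0.03      # bag-to-bag latent damage spread
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi, n = self.grid
        if n < 50:
            raise ScenarioError(f"grid needs >= 50 points, got {n}")
        if not lo < hi:
            raise ScenarioError("grid bounds must satisfy lo < hi")
        rates = self.treatment_rates
        if set(rates) != {"A", "B", "C"}:
            raise ScenarioError("treatment_rates must cover exactly A, B, C")
        if rates["C"] < rates["B"]:
            raise ScenarioError(
                "default study conditions require rate(C) >= rate(B): the "
                "CO2-rich atmosphere deteriorates fastest"
            )

    def replace(self, **changes) -> "SpectralScenario":
        return _dc_replace(self, **changes)

    @property
    def wavelengths(self) -> np.ndarray:
        return instrument_grid(*self.grid)

    def damage_curve(self, day) -> np.ndarray:
        """Treatment-free logistic time course, ~0 early then rising."""
        day = np.asarray(day, dtype=float)
        return 1.0 / (1.0 + np.exp(-(day - self.damage_midpoint) / self.damage_scale))


TRIAL1 = SpectralScenario()
#: Second-harvest-like conditions: more heterogeneous optics (larger scatter
#: variance) and the opposite aquagram drift direction.
TRIAL2 = SpectralScenario(
    bands=tuple(
        Band(b.center, b.width, b.amplitude, -b.day_coeff) for b in default_bands()
    ),
    scatter_slope_sd=0.10,
    scatter_offset_sd=0.04,
)

PRESET_SCENARIOS = {"trial1": TRIAL1, "trial2": TRIAL2}


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground truth emitted alongside every generated dataset."""

    damage: np.ndarray               # latent damage score per spectrum/record
    band_amplitudes: np.ndarray      # n_samples x n_bands realized amplitudes
    scatter: np.ndarray              # n_samples x 2 (slope a, offset b)
    bag_damage: dict                 # (treatment, day, bag) -> damage score

    def to_json(self, path) -> None:
        payload = {
            "damage": self.damage.tolist(),
            "band_amplitudes": self.band_amplitudes.tolist(),
            "scatter": self.scatter.tolist(),
            "bag_damage": {"|".join(map(str, k)): v for k, v in self.bag_damage.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _rng(sc: SpectralScenario, stream: int) -> np.random.Generator:
    """Named substream of the scenario seed (stream ids keep generators
    mutually independent but jointly reproducible)."""
    return np.random.default_rng(np.random.SeedSequence([int(sc.seed), stream]))


_STREAM_DAMAGE, _STREAM_SPECTRA, _STREAM_LEAKAGE, _STREAM_ENOSE = 1, 2, 3, 4


def bag_damage_scores(sc: SpectralScenario) -> dict[tuple[str, int, str], float]:
    """Latent damage per (treatment, day, bag), shared by all generators."""
    rng = _rng(sc, _STREAM_DAMAGE)
    scores: dict[tuple[str, int, str], float] = {}
    for treatment in ("A", "B", "C"):
        rate = sc.treatment_rates[treatment]
        for day in sc.days:
            base = rate * float(sc.damage_curve(day))
            for bag in range(1, sc.n_bags + 1):
                jitter = rng.normal(0.0, sc.bag_damage_sd)
                scores[(treatment, day, str(bag))] = max(0.0, base + jitter)
    return scores


def generate_spectra(sc: SpectralScenario) -> tuple[SpectralDataset, ScenarioTruth]:
    """Simulate the full spectral acquisition for a scenario.

    Returns a reflectance-mode dataset (rows ordered treatment, day, bag,
    side, replicate) and the matching ground truth.  Same seed -> bit
    identical output.
    """
    wl = sc.wavelengths
    rng = _rng(sc, _STREAM_SPECTRA)
    damage = bag_damage_scores(sc)
    shapes = np.stack(
        [np.exp(-0.5 * ((wl - b.center) / b.width) ** 2) for b in sc.bands]
    )  # n_bands x n_wl
    rows, samples = [], []
    amp_rows, scat_rows, dmg_rows = [], [], []
    for treatment in ("A", "B", "C"):
        for day in sc.days:
            for bag in range(1, sc.n_bags + 1):
                d = damage[(treatment, day, str(bag))]
                amps = np.array(
                    [b.amplitude + b.day_coeff * d for b in sc.bands]
                )
                if np.any(amps <= 0):
                    bad = sc.bands[int(np.argmin(amps))]
                    raise ScenarioError(
                        f"drift drove the band at {bad.center:g} nm to a "
                        "nonpositive amplitude; reduce the drift coefficient "
                        "or raise the base amplitude"
                    )
                clean = sc.baseline + amps @ shapes
                for side in ("front", "back"):
                    a = 1.0 + rng.normal(0.0, sc.scatter_slope_sd)
                    b_off = rng.normal(0.0, sc.scatter_offset_sd)
                    for rep in range(1, sc.n_reps + 1):
                        noise = rng.normal(0.0, sc.noise_sd, wl.size)
                        absorb = a * clean + b_off + noise
                        if np.any(absorb <= 0):
                            raise ScenarioError(
                                "scatter/noise drove absorbance nonpositive; "
                                "raise the baseline or reduce scatter"
                            )
                        rows.append(np.power(10.0, -absorb))
                        samples.append(
                            SampleMeta(treatment, day, str(bag), side, rep)
                        )
                        amp_rows.append(amps)
                        scat_rows.append((a, b_off))
                        dmg_rows.append(d)
    ds = SpectralDataset(wl, np.vstack(rows), MODE_REFLECTANCE, samples)
    truth = ScenarioTruth(
        damage=np.array(dmg_rows),
        band_amplitudes=np.vstack(amp_rows),
        scatter=np.array(scat_rows),
        bag_damage=damage,
    )
    return ds, truth


@dataclass(frozen=True)
class LeakageLink:
    """Linear link from latent damage to I_LD (percent)."""

    slope: float = 28.0
    intercept: float = 3.0
    noise_sd: float = 0.35
    fc_scale: float = 1500.0   # plausible final conductivity, uS/cm
    n_measurements: int = 3    # conductivity measurements per bag

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ScenarioError("leakage noise_sd must be >= 0")
        if self.fc_scale <= 0:
            raise ScenarioError("fc_scale must be positive")


def generate_leakage(
    sc: SpectralScenario, link: LeakageLink = LeakageLink()
) -> tuple[list[LeakageRecord], ScenarioTruth]:
    """Electrolyte-leakage records consistent with the spectral scenario.

    The same per-bag latent damage that drives the spectral drift sets
    I_LD = intercept + slope * damage + noise (clipped to (0, 100]); the
    (IC, FC) pair is back-solved at a fixed FC so the index round-trips
    exactly through :func:`aquarocket.damage_stats.compute_ild`.
    """
    rng = _rng(sc, _STREAM_LEAKAGE)
    damage = bag_damage_scores(sc)
    records, dmg_rows = [], []
    for treatment in ("A", "B", "C"):
        for day in sc.days:
            for bag in range(1, sc.n_bags + 1):
                d = damage[(treatment, day, str(bag))]
                for rep in range(1, link.n_measurements + 1):
                    ild = link.intercept + link.slope * d + rng.normal(0.0, link.noise_sd)
                    if ild <= 0 or ild > 100:
                        raise ScenarioError(
                            f"link parameters produced I_LD = {ild:.2f}% outside "
                            "(0, 100]; adjust slope/intercept/noise"
                        )
                    fc = link.fc_scale
                    ic = ild * fc / 100.0
                    records.append(
                        LeakageRecord(
                            treatment=treatment, day=day, replicate=rep,
                            ic=ic, fc=fc, bag=str(bag),
                        )
                    )
                    dmg_rows.append(d)
    truth = ScenarioTruth(
        damage=np.array(dmg_rows),
        band_amplitudes=np.empty((len(records), 0)),
        scatter=np.empty((len(records), 0)),
        bag_damage=damage,
    )
    return records, truth


@dataclass(frozen=True)
class EnoseParams:
    """Baselines and drift of the 10-sensor array (G/G0 ratios)."""

    baselines: dict = field(
        default_factory=lambda: {
            "W1C": 0.95, "W5S": 2.2, "W3C": 0.92, "W6S": 1.05, "W5C": 0.90,
            "W1S": 1.80, "W1W": 1.30, "W2S": 1.60, "W2W": 1.25, "W3S": 1.10,
        }
    )
    drift: float = 1.2           # relative upward drift of broad sensors per unit damage
    noise_sigma: float = 0.03    # lognormal sigma
    n_measurements: int = 3
    days: tuple[int, ...] = (1, 4, 7, 11, 13)  # no E-nose run at packaging day

    def __post_init__(self) -> None:
        if set(self.baselines) != set(SENSORS):
            raise ScenarioError("baselines must cover exactly the 10 sensors")
        if any(v <= 0 for v in self.baselines.values()):
            raise ScenarioError("sensor baselines must be positive")


def generate_enose(
    sc: SpectralScenario, params: EnoseParams = EnoseParams()
) -> tuple[list[dict], ScenarioTruth]:
    """Sensor-response vectors; broad-range sensors drift with damage.

    Returns a list of dict rows (treatment, day, bag, replicate + 10 sensor
    columns) suitable for :func:`aquarocket.damage_stats.enose_frame`.
    """
    rng = _rng(sc, _STREAM_ENOSE)
    damage = bag_damage_scores(sc)
    rows, dmg_rows = [], []
    for treatment in ("A", "B", "C"):
        for day in params.days:
            if day not in sc.days:
                continue
            for bag in range(1, sc.n_bags + 1):
                d = damage[(treatment, day, str(bag))]
                for rep in range(1, params.n_measurements + 1):
                    row = {"treatment": treatment, "day": day, "bag": str(bag), "replicate": rep}
                    for sensor in SENSORS:
                        base = params.baselines[sensor]
                        level = base * (1.0 + params.drift * d) if sensor in BROAD_RANGE_SENSORS else base
                        row[sensor] = level * float(np.exp(rng.normal(0.0, params.noise_sigma)))
                    rows.append(row)
                    dmg_rows.append(d)
    truth = ScenarioTruth(
        damage=np.array(dmg_rows),
        band_amplitudes=np.empty((len(rows), 0)),
        scatter=np.empty((len(rows), 0)),
        bag_damage=damage,
    )
    return rows, truth
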