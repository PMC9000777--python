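"""Leaf-damage index and group-comparison statistics.

The electrolyte-leakage test measures the conductivity of a water bath
containing leaf pieces before (IC) and after (FC) complete cell rupture by
freezing; the index of leaf damage is

    I_LD = 100 * IC / FC   (percent)

and proxies cell-membrane permeability.  Storage-day and treatment effects
on I_LD and on the 10-sensor electronic-nose response vectors (G/G0
conductivity ratios) are assessed by one-way ANOVA with either Fisher's LSD
or Tukey's HSD post-hoc test at alpha = 0.05.

Sensor-wise ANOVA treats each E-nose sensor independently (per treatment,
across days) without multiplicity correction across sensors, mirroring the
conventional per-sensor significance marks on trend plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import chemometrics


class DamageStatsError(ValueError):
    pass


#: The 10 metal-oxide-semiconductor E-nose sensors.  W5S, W1S and W2S are
#: broad-range (W1S: methane; W2S: alcohols) and are the ones that drift
#: upward late in storage under oxygen-poor atmospheres.
SENSORS = ("W1C", "W5S", "W3C", "W6S", "W5C", "W1S", "W1W", "W2S", "W2W", "W3S")
BROAD_RANGE_SENSORS = ("W5S", "W1S", "W2S")


@dataclass(frozen=True)
class LeakageRecord:
    """One electrolyte-leakage measurement: conductivity pair and I_LD."""

    treatment: str
    day: int
    replicate: int
    ic: float
    fc: float
    bag: str = "1"

    def __post_init__(self) -> None:
        compute_ild(self.ic, self.fc)  # validates the pair

    @property
    def ild(self) -> float:
        return compute_ild(self.ic, self.fc)


def compute_ild(ic: float, fc: float) -> float:
    """Index of leaf damage, I_LD = 100 * IC / FC (percent)."""
    if fc <= 0:
        raise DamageStatsError(f"final conductivity must be positive, got {fc}")
    if ic < 0:
        raise DamageStatsError(f"initial conductivity must be >= 0, got {ic}")
    if ic > fc:
        warnings.warn(
            f"IC ({ic}) exceeds FC ({fc}): I_LD > 100% is physically suspect",
            RuntimeWarning,
            stacklevel=2,
        )
    return 100.0 * ic / fc


def leakage_frame(records: Sequence[LeakageRecord]) -> pd.DataFrame:
    """Records as a DataFrame with a derived ``ild`` column."""
    return pd.DataFrame(
        {
            "treatment": [r.treatment for r in records],
            "day": [r.day for r in records],
            "bag": [r.bag for r in records],
            "replicate": [r.replicate for r in records],
            "ic": [r.ic for r in records],
            "fc": [r.fc for r in records],
            "ild": [r.ild for r in records],
        }
    )


def read_leakage(path) -> list[LeakageRecord]:
    df = pd.read_csv(path)
    required = {"treatment", "day", "replicate", "ic", "fc"}
    missing = required - set(df.columns)
    if missing:
        raise DamageStatsError(f"leakage CSV missing columns: {sorted(missing)}")
    return [
        LeakageRecord(
            treatment=str(r.treatment),
            day=int(r.day),
            replicate=int(r.replicate),
            ic=float(r.ic),
            fc=float(r.fc),
            bag=str(getattr(r, "bag", "1")),
        )
        for r in df.itertuples()
    ]


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA summary plus optional pairwise post-hoc decisions."""

    levels: tuple
    means: np.ndarray
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    mse: float
    alpha: float = 0.05
    method: str = "anova"
    #: (level_i, level_j) -> dict(diff, critical, significant)
    pairs: dict = field(default_factory=dict)

    def significant_pairs(self) -> list[tuple]:
        return [pair for pair, d in self.pairs.items() if d["significant"]]


def _as_groups(values) -> tuple[tuple, list[np.ndarray]]:
    if isinstance(values, Mapping):
        levels = tuple(values.keys())
        groups = [np.asarray(values[k], dtype=float).ravel() for k in levels]
    else:
        groups = [np.asarray(g, dtype=float).ravel() for g in values]
        levels = tuple(range(len(groups)))
    if len(groups) < 2:
        raise DamageStatsError("need at least 2 groups")
    for lvl, g in zip(levels, groups):
        if g.size < 2:
            raise DamageStatsError(f"group {lvl!r} needs >= 2 observations")
    return levels, groups


def anova_oneway(values, alpha: float = 0.05) -> GroupComparison:
    """Classical one-way ANOVA (between/within sum-of-squares decomposition).

    ``values`` is a mapping level -> observations or a sequence of
    observation arrays.  If every observation is identical the F statistic
    is taken as 0 (no evidence of group differences) with p = 1.
    """
    levels, groups = _as_groups(values)
    k = len(groups)
    n = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    mse = ss_within / df_w
    if mse == 0:
        f = 0.0 if ss_between == 0 else np.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        f = (ss_between / df_b) / mse
        p = float(sps.f.sf(f, df_b, df_w))
    return GroupComparison(
        levels=levels,
        means=np.array([g.mean() for g in groups]),
        f_statistic=float(f),
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        mse=float(mse),
        alpha=alpha,
    )


def lsd_test(values, alpha: float = 0.05) -> GroupComparison:
    """Fisher's least-significant-difference post-hoc test.

    LSD_ij = t(1 - alpha/2, df_within) * sqrt(MSE * (1/n_i + 1/n_j));
    a pair of means is significant when |mean_i - mean_j| > LSD_ij.
    """
    base = anova_oneway(values, alpha=alpha)
    _, groups = _as_groups(values)
    tcrit = sps.t.ppf(1 - alpha / 2, base.df_within)
    pairs = {}
    for (i, gi), (j, gj) in combinations(enumerate(groups), 2):
        lsd = tcrit * np.sqrt(base.mse * (1 / gi.size + 1 / gj.size))
        diff = abs(gi.mean() - gj.mean())
        pairs[(base.levels[i], base.levels[j])] = {
            "diff": float(diff),
            "critical": float(lsd),
            "significant": bool(diff > lsd),
        }
    return GroupComparison(
        levels=base.levels,
        means=base.means,
        f_statistic=base.f_statistic,
        p_value=base.p_value,
        df_between=base.df_between,
        df_within=base.df_within,
        mse=base.mse,
        alpha=alpha,
        method="lsd",
        pairs=pairs,
    )


def tukey_hsd(values, alpha: float = 0.05) -> GroupComparison:
    """Tukey's honestly-significant-difference post-hoc test.

    Critical difference for pair (i, j) uses the studentized range with the
    Tukey-Kramer correction for unequal group sizes:
    q(1 - alpha, k, df) * sqrt(MSE/2 * (1/n_i + 1/n_j)).
    """
    base = anova_oneway(values, alpha=alpha)
    _, groups = _as_groups(values)
    k = len(groups)
    q = sps.studentized_range.ppf(1 - alpha, k, base.df_within)
    pairs = {}
    for (i, gi), (j, gj) in combinations(enumerate(groups), 2):
        crit = q * np.sqrt(base.mse / 2 * (1 / gi.size + 1 / gj.size))
        diff = abs(gi.mean() - gj.mean())
        pairs[(base.levels[i], base.levels[j])] = {
            "diff": float(diff),
            "critical": float(crit),
            "significant": bool(diff > crit),
        }
    return GroupComparison(
        levels=base.levels,
        means=base.means,
        f_statistic=base.f_statistic,
        p_value=base.p_value,
        df_between=base.df_between,
        df_within=base.df_within,
        mse=base.mse,
        alpha=alpha,
        method="tukey",
        pairs=pairs,
    )


# ---------------------------------------------------------------------------
# study-level helpers
# ---------------------------------------------------------------------------

def ild_day_comparisons(
    records: Sequence[LeakageRecord],
    posthoc: str = "lsd",
    alpha: float = 0.05,
    aggregate_bags: bool = True,
) -> dict[str, GroupComparison]:
    """Per-treatment ANOVA of I_LD across storage days.

    Replicate measurements are aggregated to bag means before testing (the
    bag is the experimental unit), matching the 3 bags x 3 measurements
    replication structure.
    """
    df = leakage_frame(records)
    if aggregate_bags:
        df = df.groupby(["treatment", "day", "bag"], as_index=False)["ild"].mean()
    test = {"lsd": lsd_test, "tukey": tukey_hsd}.get(posthoc)
    if test is None:
        raise DamageStatsError(f"unknown post-hoc test {posthoc!r}")
    out = {}
    for treatment, sub in df.groupby("treatment"):
        groups = {int(day): s["ild"].to_numpy() for day, s in sub.groupby("day")}
        out[str(treatment)] = test(groups, alpha=alpha)
    return out


def enose_frame(vectors) -> pd.DataFrame:
    """SensorVector-like records (mappings or objects) as a DataFrame."""
    rows = []
    for v in vectors:
        if isinstance(v, Mapping):
            rows.append(dict(v))
        else:
            row = {"treatment": v.treatment, "day": v.day, "replicate": v.replicate}
            row.update(v.g_ratio)
            rows.append(row)
    df = pd.DataFrame(rows)
    missing = set(SENSORS) - set(df.columns)
    if missing:
        raise DamageStatsError(f"missing sensor columns: {sorted(missing)}")
    return df


def sensorwise_day_comparisons(
    df: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-(treatment, sensor) ANOVA + Tukey HSD across storage days.

    Replicates are first averaged within bag where a ``bag`` column exists.
    Returns a tidy table: treatment, sensor, F, p, n_significant_pairs.
    """
    if "bag" in df.columns:
        df = df.groupby(["treatment", "day", "bag"], as_index=False)[list(SENSORS)].mean()
    rows = []
    for treatment, sub in df.groupby("treatment"):
        for sensor in SENSORS:
            groups = {int(day): s[sensor].to_numpy() for day, s in sub.groupby("day")}
            cmp_ = tukey_hsd(groups, alpha=alpha)
            rows.append(
                {
                    "treatment": treatment,
                    "sensor": sensor,
                    "F": cmp_.f_statistic,
                    "p": cmp_.p_value,
                    "n_significant_pairs": len(cmp_.significant_pairs()),
                }
            )
    return pd.DataFrame(rows)


def enose_pca(df: pd.DataFrame, n_components: int = 2):
    """PCA biplot inputs for the E-nose table.

    Sensor responses are averaged per (treatment, day) and the columns are
    standardized before the decomposition, so every sensor contributes on an
    equal footing.  Returns (PCAResult, mean_table).
    """
    mean_table = df.groupby(["treatment", "day"], as_index=False)[list(SENSORS)].mean()
    X = mean_table[list(SENSORS)].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DamageStatsError("a sensor column has zero variance; cannot standardize")
    Z = (X - X.mean(axis=0)) / sd
    res = chemometrics.fit_pca(Z, n_components=n_components)
    return res, mean_table


def render_enose_biplot(res, mean_table: pd.DataFrame, path) -> None:
    """Scores + sensor-loading arrows on the first two components."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    labels = mean_table["treatment"].astype(str) + mean_table["day"].astype(str)
    ax.scatter(res.scores[:, 0], res.scores[:, 1], s=12)
    for x, y, lab in zip(res.scores[:, 0], res.scores[:, 1], labels):
        ax.annotate(lab, (x, y), fontsize=7)
    scale = np.abs(res.scores[:, :2]).max() / max(np.abs(res.loadings[:, :2]).max(), 1e-12)
    for sensor, (lx, ly) in zip(SENSORS, res.loadings[:, :2]):
        ax.arrow(0, 0, lx * scale * 0.8, ly * scale * 0.8, color="firebrick", width=0.002)
        ax.annotate(sensor, (lx * scale * 0.85, ly * scale * 0.85), color="firebrick", fontsize=8)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"PC1 ({res.explained_variance_pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({res.explained_variance_pct[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
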