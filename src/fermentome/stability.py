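"""In-situ stability assessment of synthetic communities.

Covers GC-MS peak filtering and internal-standard quantification, the
per-compound Welch + Benjamini-Hochberg differential test between two
sampling times, chemical-class metabolic deltas, a 2-component PCA
projection of the volatilome, biotype persistence tracking over
back-slopping, and (re-parameterized) Gompertz growth fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.decomposition import PCA

from .errors import FitError, ValidationError
from .model import GrowthModel, PeakTable, PersistenceLog, VocConfig, VOCTable
from .redundancy import bh_adjust


def filter_peaks(peaks: PeakTable, voc_config: Optional[VocConfig] = None) -> PeakTable:
    """Keep peaks with area strictly above 1e6 and match strictly above 85%."""
    cfg = voc_config or VocConfig()
    df = peaks.df
    keep = (df["peak_area"] > cfg.peak_area_threshold) & (
        df["spectral_match"] > cfg.spectral_match_threshold
    )
    return PeakTable(df[keep].reset_index(drop=True))


def quantify_voc(
    peak_area: float, is_area: float, voc_config: Optional[VocConfig] = None
) -> float:
    """Single-point internal-standard quantification (response factor 1).

    concentration = (peak area / internal-standard area) x 33 mg/l.
    """
    cfg = voc_config or VocConfig()
    if is_area <= 0:
        raise ValidationError("internal standard area must be positive")
    if peak_area < 0:
        raise ValidationError("peak area must be non-negative")
    return peak_area / is_area * cfg.internal_standard_mg_l


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch test; degenerate zero-variance cases handled."""
    if np.var(x) == 0 and np.var(y) == 0:
        return (0.0, 1.0) if np.mean(x) == np.mean(y) else (np.inf, 0.0)
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def voc_differential(
    voc_table: VOCTable,
    community: str,
    t0: str,
    t1: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-compound Welch test between two timepoints of one community.

    BH adjustment runs across this community's compound set only; a
    compound with fewer than 2 replicates at either timepoint is excluded
    with a warning.  Returns (statistic, p, q, significant) per compound.
    """
    df = voc_table.df
    df = df[df["community"] == community]
    if df.empty:
        raise ValidationError(f"community {community!r} absent from VOC table")
    rows = []
    skipped = []
    for compound, grp in df.groupby("compound"):
        x = grp.loc[grp["timepoint"] == t0, "concentration"].to_numpy(float)
        y = grp.loc[grp["timepoint"] == t1, "concentration"].to_numpy(float)
        if len(x) < 2 or len(y) < 2:
            skipped.append(compound)
            continue
        t, p = _welch(x, y)
        rows.append(
            {
                "compound": compound,
                "statistic": t,
                "p": p,
                "mean_t0": float(np.mean(x)),
                "mean_t1": float(np.mean(y)),
            }
        )
    if skipped:
        warnings.warn(
            f"{len(skipped)} compound(s) excluded (<2 replicates): {skipped[:5]}",
            stacklevel=2,
        )
    if not rows:
        raise ValidationError("no compound with >= 2 replicates at both timepoints")
    out = pd.DataFrame(rows).set_index("compound")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


def metabolic_delta(
    voc_table: VOCTable,
    significant: Iterable[str],
    community: str,
    t0: str,
    t1: str,
) -> pd.Series:
    """Per-chemical-class sum of mean concentration changes (t1 - t0),
    restricted to the statistically significant compounds."""
    sig = set(significant)
    classes = voc_table.compound_classes()
    unknown = sig - set(classes.index)
    if unknown:
        raise ValidationError(f"significant compounds not in table: {sorted(unknown)}")
    df = voc_table.df
    df = df[(df["community"] == community) & df["compound"].isin(sig)]
    deltas: dict[str, float] = {c: 0.0 for c in sorted(classes.unique())}
    for compound, grp in df.groupby("compound"):
        m0 = grp.loc[grp["timepoint"] == t0, "concentration"].mean()
        m1 = grp.loc[grp["timepoint"] == t1, "concentration"].mean()
        deltas[classes[compound]] += float(m1 - m0)
    return pd.Series(deltas).sort_index()


def pca_projection(voc_table: VOCTable) -> pd.DataFrame:
    """First two principal-component scores per (community, timepoint).

    Observations are replicate-averaged volatilome vectors; compound
    columns are z-scored, zero-variance columns dropped with a warning.
    The sign of each component is fixed so its largest-magnitude loading
    is positive.
    """
    wide = voc_table.df.pivot_table(
        index=["community", "timepoint"],
        columns="compound",
        values="concentration",
        aggfunc="mean",
        fill_value=0.0,
    )
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        raise ValidationError("PCA needs >= 2 observations and >= 2 compounds")
    sd = wide.std(axis=0, ddof=0)
    dead = sd[sd == 0].index
    if len(dead):
        warnings.warn(f"dropping {len(dead)} zero-variance compound(s)", stacklevel=2)
        wide = wide.drop(columns=dead)
        sd = sd.drop(dead)
    z = (wide - wide.mean(axis=0)) / sd
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    # deterministic sign: largest |loading| positive per component
    for k in range(scores.shape[1]):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, k] *= -1
    return pd.DataFrame(scores, index=wide.index, columns=["dim1", "dim2"])


@dataclass(frozen=True)
class PersistenceSummary:
    last_detected: pd.Series  # member -> last day with detected=True (or -1)
    survivors_by_day: dict[int, frozenset[str]]
    survivor_counts: pd.Series  # day -> number surviving


def track_persistence(log: PersistenceLog) -> PersistenceSummary:
    """Survivor sets per sampling day under the latest-record rule.

    A member survives at sampling day d iff its latest record at or
    before d has detected = True; re-detection after a miss is allowed.
    """
    df = log.df.sort_values("day")
    days = log.sampling_days
    members = sorted(df["member"].unique())
    last_det = {}
    for m in members:
        det = df[(df["member"] == m) & df["detected"]]["day"]
        last_det[m] = int(det.max()) if len(det) else -1
    survivors: dict[int, frozenset[str]] = {}
    for d in days:
        alive = set()
        for m in members:
            upto = df[(df["member"] == m) & (df["day"] <= d)]
            if len(upto) and bool(upto.iloc[-1]["detected"]):
                alive.add(m)
        survivors[d] = frozenset(alive)
    counts = pd.Series({d: len(v) for d, v in survivors.items()}).sort_index()
    return PersistenceSummary(
        last_detected=pd.Series(last_det).sort_index(),
        survivors_by_day=survivors,
        survivor_counts=counts,
    )


def gompertz(t: np.ndarray, a: float, mu_m: float, lag: float) -> np.ndarray:
    """Re-parameterized Gompertz: y = A exp(-exp(mu_m e / A (lag - t) + 1))."""
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        inner = mu_m * np.e / a * (lag - t) + 1.0
        return a * np.exp(-np.exp(inner))


@dataclass(frozen=True)
class GompertzFit:
    model: GrowthModel
    rss: float
    degenerate: bool = False


def fit_gompertz(
    time: Sequence[float], values: Sequence[float], *, n_starts: int = 5
) -> GompertzFit:
    """Least-squares Gompertz fit with multi-start initialization.

    Starts from a heuristic (A = max value, mu from the steepest observed
    slope, lag from the 10%-of-asymptote crossing) plus jittered variants;
    the best converged start by residual sum of squares wins.  A flat
    series returns a degenerate A = 0 fit rather than diverging.
    """
    t = np.asarray(list(time), dtype=float)
    y = np.asarray(list(values), dtype=float)
    if t.size < 4:
        raise ValidationError("need at least 4 time points")
    if not (np.isfinite(t).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in growth series")
    span = float(np.ptp(y))
    if span < 1e-12:
        return GompertzFit(
            model=GrowthModel(a=0.0, mu_m=0.0, lag=0.0),
            rss=float(np.sum((y - y.mean()) ** 2)),
            degenerate=True,
        )
    order = np.argsort(t)
    t, y = t[order], y[order]
    a0 = max(float(y.max()), 1e-6)
    slopes = np.diff(y) / np.maximum(np.diff(t), 1e-9)
    mu0 = max(float(slopes.max()), 1e-3)
    above = t[y >= 0.1 * a0]
    lag0 = float(above[0]) if len(above) else float(t[0])
    rng = np.random.default_rng(0)
    starts = [(a0, mu0, lag0)]
    for _ in range(n_starts - 1):
        starts.append(
            (
                a0 * rng.uniform(0.5, 1.5),
                mu0 * rng.uniform(0.3, 3.0),
                max(lag0 * rng.uniform(0.2, 2.0), 1e-3),
            )
        )
    best: Optional[tuple[float, np.ndarray]] = None
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    gompertz,
                    t,
                    y,
                    p0=p0,
                    bounds=([1e-9, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                    maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((gompertz(t, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise FitError(
            f"Gompertz fit failed to converge from {len(starts)} starts "
            f"(n={t.size}, span={span:.3g})"
        )
    rss, popt = best
    return GompertzFit(
        model=GrowthModel(a=float(popt[0]), mu_m=float(popt[1]), lag=float(popt[2])),
        rss=rss,
    )
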