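"""Growth-curve fitness statistics and fermentation consumption rates.

Fitness on a poor carbon source is scored from plate-reader OD600 time
series: AUC is the trapezoidal area under a strain's curve; ABC (area
between curves) subtracts the AUC of a transporter-negative reference strain
grown in the same medium (ABC = AUC_plus − AUC_minus); the fold utilization
capacity of a variant is the ratio of its ABC to the wild-type strain's ABC.

Fermentation consumption rates are the negated least-squares slope of an
analyte concentration (g/L) against time (hr) over a stated window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedStatisticError


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series for one well."""

    times: tuple[float, ...]
    od: tuple[float, ...]
    strain: str = ""
    replicate: int = 0

    def __post_init__(self):
        t = tuple(float(x) for x in self.times)
        y = tuple(float(x) for x in self.od)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", y)
        if len(t) != len(y):
            raise InputError("times and od must have equal length")
        if len(t) < 2:
            raise InputError("a growth curve needs at least 2 time points")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise InputError("times must be strictly increasing")
        if any(v < 0 for v in y):
            raise InputError("OD values must be non-negative")


@dataclass(frozen=True)
class FitnessResult:
    strain: str
    auc: float
    abc: float
    fold: float
    dispersion: float  # replicate SD of ABC
    n_replicates: int


@dataclass(frozen=True)
class FermentationSeries:
    """Concentration (g/L) of one analyte over time (hr)."""

    times: tuple[float, ...]
    concentrations: tuple[float, ...]
    analyte: str = ""

    def __post_init__(self):
        t = tuple(float(x) for x in self.times)
        c = tuple(float(x) for x in self.concentrations)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if len(t) != len(c):
            raise InputError("times and concentrations must have equal length")
        if any(v < 0 for v in c):
            raise InputError("concentrations must be non-negative")


def auc(curve: GrowthCurve) -> float:
    """Trapezoidal area under the curve over the observed span (OD·hr)."""
    return float(np.trapezoid(curve.od, curve.times))


def abc(curve_plus: GrowthCurve, curve_minus: GrowthCurve) -> float:
    """Area between two curves: AUC(plus) − AUC(minus), may be negative.

    Curves on different grids are linearly interpolated onto the union grid
    restricted to their overlapping time span; extrapolation is never
    performed (disjoint spans are an error).
    """
    if curve_plus.times == curve_minus.times:
        return auc(curve_plus) - auc(curve_minus)
    lo = max(curve_plus.times[0], curve_minus.times[0])
    hi = min(curve_plus.times[-1], curve_minus.times[-1])
    if lo >= hi:
        raise InputError("growth curves have disjoint time ranges")
    grid = np.union1d(np.asarray(curve_plus.times), np.asarray(curve_minus.times))
    grid = grid[(grid >= lo) & (grid <= hi)]
    plus = np.interp(grid, curve_plus.times, curve_plus.od)
    minus = np.interp(grid, curve_minus.times, curve_minus.od)
    return float(np.trapezoid(plus - minus, grid))


def fold_utilization(abc_variant, abc_reference) -> tuple[float, float]:
    """Ratio of variant ABC to reference ABC; (fold, dispersion).

    Scalars give (ratio, 0). Replicate arrays give the ratio of replicate
    means with a first-order (delta-method) standard error as dispersion.
    A variant with no growth above the negative reference gives fold 0.
    """
    v = np.atleast_1d(np.asarray(abc_variant, dtype=float))
    r = np.atleast_1d(np.asarray(abc_reference, dtype=float))
    mv, mr = v.mean(), r.mean()
    if mr <= 0:
        raise UndefinedStatisticError("reference ABC must be positive for a fold")
    fold = max(mv / mr, 0.0)
    if len(v) > 1 or len(r) > 1:
        sev2 = v.var(ddof=1) / len(v) if len(v) > 1 else 0.0
        ser2 = r.var(ddof=1) / len(r) if len(r) > 1 else 0.0
        disp = abs(mv / mr) * np.sqrt(
            (sev2 / mv**2 if mv != 0 else 0.0) + ser2 / mr**2
        )
    else:
        disp = 0.0
    return float(fold), float(disp)


def fitness_analysis(
    curves: list[GrowthCurve],
    reference_minus: str,
    reference_plus: str,
) -> dict[str, FitnessResult]:
    """Per-strain AUC/ABC/fold statistics from replicate growth curves.

    ``reference_minus`` is the transporter-negative strain whose mean AUC is
    subtracted from every replicate AUC; ``reference_plus`` is the wild-type
    transporter strain whose mean ABC is the fold denominator.
    """
    by_strain: dict[str, list[GrowthCurve]] = {}
    for c in curves:
        by_strain.setdefault(c.strain, []).append(c)
    for name in (reference_minus, reference_plus):
        if name not in by_strain:
            raise InputError(f"reference strain {name!r} absent from the curve set")
    minus_auc = float(np.mean([auc(c) for c in by_strain[reference_minus]]))
    abc_by_strain = {
        strain: np.array([auc(c) - minus_auc for c in reps])
        for strain, reps in by_strain.items()
    }
    ref_abcs = abc_by_strain[reference_plus]
    results = {}
    for strain, abcs in abc_by_strain.items():
        if strain == reference_minus:
            continue
        fold, _ = fold_utilization(abcs, ref_abcs)
        results[strain] = FitnessResult(
            strain=strain,
            auc=float(np.mean([auc(c) for c in by_strain[strain]])),
            abc=float(abcs.mean()),
            fold=fold,
            dispersion=float(abcs.std(ddof=1)) if len(abcs) > 1 else 0.0,
            n_replicates=len(abcs),
        )
    return results


def consumption_rate(
    series: FermentationSeries, window: tuple[float, float] | None = None
) -> float:
    """Consumption rate (g L^-1 hr^-1): negated least-squares slope over the window."""
    t = np.asarray(series.times)
    c = np.asarray(series.concentrations)
    if window is not None:
        lo, hi = window
        keep = (t >= lo) & (t <= hi)
        t, c = t[keep], c[keep]
    if len(t) < 2:
        raise InputError("need at least 2 points inside the window")
    slope = np.polyfit(t, c, 1)[0]
    return float(-slope)


def read_growth_curves(path) -> list[GrowthCurve]:
    """Read long-format CSV (time_hr, od, strain, replicate) into curves."""
    df = pd.read_csv(path)
    required = {"time_hr", "od", "strain", "replicate"}
    if not required <= set(df.columns):
        raise InputError(f"growth CSV must have columns {sorted(required)}")
    curves = []
    for (strain, rep), grp in df.groupby(["strain", "replicate"], sort=True):
        grp = grp.sort_values("time_hr")
        curves.append(
            GrowthCurve(
                times=tuple(grp["time_hr"]),
                od=tuple(grp["od"]),
                strain=str(strain),
                replicate=int(rep),
            )
        )
    return curves


def read_fermentation_series(path) -> dict[str, FermentationSeries]:
    """Read long-format CSV (time_hr, value, analyte) into per-analyte series."""
    df = pd.read_csv(path)
    required = {"time_hr", "value", "analyte"}
    if not required <= set(df.columns):
        raise InputError(f"fermentation CSV must have columns {sorted(required)}")
    out = {}
    for analyte, grp in df.groupby("analyte", sort=True):
        grp = grp.sort_values("time_hr")
        out[str(analyte)] = FermentationSeries(
            times=tuple(grp["time_hr"]),
            concentrations=tuple(grp["value"]),
            analyte=str(analyte),
        )
    return out
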