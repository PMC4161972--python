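"""Targeting-efficiency proportions and sgRNA abundance fold changes.

Targeting efficiency is the fraction of transformant colonies on the
selection plate (YPD+G418) that pass the phenotype screen; it is reported
with a binomial confidence interval (Wilson score by default, which stays
well-behaved at 0% and 100%).

sgRNA abundance is quantified by the comparative-CT (ΔΔCT) method: per
condition, ΔCT = mean CT(target) − mean CT(endogenous control); the fold
change of the test condition over the reference is 2^(−ΔΔCT) with
ΔΔCT = ΔCT_test − ΔCT_reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import InputError, ParameterError, UndefinedStatisticError

_CI_METHODS = {"wilson": "wilson", "exact": "beta", "beta": "beta", "normal": "normal"}


@dataclass(frozen=True)
class ColonyCounts:
    """Colony counts from one targeting experiment."""

    experiment: str
    total_g418: int
    phenotype_positive: int

    def __post_init__(self):
        if self.total_g418 < 0 or not 0 <= self.phenotype_positive <= self.total_g418:
            raise ParameterError(
                f"{self.experiment!r}: need 0 <= positive ({self.phenotype_positive}) "
                f"<= total ({self.total_g418})"
            )


@dataclass(frozen=True)
class EfficiencyEstimate:
    proportion: float
    ci_low: float
    ci_high: float
    n: int
    method: str = "wilson"
    confidence: float = 0.95

    def __post_init__(self):
        if not (0 <= self.ci_low <= self.proportion <= self.ci_high <= 1):
            raise ParameterError("efficiency estimate out of order or out of [0,1]")


def targeting_efficiency(
    counts: ColonyCounts, ci_method: str = "wilson", confidence: float = 0.95
) -> EfficiencyEstimate:
    """Phenotype-positive fraction of selection-plate colonies, with a two-sided CI."""
    if counts.total_g418 == 0:
        raise UndefinedStatisticError(
            f"{counts.experiment!r}: efficiency undefined for zero colonies"
        )
    if ci_method not in _CI_METHODS:
        raise ParameterError(f"unknown CI method {ci_method!r}")
    p = counts.phenotype_positive / counts.total_g418
    low, high = proportion_confint(
        counts.phenotype_positive,
        counts.total_g418,
        alpha=1 - confidence,
        method=_CI_METHODS[ci_method],
    )
    # degenerate ends can come back as nan from some methods
    low = 0.0 if np.isnan(low) else float(low)
    high = 1.0 if np.isnan(high) else float(high)
    return EfficiencyEstimate(
        proportion=p, ci_low=min(low, p), ci_high=max(high, p),
        n=counts.total_g418, method=ci_method, confidence=confidence,
    )


def read_colony_counts(path) -> list[ColonyCounts]:
    """Read a TSV with columns experiment, total, positive."""
    df = pd.read_csv(path, sep="\t")
    required = {"experiment", "total", "positive"}
    if not required <= set(df.columns):
        raise InputError(f"colony count table must have columns {sorted(required)}")
    return [
        ColonyCounts(str(r.experiment), int(r.total), int(r.positive))
        for r in df.itertuples()
    ]


@dataclass(frozen=True)
class CtPanel:
    """Replicate qPCR threshold cycles for one condition.

    ``target_ct`` are CTs for the transcript of interest (the sgRNA);
    ``control_ct`` for the endogenous control transcript (e.g. UBC6).
    """

    target_ct: tuple[float, ...]
    control_ct: tuple[float, ...]
    condition: str = ""

    def __post_init__(self):
        t = tuple(float(x) for x in self.target_ct)
        c = tuple(float(x) for x in self.control_ct)
        object.__setattr__(self, "target_ct", t)
        object.__setattr__(self, "control_ct", c)
        if len(t) < 1 or len(c) < 1:
            raise InputError("each CT panel needs at least one replicate")
        if any(x <= 0 for x in t + c):
            raise InputError("CT values must be positive")

    @property
    def delta_ct(self) -> float:
        return float(np.mean(self.target_ct) - np.mean(self.control_ct))

    @property
    def delta_ct_se(self) -> float:
        t, c = np.asarray(self.target_ct), np.asarray(self.control_ct)
        vt = t.var(ddof=1) / len(t) if len(t) > 1 else 0.0
        vc = c.var(ddof=1) / len(c) if len(c) > 1 else 0.0
        return float(np.sqrt(vt + vc))


@dataclass(frozen=True)
class DdctResult:
    fold: float
    ddct: float
    ddct_se: float
    fold_low: float
    fold_high: float
    test_condition: str = ""
    reference_condition: str = ""


def ddct_fold_change(
    test: CtPanel, reference: CtPanel, pairing: str = "mean"
) -> DdctResult:
    """Comparative-CT fold change of the test condition over the reference.

    ``pairing='mean'`` differences per-condition mean CTs (default);
    ``pairing='paired'`` pairs target/control replicates by index (requires
    equal replicate counts) before averaging. Replicate dispersion is
    propagated to a ±1 SE band on the fold.
    """
    if pairing == "mean":
        dct_t, dct_r = test.delta_ct, reference.delta_ct
        se = float(np.sqrt(test.delta_ct_se**2 + reference.delta_ct_se**2))
    elif pairing == "paired":
        for panel in (test, reference):
            if len(panel.target_ct) != len(panel.control_ct):
                raise InputError("paired mode requires equal target/control replicate counts")
        d_t = np.asarray(test.target_ct) - np.asarray(test.control_ct)
        d_r = np.asarray(reference.target_ct) - np.asarray(reference.control_ct)
        dct_t, dct_r = float(d_t.mean()), float(d_r.mean())
        vt = d_t.var(ddof=1) / len(d_t) if len(d_t) > 1 else 0.0
        vr = d_r.var(ddof=1) / len(d_r) if len(d_r) > 1 else 0.0
        se = float(np.sqrt(vt + vr))
    else:
        raise ParameterError(f"unknown pairing mode {pairing!r}")
    ddct = dct_t - dct_r
    return DdctResult(
        fold=float(2.0 ** (-ddct)),
        ddct=float(ddct),
        ddct_se=se,
        fold_low=float(2.0 ** (-(ddct + se))),
        fold_high=float(2.0 ** (-(ddct - se))),
        test_condition=test.condition,
        reference_condition=reference.condition,
    )


def read_ct_panels(path) -> dict[str, CtPanel]:
    """Read a CSV with columns condition, replicate, target_ct, control_ct."""
    df = pd.read_csv(path)
    required = {"condition", "target_ct", "control_ct"}
    if not required <= set(df.columns):
        raise InputError(f"CT table must have columns {sorted(required)}")
    panels = {}
    for cond, grp in df.groupby("condition", sort=True):
        panels[str(cond)] = CtPanel(
            target_ct=tuple(grp["target_ct"]),
            control_ct=tuple(grp["control_ct"]),
            condition=str(cond),
        )
    return panels
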