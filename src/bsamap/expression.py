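"""Relative qPCR expression: ΔCt, 2^(−ΔΔCt) fold changes, Welch tests.

Expression of candidate genes is compared between male-sterile (ms) and
fertile (fs) plants at two bud stages (2 mm, tetrad; 5 mm, first pollen
mitosis).  Target-gene Ct values are normalised against a reference gene
(β-actin) per paired replicate, ΔΔCt is taken against a calibrator
condition (fertile 2-mm buds), and fold change is 2^(−ΔΔCt).  Group
differences are tested on the ΔCt scale — where qPCR noise is close to
Gaussian — with Welch's two-sample t-test, called significant below
alpha = 0.01 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtMeasurement",
    "delta_ct",
    "relative_expression",
    "compare_expression",
    "analyze_ct_table",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class CtMeasurement:
    """Replicate Ct values for one gene in one (group, stage) condition."""

    gene: str
    group: str  # "ms" (sterile) or "fs" (fertile)
    stage: str  # "2mm" or "5mm"
    target_ct: tuple[float, ...]
    reference_ct: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.target_ct) < 2:
            raise ValueError("need at least two replicates")
        for ct in (*self.target_ct, *self.reference_ct):
            if not (0 < ct < 45):
                raise ValueError(f"Ct value {ct} outside the plausible (0, 45) range")


def delta_ct(measurement: CtMeasurement) -> np.ndarray:
    """Per-replicate ΔCt = Ct(target) − Ct(reference), paired by run."""
    if len(measurement.target_ct) != len(measurement.reference_ct):
        raise ValueError("target and reference replicate counts differ")
    return np.asarray(measurement.target_ct) - np.asarray(measurement.reference_ct)


def relative_expression(
    sample: CtMeasurement, calibrator: CtMeasurement
) -> tuple[float, float]:
    """Fold change of sample vs calibrator by the 2^(−ΔΔCt) method.

    ΔΔCt = mean ΔCt(sample) − mean ΔCt(calibrator); the returned
    dispersion is the fold-scale standard error fold·ln2·SE(ΔΔCt) with
    replicate SEs combined in quadrature.
    """
    d_s, d_c = delta_ct(sample), delta_ct(calibrator)
    ddct = float(d_s.mean() - d_c.mean())
    fold = 2.0 ** (-ddct)
    se = math.sqrt(
        d_s.var(ddof=1) / d_s.size + d_c.var(ddof=1) / d_c.size
    )
    return fold, fold * math.log(2) * se


def compare_expression(
    group1: Sequence[float],
    group2: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
) -> tuple[float, float, bool]:
    """Welch two-sided t-test on replicate ΔCt values.

    Returns ``(t, p, significant)`` with significant = p < alpha.
    Degenerate zero-variance inputs are handled explicitly: equal means
    give p = 1, distinct means p = 0.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two replicates per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0, False
        return math.inf if x.mean() > y.mean() else -math.inf, 0.0, 0.0 < alpha
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p), bool(p < alpha)


def analyze_ct_table(
    ct_table: pd.DataFrame,
    calibrator: tuple[str, str] = ("fs", "2mm"),
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-gene fold changes and significance calls against a calibrator.

    ``ct_table`` columns: ``gene, group, stage, replicate, ct_target,
    ct_reference``.  For every gene and condition the fold change vs the
    gene's calibrator condition (default fertile 2-mm buds) and a Welch
    test of the ΔCt replicates against the calibrator's are reported.
    """
    rows = []
    for gene, sub in ct_table.groupby("gene", sort=True):
        conditions = {
            (g, s): CtMeasurement(
                gene=gene,
                group=g,
                stage=s,
                target_ct=tuple(grp["ct_target"]),
                reference_ct=tuple(grp["ct_reference"]),
            )
            for (g, s), grp in sub.groupby(["group", "stage"], sort=True)
        }
        if calibrator not in conditions:
            raise ValueError(f"{gene}: calibrator condition {calibrator} absent")
        cal = conditions[calibrator]
        for (group, stage), meas in sorted(conditions.items()):
            fold, disp = relative_expression(meas, cal)
            if (group, stage) == calibrator:
                t, p, sig = 0.0, 1.0, False
            else:
                t, p, sig = compare_expression(delta_ct(meas), delta_ct(cal), alpha)
            rows.append(
                {
                    "gene": gene,
                    "group": group,
                    "stage": stage,
                    "fold": fold,
                    "fold_se": disp,
                    "t": t,
                    "p": p,
                    "significant": sig,
                }
            )
    return pd.DataFrame(rows)
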