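"""Co-administration dose-response analysis.

Works on plate-format viability matrices: rows are concentrations of the
primary drug (e.g. gemcitabine) including a zero dose, columns are sensitiser
concentrations including zero, and each cell holds replicate raw readings
from a colorimetric viability assay (WST-1/MTT style).  The module normalises
to the untreated control (set to 100% viability), quantifies sensitiser
enhancement in percentage points, estimates dose-sparing by inverse
interpolation of the two dose-response columns, flags biphasic (hormesis)
behaviour, and compares treatment groups by one-way ANOVA with Tukey HSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


class PlateError(Exception):
    """Invalid dose-response matrix or analysis request."""


class HormesisError(PlateError):
    """The curve is non-monotone around the requested target viability."""


@dataclass
class DoseResponseMatrix:
    """Replicate raw signals over a (drug A x sensitiser) concentration grid.

    ``signals`` maps ``(dose_a, dose_b)`` to a 1-D array of replicate
    readings.  Both dose axes are strictly ascending, non-negative and
    include 0; the (0, 0) cell is the untreated control.
    """

    drug_a_doses: tuple
    sensitiser_doses: tuple
    signals: dict
    cell_line: str = ""

    def __post_init__(self):
        for axis in (self.drug_a_doses, self.sensitiser_doses):
            arr = np.asarray(axis, dtype=float)
            if arr.size == 0 or arr[0] != 0:
                raise PlateError("dose axes must start at the 0-dose control")
            if np.any(arr < 0) or np.any(np.diff(arr) <= 0):
                raise PlateError("doses must be non-negative and strictly ascending")
        self.signals = {
            (float(a), float(b)): np.asarray(v, dtype=float).ravel()
            for (a, b), v in self.signals.items()
        }
        for a in self.drug_a_doses:
            for b in self.sensitiser_doses:
                cell = self.signals.get((float(a), float(b)))
                if cell is None or cell.size == 0:
                    raise PlateError(f"cell ({a}, {b}) has no replicates")


@dataclass
class ViabilitySummary:
    """Per-cell viability as percent of untreated control (mean, SEM, n).

    Each field is a DataFrame indexed by drug-A dose with sensitiser doses as
    columns.  The control cell is exactly 100%.
    """

    mean_percent: pd.DataFrame
    sem_percent: pd.DataFrame
    n: pd.DataFrame
    cell_line: str = ""


def normalize_viability(m: DoseResponseMatrix) -> ViabilitySummary:
    """Express every cell as percent of the untreated-control mean.

    Replicates are aggregated first (mean, SEM) and then divided by the
    control mean; cells with a single replicate get SEM 0.
    """
    control = m.signals[(0.0, 0.0)]
    control_mean = float(np.mean(control))
    if control_mean <= 0:
        raise PlateError(f"control mean must be positive, got {control_mean}")

    a_doses = [float(a) for a in m.drug_a_doses]
    b_doses = [float(b) for b in m.sensitiser_doses]
    mean = pd.DataFrame(index=a_doses, columns=b_doses, dtype=float)
    sem = pd.DataFrame(index=a_doses, columns=b_doses, dtype=float)
    n = pd.DataFrame(index=a_doses, columns=b_doses, dtype=int)
    for a in a_doses:
        for b in b_doses:
            reps = m.signals[(a, b)]
            mean.loc[a, b] = np.mean(reps) / control_mean * 100.0
            sem.loc[a, b] = (
                np.std(reps, ddof=1) / np.sqrt(reps.size) / control_mean * 100.0
                if reps.size > 1
                else 0.0
            )
            n.loc[a, b] = reps.size
    return ViabilitySummary(mean_percent=mean, sem_percent=sem, n=n, cell_line=m.cell_line)


def enhancement_delta(v: ViabilitySummary, dose_a: float, dose_b: float) -> float:
    """Sensitiser enhancement in percentage points at a drug-A dose.

    Positive values mean the combination kills more than the drug alone
    (sensitisation); negative values signal antagonism and are reported, not
    clipped.  ``enhancement_delta(v, a, 0)`` is exactly 0.
    """
    for dose, axis in ((dose_a, v.mean_percent.index), (dose_b, v.mean_percent.columns)):
        if float(dose) not in axis:
            raise PlateError(f"dose {dose} not on the plate grid")
    alone = float(v.mean_percent.loc[float(dose_a), 0.0])
    combo = float(v.mean_percent.loc[float(dose_a), float(dose_b)])
    return alone - combo


def _invert_column(doses: np.ndarray, viab: np.ndarray, target: float) -> float:
    """Dose achieving ``target`` viability, by inverse piecewise-linear
    interpolation of viability against log10(dose).

    The 0-dose anchor must already be excluded.  Exactly one bracketing
    segment is required; none -> target outside the achievable range, more
    than one -> the curve is non-monotone around the target (hormesis).
    """
    crossings = []
    for i in range(len(viab) - 1):
        lo, hi = sorted((viab[i], viab[i + 1]))
        if lo <= target <= hi:
            crossings.append(i)
    if not crossings:
        raise PlateError(
            f"target viability {target}% outside the achievable interval "
            f"[{viab.min():.1f}%, {viab.max():.1f}%] of this column"
        )
    if len(crossings) > 1:
        raise HormesisError(
            f"viability crosses {target}% more than once; inspect the column "
            "for a biphasic (hormesis) response before interpolating"
        )
    i = crossings[0]
    v1, v2 = viab[i], viab[i + 1]
    lam = 0.5 if v1 == v2 else (v1 - target) / (v1 - v2)
    lg = np.log10(doses)
    return float(10 ** (lg[i] + lam * (lg[i + 1] - lg[i])))


def dose_sparing(
    v: ViabilitySummary, sensitiser_dose: float, target_viability: float
) -> float:
    """Fractional reduction in the primary drug's dose needed to reach
    ``target_viability`` when the sensitiser is present.

    Both the drug-alone column and the combination column are inverted at the
    target by piecewise-linear interpolation on log10(dose) (the 0-dose
    anchor is excluded); the result is ``1 - D_combo / D_alone``.
    """
    if float(sensitiser_dose) not in v.mean_percent.columns:
        raise PlateError(f"sensitiser dose {sensitiser_dose} not on the plate grid")
    doses = np.asarray([a for a in v.mean_percent.index if a > 0], dtype=float)
    if doses.size < 2:
        raise PlateError("need at least two non-zero drug-A doses to interpolate")
    alone = v.mean_percent.loc[doses, 0.0].to_numpy(dtype=float)
    combo = v.mean_percent.loc[doses, float(sensitiser_dose)].to_numpy(dtype=float)
    d_alone = _invert_column(doses, alone, target_viability)
    d_combo = _invert_column(doses, combo, target_viability)
    return 1.0 - d_combo / d_alone


def detect_hormesis(
    v: ViabilitySummary, column: float, k: float = 2.0
) -> tuple[bool, list]:
    """Flag a biphasic (hormesis) response in one sensitiser column.

    The column's viability curve over the drug-A doses is scanned over every
    ordered dose pair; hormesis is flagged when a higher dose's mean
    viability exceeds a lower dose's mean by more than ``k`` times the pooled
    SEM ``sqrt(sem_lo^2 + sem_hi^2)``.  Returns the flag and the offending
    ``(lower dose, higher dose)`` pairs.
    """
    col = float(column)
    if col not in v.mean_percent.columns:
        raise PlateError(f"sensitiser dose {column} not on the plate grid")
    doses = list(v.mean_percent.index)
    if len(doses) < 3:
        raise PlateError("hormesis detection needs at least 3 dose points")
    means = v.mean_percent[col].to_numpy(dtype=float)
    sems = v.sem_percent[col].to_numpy(dtype=float)
    locations = []
    for i in range(len(doses)):
        for j in range(i + 1, len(doses)):
            pooled = float(np.hypot(sems[i], sems[j]))
            if means[j] - means[i] > k * pooled:
                locations.append((doses[i], doses[j]))
    return (bool(locations), locations)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, p_adj, stars


def significance_stars(p: float) -> str:
    """Conventional significance marks at 0.05 / 0.01 / 0.001 / 0.0001."""
    for threshold, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < threshold:
            return stars
    return "ns"


def compare_groups(groups, labels=None) -> GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise correction.

    ``groups`` is a list of replicate arrays (>= 2 groups, each with >= 2
    replicates).  Degenerate all-identical data (zero variance everywhere)
    is reported as F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least two replicates")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]

    pooled = np.concatenate(groups)
    pairs = [(i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))]
    if np.ptp(pooled) == 0:
        pairwise = pd.DataFrame(
            [
                {"group_a": labels[i], "group_b": labels[j], "p_adj": 1.0, "stars": "ns"}
                for i, j in pairs
            ]
        )
        return GroupComparison(f_statistic=0.0, p_value=1.0, pairwise=pairwise)

    f_stat, p_val = stats.f_oneway(*groups)
    values = np.concatenate(groups)
    group_labels = np.concatenate(
        [np.full(g.size, labels[i], dtype=object) for i, g in enumerate(groups)]
    )
    tukey = pairwise_tukeyhsd(values, group_labels)
    frame = pd.DataFrame(
        tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]]
    )
    pairwise = pd.DataFrame(
        {
            "group_a": frame["group1"],
            "group_b": frame["group2"],
            "p_adj": frame["p-adj"].astype(float),
        }
    )
    pairwise["stars"] = pairwise["p_adj"].map(significance_stars)
    return GroupComparison(f_statistic=float(f_stat), p_value=float(p_val), pairwise=pairwise)


def vehicle_dilution_percent(fold: float) -> float:
    """Final vehicle (DMSO) concentration, % v/v, after a given fold dilution.

    A 5000-fold dilution of neat vehicle gives 100/5000 = 0.02% v/v.
    """
    if fold <= 0:
        raise ValueError("dilution fold must be positive")
    return 100.0 / fold
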