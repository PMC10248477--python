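"""Paired modality statistics: linear regression, Bland-Altman, cohort summaries.

Conventions (fixed so the printed agreement statistics are reproducible):

* regression direction: x = 4D flow MRI, y = CFD (ordinary least squares);
* Bland-Altman differences: d_i = CFD_i - MRI_i, bias = mean(d),
  sd = sample standard deviation (n-1 denominator),
  limits of agreement = bias +/- 1.96 sd;
* cohort summaries report mean +/- sample SD, rounded to 2 decimals for
  m/s, mJ, mW and mm and 1 decimal for percentages.

The packaged reference cohort (29 Fontan patients, energetics / pulmonary
flow distribution / regional tables for both modalities) is available via
:func:`load_reference_cohort` so the statistics layer can be exercised
without any field data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, FormatError, InputError

#: p-value threshold reported alongside regressions (never used to drop data)
SIGNIFICANCE_LEVEL = 0.05

_FIXTURES = {
    "energetics": "fontan29_energetics.csv",
    "pfd": "fontan29_pfd.csv",
    "regional": "fontan29_regional.csv",
}


@dataclass
class PairedMetric:
    """Per-case values of one metric from both modalities."""

    name: str
    unit: str
    mri: np.ndarray
    cfd: np.ndarray
    case_ids: list[str]

    def __post_init__(self) -> None:
        self.mri = np.asarray(self.mri, float)
        self.cfd = np.asarray(self.cfd, float)
        if self.mri.shape != self.cfd.shape or self.mri.ndim != 1:
            raise InputError("paired series must be 1D and of equal length")
        if len(self.mri) < 3:
            raise InputError("paired comparison needs at least 3 cases")
        if not (np.isfinite(self.mri).all() and np.isfinite(self.cfd).all()):
            raise InputError(f"metric {self.name}: missing value in a pair")


@dataclass
class ComparisonStats:
    """Regression + Bland-Altman agreement for one paired metric."""

    metric: str
    n: int
    slope: float
    intercept: float
    r: float
    p: float
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    direction: str = "cfd-mri"


def linear_regression(mri, cfd) -> tuple[float, float, float, float]:
    """OLS of CFD on MRI: returns (slope, intercept, Pearson r, two-sided p).

    The p-value tests r = 0 with the t distribution on n-2 degrees of
    freedom.
    """
    x = np.asarray(mri, float)
    y = np.asarray(cfd, float)
    if len(x) < 3:
        raise InputError("regression needs n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance in the MRI series")
    res = stats.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue), float(res.pvalue))


def bland_altman(mri, cfd, direction: str = "cfd-mri"
                 ) -> tuple[float, float, tuple[float, float]]:
    """Bias, sample SD and 1.96-SD limits of agreement of paired differences.

    ``direction`` selects d = CFD - MRI (default) or "mri-cfd".
    """
    a = np.asarray(mri, float)
    b = np.asarray(cfd, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise InputError("need two equal-length series with n >= 2")
    d = b - a if direction == "cfd-mri" else a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, (bias - 1.96 * sd, bias + 1.96 * sd)


def compare_paired(metric: PairedMetric, direction: str = "cfd-mri"
                   ) -> ComparisonStats:
    slope, intercept, r, p = linear_regression(metric.mri, metric.cfd)
    bias, sd, (lo, hi) = bland_altman(metric.mri, metric.cfd, direction)
    return ComparisonStats(metric=metric.name, n=len(metric.mri),
                           slope=slope, intercept=intercept, r=r, p=p,
                           bias=bias, sd=sd, loa_low=lo, loa_high=hi,
                           direction=direction)


def _decimals_for(column: str) -> int:
    return 1 if "pfd" in column.lower() or column.endswith("%") else 2


def cohort_summary(table: pd.DataFrame, columns=None,
                   decimals: dict[str, int] | None = None) -> pd.DataFrame:
    """Mean and sample SD per numeric column, with a rounded display row.

    Returns a DataFrame indexed by column with ``mean``, ``sd``, ``n`` and a
    formatted ``mean_sd`` string rounded per column (1 decimal for
    percentages, 2 otherwise, overridable via ``decimals``).
    """
    if columns is None:
        columns = [c for c in table.columns
                   if pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for col in columns:
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any():
            bad = table.index[vals.isna()][0]
            raise FormatError(f"non-numeric cell in column {col!r}, row {bad}")
        dp = (decimals or {}).get(col, _decimals_for(col))
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append({"column": col, "n": len(vals), "mean": mean, "sd": sd,
                     "mean_sd": f"{mean:.{dp}f} ± {sd:.{dp}f}"})
    return pd.DataFrame(rows).set_index("column")


def paired_metrics(table: pd.DataFrame, unit_map: dict[str, str] | None = None
                   ) -> list[PairedMetric]:
    """Extract ``metric__mri`` / ``metric__cfd`` column pairs from a cohort CSV."""
    metrics = []
    case_ids = [str(c) for c in
                (table["case"] if "case" in table.columns else table.index)]
    names = sorted({c[:-5] for c in table.columns if c.endswith("__mri")})
    for name in names:
        if f"{name}__cfd" not in table.columns:
            continue
        metrics.append(PairedMetric(
            name=name, unit=(unit_map or {}).get(name, ""),
            mri=table[f"{name}__mri"].to_numpy(float),
            cfd=table[f"{name}__cfd"].to_numpy(float),
            case_ids=case_ids))
    return metrics


def compare_cohort(table: pd.DataFrame, direction: str = "cfd-mri"
                   ) -> pd.DataFrame:
    """ComparisonStats for every paired metric in a cohort table."""
    rows = [compare_paired(m, direction).__dict__
            for m in paired_metrics(table)]
    return pd.DataFrame(rows).set_index("metric")


def load_reference_cohort(name: str) -> pd.DataFrame:
    """Load a packaged reference cohort table.

    ``name`` is one of ``energetics`` (Vmax/KE/VD per modality), ``pfd``
    (pulmonary flow distribution per modality) or ``regional`` (MRI-only
    per-region Vmean/KE/VD/diameter), each with one row per patient.
    """
    if name not in _FIXTURES:
        raise InputError(f"unknown reference table {name!r}; "
                         f"choose from {sorted(_FIXTURES)}")
    ref = resources.files("fontanflow.data") / _FIXTURES[name]
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
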