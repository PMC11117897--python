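"""Phenotype-microarray (Biolog PM-M style) metabolic profiling of cell lines.

Plates expose cells to one carbon energy source per well; after incubation
with a tetrazolium redox dye, NADH production is read as dual-wavelength
absorbance — A590 is the dye peak, A750 the background — and the per-well
NADH proxy is the relative absorbance A590 − A750. The analysis steps are:

* background filtering: compounds whose signal is not distinguishable from
  the no-cell negative control are removed (one-sided Welch test),
* group comparison per compound: one-way ANOVA with Tukey HSD post hoc,
* PCA over the cell-line × compound profile matrix, with per-compound
  contributions to each dimension,
* db-cAMP dose–response: values normalised to the zero-dose baseline and a
  monotone-trend test across dose levels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PLATE_IDS",
    "PlateAssay",
    "MetabolicProfile",
    "PCAResult",
    "AnovaTukeyResult",
    "DoseResponse",
    "load_plate_layout",
    "relative_absorbance",
    "profile_from_assay",
    "filter_background",
    "anova_tukey",
    "pca_metabolic",
    "dose_response",
    "dbcamp_dose",
]

PLATE_IDS = ("PM-M1", "PM-M2", "PM-M3", "PM-M4", "PM-M6")
_LAYOUT_FILES = {p: f"layout_pm_{p[-2:].lower()}.csv" for p in PLATE_IDS}
_DOSE_RE = re.compile(r"^db-cAMP ([0-9.]+) uM$")


@dataclass
class PlateAssay:
    """One 96-well plate read for one cell line.

    ``wells`` maps well id → (compound, a590, a750); compound ``"blank"``
    marks negative-control wells.
    """

    plate_id: str
    wells: dict
    cell_line_id: str
    group: str
    treatment: str = "none"

    def __post_init__(self) -> None:
        if self.plate_id not in PLATE_IDS:
            raise ValueError(f"unknown plate id {self.plate_id!r}")
        if len(self.wells) != 96:
            raise ValueError(f"expected 96 wells, got {len(self.wells)}")
        for w, (comp, a590, a750) in self.wells.items():
            if a590 < 0 or a750 < 0:
                raise ValueError(f"negative absorbance in well {w}")


@dataclass
class MetabolicProfile:
    """Per-compound NADH proxy (relative absorbance) for one cell line."""

    cell_line_id: str
    group: str
    treatment: str
    values: pd.Series  # compound -> A590-750

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("profile values must be finite")


@dataclass
class PCAResult:
    scores: pd.DataFrame  # observations × dims
    loadings: pd.DataFrame  # variables × dims
    variance_explained: np.ndarray
    contributions: pd.DataFrame  # variables × dims, each column sums to 1


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group1, group2, diff, p_adj


@dataclass
class DoseResponse:
    curve: pd.DataFrame  # dose, value, normalized
    baseline: float
    p_trend: float
    trend_method: str = field(default="anova")


def load_plate_layout(plate_id: str) -> pd.Series:
    """Packaged synthetic PM-M-style layout: well → compound name."""
    try:
        fname = _LAYOUT_FILES[plate_id]
    except KeyError:
        raise ValueError(f"unknown plate id {plate_id!r}") from None
    text = resources.files("endophen.resources").joinpath(fname).read_text()
    rows = [ln.split(",", 1) for ln in text.strip().splitlines()[1:]]
    return pd.Series({w: c for w, c in rows}, name="compound")


def relative_absorbance(a590, a750):
    """NADH proxy per well: dye absorbance minus background, A590 − A750."""
    a590 = np.asarray(a590, dtype=float)
    a750 = np.asarray(a750, dtype=float)
    if not (np.isfinite(a590).all() and np.isfinite(a750).all()):
        raise ValueError("absorbances must be finite")
    if (a590 < 0).any() or (a750 < 0).any():
        raise ValueError("absorbances must be non-negative")
    out = a590 - a750
    return float(out) if out.ndim == 0 else out


def profile_from_assay(assay: PlateAssay) -> MetabolicProfile:
    """Collapse a plate to a per-compound profile (mean over same-compound wells).

    Blank (negative-control) wells are excluded; use them, or dedicated
    no-cell plates, as the blank reference for ``filter_background``.
    """
    vals: dict[str, list[float]] = {}
    for _, (comp, a590, a750) in assay.wells.items():
        if comp == "blank":
            continue
        vals.setdefault(comp, []).append(relative_absorbance(a590, a750))
    series = pd.Series({c: float(np.mean(v)) for c, v in vals.items()})
    return MetabolicProfile(
        cell_line_id=assay.cell_line_id,
        group=assay.group,
        treatment=assay.treatment,
        values=series,
    )


def filter_background(
    profiles: list[MetabolicProfile],
    blanks: list[MetabolicProfile],
    alpha: float = 0.05,
) -> tuple[list[str], pd.Series]:
    """Remove compounds indistinguishable from the no-cell negative control.

    Per compound, a one-sided Welch t-test asks whether cell values exceed
    blank values; compounds failing at level ``alpha`` are removed. Returns
    the kept compound list and the per-compound p-values.
    """
    if not profiles or not blanks:
        raise ValueError("need at least one cell profile and one blank profile")
    compounds = list(profiles[0].values.index)
    pvals = {}
    for comp in compounds:
        cell = np.array([p.values[comp] for p in profiles if comp in p.values.index])
        blank = np.array([b.values[comp] for b in blanks if comp in b.values.index])
        if blank.size < 2:
            raise ValueError(f"compound {comp!r}: need >=2 blank observations")
        pvals[comp] = stats.ttest_ind(
            cell, blank, equal_var=False, alternative="greater"
        ).pvalue
    pvals = pd.Series(pvals, name="p_vs_blank")
    kept = [c for c in compounds if pvals[c] < alpha]
    return kept, pvals


def anova_tukey(values_by_group: dict) -> AnovaTukeyResult:
    """One-way ANOVA across groups followed by Tukey's HSD post hoc test.

    Unequal group sizes are handled by the Tukey–Kramer adjustment.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    for g, arr in zip(groups, arrays):
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat, p = stats.f_oneway(*arrays)
    if np.isnan(f_stat):  # zero between- and within-group variance
        f_stat, p = 0.0, 1.0
    elif np.isinf(f_stat):  # groups differ with zero within-group variance
        p = 0.0
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                {
                    "group1": groups[i],
                    "group2": groups[j],
                    "diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": float(hsd.pvalue[i, j]),
                }
            )
    return AnovaTukeyResult(
        f_statistic=float(f_stat), p_value=float(p), pairwise=pd.DataFrame(rows)
    )


def pca_metabolic(matrix: pd.DataFrame, scale: bool = True) -> PCAResult:
    """PCA of an observations × compounds profile matrix.

    ``scale=True`` (default) runs correlation-mode PCA (columns centred and
    unit-scaled), appropriate when compounds have heterogeneous dynamic
    ranges; ``scale=False`` gives covariance-mode PCA. Contributions are the
    squared loadings, normalised per dimension.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains missing or non-finite values")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = list(matrix.columns[sd == 0])
            raise ValueError(f"zero-variance columns cannot be unit-scaled: {bad[:10]}")
        Xc = Xc / sd
    u, sv, vt = np.linalg.svd(Xc, full_matrices=False)
    ndim = min(X.shape[0] - 1, X.shape[1])
    u, sv, vt = u[:, :ndim], sv[:ndim], vt[:ndim]
    var = sv**2 / (X.shape[0] - 1)
    var_expl = var / (Xc.var(axis=0, ddof=1).sum())
    dims = [f"dim{i + 1}" for i in range(ndim)]
    scores = pd.DataFrame(u * sv, index=matrix.index, columns=dims)
    loadings = pd.DataFrame(vt.T, index=matrix.columns, columns=dims)
    contrib = loadings**2
    contrib = contrib / contrib.sum(axis=0)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_explained=var_expl,
        contributions=contrib,
    )


def dbcamp_dose(compound: str) -> float | None:
    """Parse the db-cAMP dose (µM) from a dose-series compound label."""
    m = _DOSE_RE.match(compound)
    return float(m.group(1)) if m else None


def dose_response(series, baseline: float | None = None) -> DoseResponse:
    """Normalise a dose series to its zero-dose baseline and test for a trend.

    ``series`` is an iterable of (dose, value) pairs; the baseline defaults to
    the mean value at dose zero and must be positive. Values are divided by
    the baseline (so the zero-dose level is exactly 1). The trend p-value is
    a one-way ANOVA across dose levels when every level has at least two
    observations, otherwise the slope t-test of a linear regression on dose.
    """
    df = pd.DataFrame(list(series), columns=["dose", "value"])
    if baseline is None:
        at_zero = df.loc[df["dose"] == 0, "value"]
        if at_zero.empty:
            raise ValueError("no zero-dose value present and no baseline given")
        baseline = float(at_zero.mean())
    if not np.isfinite(baseline) or baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    df["normalized"] = df["value"] / baseline
    by_level = [g["normalized"].to_numpy() for _, g in df.groupby("dose")]
    if len(by_level) < 2:
        raise ValueError("need at least two dose levels")
    if all(len(v) >= 2 for v in by_level):
        f, p = stats.f_oneway(*by_level)
        if not np.isfinite(f):
            p = 1.0
        method = "anova"
    else:
        res = stats.linregress(df["dose"], df["normalized"])
        p = res.pvalue if np.isfinite(res.pvalue) else 1.0
        method = "linregress"
    return DoseResponse(
        curve=df, baseline=baseline, p_trend=float(p), trend_method=method
    )
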