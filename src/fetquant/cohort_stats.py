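"""Cohort-level summaries and hypothesis tests.

The statistics layer mirrors a standard neuro-oncology imaging cohort
analysis: metric variables summarized as median (range), categorical
variables as n (%), group comparisons via Pearson χ² (no continuity
correction), Fisher's exact test, Mann–Whitney U and Kruskal–Wallis, and
rater agreement via Cohen's κ. Significance is two-tailed at p < 0.05 and no
multiple-testing correction is applied anywhere — every p-value is reported
as computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

HISTOLOGIES = ("astrocytoma", "oligodendroglioma")
CURVE_CLASSES = ("increasing", "stable", "decreasing")

#: Exact p-values switch to the asymptotic approximation above this combined n.
EXACT_N_THRESHOLD = 25


@dataclass
class PatientRecord:
    """One row of the cohort table.

    Missing values (no dynamic scan, no CE lesion, PET-negative) are None
    and excluded per analysis with the exclusion count reported.
    """

    patient_id: str
    histology: str
    who_grade: int
    ce_present: bool
    pet_positive: bool
    tbr_max: Optional[float] = None
    tbr_mean: Optional[float] = None
    pet_volume_ml: Optional[float] = None
    curve_class: Optional[str] = None
    ttp_min: Optional[float] = None
    dice_flair: Optional[float] = None
    dice_ce: Optional[float] = None

    def __post_init__(self) -> None:
        if self.histology not in HISTOLOGIES:
            raise ValueError(f"unknown histology {self.histology!r}")
        if self.who_grade not in (2, 3, 4):
            raise ValueError(f"WHO grade must be 2, 3 or 4, got {self.who_grade}")
        if self.who_grade == 4 and self.histology != "astrocytoma":
            raise ValueError("WHO grade 4 occurs only in astrocytoma")
        if self.curve_class is not None and self.curve_class not in CURVE_CLASSES:
            raise ValueError(f"unknown curve class {self.curve_class!r}")
        for name in ("tbr_max", "tbr_mean"):
            v = getattr(self, name)
            if v is not None and v < 1.0 - 1e-9:
                raise ValueError(f"{name} must be >= 1 when present, got {v}")


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)) or np.any(arr < 0):
                raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", arr.astype(np.int64))
        if arr.sum() <= 0:
            raise ValueError("grand total must be positive")
        if len(self.row_labels) != arr.shape[0] or len(self.col_labels) != arr.shape[1]:
            raise ValueError("label lengths must match table shape")

    @classmethod
    def from_arrays(
        cls, rows: Sequence, cols: Sequence, row_order=None, col_order=None
    ) -> "ContingencyTable":
        """Cross-tabulate two aligned categorical vectors."""
        ct = pd.crosstab(pd.Series(rows), pd.Series(cols))
        if row_order is not None:
            ct = ct.reindex(index=list(row_order), fill_value=0)
        if col_order is not None:
            ct = ct.reindex(columns=list(col_order), fill_value=0)
        return cls(
            ct.to_numpy(),
            tuple(str(i) for i in ct.index),
            tuple(str(c) for c in ct.columns),
        )


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    statistic_value: float
    p_value: float
    df: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.df is not None and self.df < 1:
            raise ValueError("df must be >= 1 where defined")

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "statistic_value": self.statistic_value,
            "p_value": self.p_value,
            "df": self.df,
            **{k: v for k, v in self.extra.items()},
        }


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


def chi_square(table: ContingencyTable) -> TestResult:
    """Pearson χ² of independence, no continuity correction.

    df = (r-1)(c-1); a ``low_expected`` flag marks tables with any expected
    count < 5, where Fisher's exact test is usually preferred.
    """
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal row/column")
    chi2, p, dof, expected = stats.chi2_contingency(counts, correction=False)
    return TestResult(
        statistic_name="chi2",
        statistic_value=float(chi2),
        p_value=float(p),
        df=int(dof),
        extra={"low_expected": bool(np.any(expected < 5))},
    )


def fisher_exact(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities of all tables (at fixed
    margins) no more probable than the observed one; the sample odds ratio
    is reported alongside.
    """
    counts = table.counts
    if counts.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    odds, p = stats.fisher_exact(counts, alternative="two-sided")
    return TestResult(
        statistic_name="fisher_odds",
        statistic_value=float(odds),
        p_value=float(p),
        df=None,
    )


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_threshold: int = EXACT_N_THRESHOLD
) -> TestResult:
    """Mann–Whitney U with midrank ties, U reported as min(U_x, U_y).

    The two-sided p-value uses exact enumeration for combined n up to
    ``exact_threshold`` with no ties, and the normal approximation with tie
    correction (no continuity correction) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r_x = ranks[: x.size].sum()
    u_x = r_x - x.size * (x.size + 1) / 2.0
    u_y = x.size * y.size - u_x
    u = min(u_x, u_y)

    has_ties = np.unique(pooled).size < pooled.size
    if (x.size + y.size) <= exact_threshold and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return TestResult(
        statistic_name="U",
        statistic_value=float(u),
        p_value=float(res.pvalue),
        df=None,
        extra={"u_x": float(u_x), "u_y": float(u_y), "method": method},
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H with tie correction, χ²_{k-1} approximation."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    if all(np.all(a == arrays[0][0]) for a in arrays):
        # identical constants: H = 0, p = 1 (scipy rejects the degenerate case)
        return TestResult("H", 0.0, 1.0, df=len(arrays) - 1)
    h, p = stats.kruskal(*arrays)
    return TestResult("H", float(h), float(p), df=len(arrays) - 1)


def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence) -> TestResult:
    """Cohen's κ = (p_o - p_e) / (1 - p_e) with marginal-product chance agreement.

    The p-value is the large-sample normal test of H0: κ = 0 using the
    standard-error formula under the null.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.size != b.size:
        raise ValueError("rating vectors must have equal length")
    if a.size == 0:
        raise ValueError("empty ratings")
    cats = np.unique(np.concatenate([a, b]))
    if cats.size < 2:
        raise ValueError("need at least two observed categories")
    n = a.size
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((cats.size, cats.size))
    for ai, bi in zip(a, b):
        table[idx[ai], idx[bi]] += 1
    table /= n
    p_o = float(np.trace(table))
    p_row = table.sum(axis=1)
    p_col = table.sum(axis=0)
    p_e = float(p_row @ p_col)
    if p_e >= 1.0 - 1e-12:
        raise ValueError("expected agreement is 1: kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)
    # SE of kappa under H0 (Fleiss/Cohen large-sample formula)
    se0_num = p_e + p_e**2 - float(np.sum(p_row * p_col * (p_row + p_col)))
    se0 = np.sqrt(max(se0_num, 0.0) / (n * (1.0 - p_e) ** 2))
    if se0 > 0:
        z = kappa / se0
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = 0.0 if kappa != 0 else 1.0
    return TestResult(
        "kappa", float(kappa), p, df=None, extra={"observed_agreement": p_o, "expected_agreement": p_e}
    )


# ---------------------------------------------------------------------------
# Summaries and record I/O
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = [
    "patient_id", "histology", "who_grade", "ce_present", "pet_positive",
    "tbr_max", "tbr_mean", "pet_volume_ml", "curve_class", "ttp_min",
    "dice_flair", "dice_ce",
]

_METRIC_FIELDS = ("tbr_max", "tbr_mean", "pet_volume_ml", "ttp_min", "dice_flair", "dice_ce")
_CATEGORICAL_FIELDS = ("ce_present", "pet_positive", "curve_class", "histology", "who_grade")


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(r, c) for c in _RECORD_COLUMNS} for r in records])


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    recs = []
    for _, row in df.iterrows():
        kwargs = {}
        for c in _RECORD_COLUMNS:
            v = row.get(c)
            if pd.isna(v):
                v = None
            kwargs[c] = v
        kwargs["who_grade"] = int(kwargs["who_grade"])
        kwargs["ce_present"] = bool(kwargs["ce_present"])
        kwargs["pet_positive"] = bool(kwargs["pet_positive"])
        kwargs["patient_id"] = str(kwargs["patient_id"])
        recs.append(PatientRecord(**kwargs))
    return recs


def read_records(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV (one row per patient, documented header)."""
    return frame_to_records(pd.read_csv(path))


def write_records(records: Sequence[PatientRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def _fmt_median_range(values: np.ndarray) -> str:
    med = np.median(values)
    return f"{med:.2f} ({values.min():.2f}–{values.max():.2f})"


def summarize(
    records: Sequence[PatientRecord],
    metric: str,
    strata: Sequence[str] = ("histology", "who_grade"),
) -> pd.DataFrame:
    """Per-stratum summary of one record field.

    Metric fields yield ``median (min–max)`` with n and the per-stratum
    missing count; categorical fields yield ``n (%)`` per level. Missing
    values are excluded per analysis and always counted.
    """
    if metric in _METRIC_FIELDS:
        kind = "metric"
    elif metric in _CATEGORICAL_FIELDS:
        kind = "categorical"
    else:
        raise ValueError(f"unknown metric {metric!r}")
    for s in strata:
        if s not in _RECORD_COLUMNS:
            raise ValueError(f"unknown stratum {s!r}")
    df = records_to_frame(records)
    if df.empty:
        raise ValueError("no records")

    rows = []
    for key, grp in df.groupby(list(strata), dropna=False, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        base = dict(zip(strata, key))
        vals = grp[metric]
        n_missing = int(vals.isna().sum())
        present = vals.dropna()
        row = {**base, "n": len(grp), "n_missing": n_missing}
        if kind == "metric":
            if len(present):
                arr = present.to_numpy(dtype=float)
                row["median"] = float(np.median(arr))
                row["min"] = float(arr.min())
                row["max"] = float(arr.max())
                row["summary"] = _fmt_median_range(arr)
            else:
                row["summary"] = "—"
        else:
            for level, count in present.value_counts().items():
                pct = 100.0 * count / len(present)
                row[f"{metric}={level}"] = f"{count} ({pct:.1f}%)"
        rows.append(row)
    return pd.DataFrame(rows)


def format_count_pct(count: int, total: int) -> str:
    """'62 (91.2%)'-style categorical formatting."""
    return f"{count} ({100.0 * count / total:.1f}%)"
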