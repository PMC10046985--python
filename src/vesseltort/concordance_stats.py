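"""Agreement and consistency statistics for paired tortuosity measurements.

Given per-vessel index values measured under both frame centers (M and
D), this module quantifies:

* agreement per index -- Bland-Altman bias, limits of agreement
  (bias +/- 1.96 sd of the paired differences) and the paired t-test of
  zero mean difference;
* heterogeneity across eyes -- a one-factor ANOVA of the differences
  grouped by eye;
* consistency among the eight indices -- pairwise Spearman rank and
  Pearson correlations, summarized by agglomerative clustering on the
  (1 - r) dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .curve_geometry import INDEX_NAMES
from .errors import (
    DegenerateTestError,
    ParameterError,
    UndefinedCorrelationError,
)

__all__ = [
    "PairedIndexTable",
    "AgreementSummary",
    "CorrelationTable",
    "IndexDendrogram",
    "bland_altman",
    "paired_t_test",
    "anova_across_eyes",
    "index_correlations",
    "cluster_indices",
    "TestResult",
]


class TestResult(NamedTuple):
    statistic: float
    p_value: float


@dataclass
class PairedIndexTable:
    """Per-vessel index values under both frame centers.

    Wraps a long-format DataFrame with columns ``vessel_id``, ``eye``,
    ``index``, ``value_M``, ``value_D`` -- one row per (vessel, index).
    """

    data: pd.DataFrame

    REQUIRED = ("vessel_id", "eye", "index", "value_M", "value_D")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ParameterError(f"paired table missing columns: {missing}")
        if self.data[["value_M", "value_D"]].isna().any().any():
            raise ParameterError("paired table contains missing cells")

    @property
    def index_names(self) -> list[str]:
        present = list(pd.unique(self.data["index"]))
        ordered = [n for n in INDEX_NAMES if n in present]
        return ordered + [n for n in present if n not in ordered]

    def values(self, index: str, frame: Literal["M", "D"]) -> np.ndarray:
        sub = self.data[self.data["index"] == index]
        return sub[f"value_{frame}"].to_numpy(dtype=float)

    def differences(self, index: str) -> np.ndarray:
        """Per-vessel D - M differences for one index."""
        sub = self.data[self.data["index"] == index]
        return (sub["value_D"] - sub["value_M"]).to_numpy(dtype=float)

    def means(self, index: str) -> np.ndarray:
        sub = self.data[self.data["index"] == index]
        return (
            (sub["value_D"] + sub["value_M"]).to_numpy(dtype=float) / 2.0
        )

    def eyes(self, index: str) -> np.ndarray:
        return self.data.loc[self.data["index"] == index, "eye"].to_numpy()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PairedIndexTable":
        return cls(pd.read_csv(path))

    @classmethod
    def from_profiles(
        cls,
        profiles_m: dict,
        profiles_d: dict,
        eyes: dict | None = None,
    ) -> "PairedIndexTable":
        """Build from ``{vessel_id: TortuosityProfile}`` maps for each frame."""
        rows = []
        for vid in profiles_m:
            if vid not in profiles_d:
                raise ParameterError(f"vessel {vid!r} missing under the D frame")
            pm, pdd = profiles_m[vid].as_dict(), profiles_d[vid].as_dict()
            eye = (eyes or {}).get(vid, "?")
            for name in INDEX_NAMES:
                rows.append(
                    {
                        "vessel_id": vid,
                        "eye": eye,
                        "index": name,
                        "value_M": pm[name],
                        "value_D": pdd[name],
                    }
                )
        return cls(pd.DataFrame(rows))


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman agreement of one index across the frame-center change."""

    bias: float  # mean of D - M differences
    sd: float  # sample sd (n - 1) of the differences
    lower: float  # bias - multiplier * sd
    upper: float  # bias + multiplier * sd
    p_value: float  # paired t-test of zero mean difference (nan if sd == 0)
    n_outside: int  # points beyond the limits of agreement
    n: int
    multiplier: float = 1.96

    def as_dict(self) -> dict[str, float]:
        return {
            "bias": self.bias,
            "sd": self.sd,
            "lower": self.lower,
            "upper": self.upper,
            "p_value": self.p_value,
            "n_outside": self.n_outside,
            "n": self.n,
        }


def bland_altman(
    diffs: Sequence[float],
    means: Sequence[float] | None = None,
    multiplier: float = 1.96,
) -> tuple[AgreementSummary, pd.DataFrame]:
    """Bland-Altman agreement summary plus the (mean, difference) plot data.

    bias = mean(D - M); limits of agreement = bias +/- ``multiplier`` *
    sample sd (n - 1).  Under normality about 5% of differences fall
    outside the limits.  ``means`` defaults to NaN plot abscissae when
    not supplied.
    """
    d = np.asarray(diffs, dtype=float)
    if len(d) < 2:
        raise ParameterError("need at least 2 paired differences")
    m = (
        np.full(len(d), np.nan)
        if means is None
        else np.asarray(means, dtype=float)
    )
    if len(m) != len(d):
        raise ParameterError("diffs and means must have equal length")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lower, upper = bias - multiplier * sd, bias + multiplier * sd
    outside = int(np.sum((d < lower) | (d > upper)))
    if sd > 0:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    else:
        p = float("nan")
    summary = AgreementSummary(
        bias=bias,
        sd=sd,
        lower=lower,
        upper=upper,
        p_value=p,
        n_outside=outside,
        n=len(d),
        multiplier=multiplier,
    )
    plot_data = pd.DataFrame({"mean": m, "difference": d})
    return summary, plot_data


def paired_t_test(diffs: Sequence[float]) -> TestResult:
    """Two-sided one-sample t-test of zero mean paired difference."""
    d = np.asarray(diffs, dtype=float)
    if len(d) < 2:
        raise ParameterError("need at least 2 paired differences")
    if d.std(ddof=1) == 0:
        raise DegenerateTestError("paired t-test undefined for constant differences")
    res = stats.ttest_1samp(d, 0.0)
    return TestResult(float(res.statistic), float(res.pvalue))


def anova_across_eyes(
    diffs: Sequence[float], eye_labels: Sequence
) -> TestResult:
    """One-way fixed-effect ANOVA of the differences grouped by eye."""
    d = np.asarray(diffs, dtype=float)
    labels = np.asarray(eye_labels)
    if len(d) != len(labels):
        raise ParameterError("diffs and eye labels must have equal length")
    groups = [d[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ParameterError("need at least 2 eye groups")
    if any(len(g) < 2 for g in groups):
        raise ParameterError("every eye group needs at least 2 observations")
    res = stats.f_oneway(*groups)
    return TestResult(float(res.statistic), float(res.pvalue))


@dataclass
class CorrelationTable:
    """Pairwise Spearman (rho) and Pearson (r) correlations among indices."""

    spearman: pd.DataFrame
    pearson: pd.DataFrame

    @property
    def index_names(self) -> list[str]:
        return list(self.spearman.columns)


def _corr_matrices(values: dict[str, np.ndarray]) -> CorrelationTable:
    names = list(values)
    for name, v in values.items():
        if np.all(v == v[0]):
            raise UndefinedCorrelationError(
                f"index {name!r} is constant: correlation undefined"
            )
    k = len(names)
    rho = np.eye(k)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            rho[i, j] = rho[j, i] = stats.spearmanr(values[names[i]], values[names[j]]).statistic
            r[i, j] = r[j, i] = stats.pearsonr(values[names[i]], values[names[j]]).statistic
    return CorrelationTable(
        spearman=pd.DataFrame(rho, index=names, columns=names),
        pearson=pd.DataFrame(r, index=names, columns=names),
    )


def index_correlations(
    table: PairedIndexTable, frame: Literal["M", "D", "pooled"] = "pooled"
) -> CorrelationTable:
    """Correlate every pair of indices across vessels.

    ``frame`` selects which measurements enter: the M values, the D
    values, or both pooled (default).  Spearman uses average ranks for
    ties.
    """
    if frame not in ("M", "D", "pooled"):
        raise ParameterError("frame must be 'M', 'D' or 'pooled'")
    names = table.index_names
    n_vessels = len(table.data[table.data["index"] == names[0]])
    if n_vessels < 3:
        raise ParameterError("need at least 3 vessels for correlations")
    values = {}
    for name in names:
        if frame == "pooled":
            values[name] = np.concatenate(
                [table.values(name, "M"), table.values(name, "D")]
            )
        else:
            values[name] = table.values(name, frame)
    return _corr_matrices(values)


@dataclass
class IndexDendrogram:
    """Agglomerative merge tree over indices on the (1 - r) dissimilarity scale."""

    linkage_matrix: np.ndarray  # scipy hierarchy linkage format
    labels: list[str]
    method: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage_matrix)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.linkage_matrix, columns=["left", "right", "height", "size"]
        )
        df["method"] = self.method
        return df


def cluster_indices(
    corr: CorrelationTable,
    linkage: Literal["single", "complete", "average"] = "complete",
    which: Literal["pearson", "spearman"] = "pearson",
) -> IndexDendrogram:
    """Hierarchical clustering of the indices at dissimilarity 1 - r.

    The linkage method is configurable (complete by default); indices
    that correlate perfectly (e.g. DF and T1) merge at height 0.
    """
    if linkage not in ("single", "complete", "average"):
        raise ParameterError("linkage must be single, complete or average")
    mat = getattr(corr, which)
    dist = 1.0 - mat.to_numpy()
    dist = np.clip(dist, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return IndexDendrogram(
        linkage_matrix=Z, labels=list(mat.columns), method=linkage
    )
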