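"""Comparative statistics for compound sets.

Summary tables (median, mean, SEM, 95th percentile), Welch confidence
intervals for mean differences between datasets, Gaussian kernel density
curves, threshold categorization, and the trivariate coordinates
(logP, logS, shape index) used for biopharmaceutics-class (BDDCS-style)
mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .descriptors import DescriptorVector

__all__ = [
    "DatasetSummary",
    "ComparisonResult",
    "summarize",
    "compare_means",
    "pairwise_comparisons",
    "kde",
    "categorize",
    "bddcs_coordinates",
    "summary_table",
]


@dataclass
class DatasetSummary:
    dataset: str
    descriptor: str
    mdn: float    # sample median
    m: float      # arithmetic mean
    sem: float    # sd (n-1 denominator) / sqrt(n)
    p95: float    # 95th percentile, linear interpolation
    n: int


@dataclass
class ComparisonResult:
    dataset_a: str
    dataset_b: str
    descriptor: str
    diff_means: float
    ci_low: float
    ci_high: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def summarize(
    values: Sequence[float], dataset: str = "", descriptor: str = ""
) -> DatasetSummary:
    """Median, mean, SEM and 95th percentile of one descriptor column."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("summarize requires at least one value")
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return DatasetSummary(
        dataset=dataset,
        descriptor=descriptor,
        mdn=float(np.median(x)),
        m=float(np.mean(x)),
        sem=sem,
        p95=float(np.percentile(x, 95)),  # linear interpolation between order stats
        n=int(x.size),
    )


def compare_means(
    a: Sequence[float],
    b: Sequence[float],
    dataset_a: str = "a",
    dataset_b: str = "b",
    descriptor: str = "",
    confidence: float = 0.95,
    equal_var: bool = False,
) -> ComparisonResult:
    """Two-sample t comparison of means (Welch by default).

    CI = (m_a - m_b) +/- t_{1-alpha/2, nu} * sqrt(s_a^2/n_a + s_b^2/n_b)
    with the Welch-Satterthwaite degrees of freedom; two-sided p-value.
    With ``equal_var=True`` the pooled-variance construction is used instead.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("compare_means requires n >= 2 in each group")
    va, vb = np.var(xa, ddof=1), np.var(xb, ddof=1)
    if va == 0.0 or vb == 0.0:
        raise ValueError(
            "degenerate (zero-variance) sample; use an exact or permutation test"
        )
    na, nb = xa.size, xb.size
    diff = float(np.mean(xa) - np.mean(xb))
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    tcrit = sps.t.ppf(0.5 + confidence / 2.0, df)
    tstat = diff / se
    p = float(2.0 * sps.t.sf(abs(tstat), df))
    return ComparisonResult(
        dataset_a=dataset_a,
        dataset_b=dataset_b,
        descriptor=descriptor,
        diff_means=diff,
        ci_low=float(diff - tcrit * se),
        ci_high=float(diff + tcrit * se),
        p_value=p,
    )


def pairwise_comparisons(
    groups: dict[str, Sequence[float]],
    descriptor: str = "",
    adjust: str = "none",
    equal_var: bool = False,
) -> list[ComparisonResult]:
    """All pairwise mean comparisons between labelled groups.

    ``adjust='holm'`` applies a Holm step-down correction to the p-values
    (off by default; pairwise p-values are reported directly otherwise).
    """
    labels = list(groups)
    results = [
        compare_means(groups[a], groups[b], a, b, descriptor, equal_var=equal_var)
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    ]
    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests([r.p_value for r in results], method="holm")
        for r, p in zip(results, p_adj):
            r.p_value = float(p)
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}; use 'none' or 'holm'")
    return results


def kde(values: Sequence[float], grid: Sequence[float]) -> np.ndarray:
    """Gaussian kernel density estimate with Silverman bandwidth, evaluated
    on ``grid``. Requires n >= 2 and nonzero spread."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("kde requires at least two values")
    if np.std(x) == 0.0:
        raise ValueError("kde requires nonzero spread")
    density = sps.gaussian_kde(x, bw_method="silverman")
    return density(np.asarray(grid, dtype=float))


def categorize(
    values: Sequence[float], cutpoints: Sequence[float], labels: Sequence[str]
) -> dict[str, int]:
    """Half-open binning [c_i, c_{i+1}): a value exactly at a cutpoint goes to
    the upper bin. Counts sum to len(values)."""
    cuts = np.asarray(cutpoints, dtype=float)
    if cuts.size and np.any(np.diff(cuts) <= 0):
        raise ValueError("cutpoints must be strictly increasing")
    if len(labels) != cuts.size + 1:
        raise ValueError("need len(labels) == len(cutpoints) + 1")
    x = np.asarray(values, dtype=float)
    idx = np.searchsorted(cuts, x, side="right")
    counts = np.bincount(idx, minlength=len(labels))
    return {label: int(c) for label, c in zip(labels, counts)}


def bddcs_coordinates(dv: DescriptorVector) -> tuple[float, float, float]:
    """(logP, logS, shape index) projection used for the biopharmaceutics
    classification scatter map. Pure passthrough; no class is asserted."""
    return (dv.logp, dv.logs, dv.shape_index)


def summary_table(
    df: pd.DataFrame, groupby: str = "dataset", descriptors: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-dataset summary matrix: rows = descriptors, columns = dataset x
    {Mdn, M, SEM, P95}, from a long per-compound descriptor table."""
    if descriptors is None:
        descriptors = [
            c for c in df.columns if c != groupby and np.issubdtype(df[c].dtype, np.number)
        ]
    rows = {}
    for desc in descriptors:
        row = {}
        for label, sub in df.groupby(groupby, sort=True):
            s = summarize(sub[desc].to_numpy(), dataset=str(label), descriptor=desc)
            row[(label, "Mdn")] = s.mdn
            row[(label, "M")] = s.m
            row[(label, "SEM")] = s.sem
            row[(label, "P95")] = s.p95
        rows[desc] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.columns = pd.MultiIndex.from_tuples(out.columns)
    return out
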