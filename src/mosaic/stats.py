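"""Statistical battery over per-factor class-proportion tables.

One-sided one-sample and paired t-tests with 95% lower confidence limits,
Shapiro-Wilk normality checks, rank correlation, and aggregate rows for the
packaged per-factor fixture tables (binding-site, motif-occurrence, TSS-split,
low-tag and cell-line comparisons).
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

#: genome share of the preferred class pairs (the null value the site and
#: motif proportions are tested against)
GENOME_PREFERRED = 0.256


@dataclass
class TestResult:
    n: int
    df: int
    t: float
    p: float                  # one-sided (upper tail)
    lower_cl: float           # 95% lower confidence limit of the mean
    mean: float


def one_sided_t(sample, mu0: float) -> TestResult:
    """Upper-tail one-sample t-test of mean > mu0, with the one-sided 95%
    lower confidence limit of the mean."""
    x = np.asarray(sample, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance sample")
    se = sd / np.sqrt(n)
    t = float((x.mean() - mu0) / se)
    p = float(sps.t.sf(t, n - 1))
    cl = float(x.mean() - sps.t.ppf(0.95, n - 1) * se)
    return TestResult(n, n - 1, t, p, cl, float(x.mean()))


def paired_difference_t(sample_a, sample_b, labels_a=None,
                        labels_b=None) -> TestResult:
    """One-sided t-test that mean(a - b) > 0, pairing by position (or by the
    given labels, which must match elementwise)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("samples must have equal length")
    if labels_a is not None or labels_b is not None:
        if list(labels_a) != list(labels_b):
            raise ValueError("sample labels do not match")
    return one_sided_t(a - b, 0.0)


def shapiro_wilk(sample):
    """Shapiro-Wilk W and p (scipy's polynomial approximation; p-values are
    approximation-dependent at the second decimal)."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk needs 3 to 5000 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.ptp(sps.rankdata(x)) == 0 or np.ptp(sps.rankdata(y)) == 0:
        raise ValueError("zero rank variance")
    return float(sps.spearmanr(x, y).statistic)


def pearson(x, y) -> float:
    return float(sps.pearsonr(np.asarray(x, float),
                              np.asarray(y, float)).statistic)


# ---------------------------------------------------------------------------
# fixture tables

_TABLES = {
    "table2": "table2.tsv",
    "table4": "table4.tsv",
    "table5": "table5.tsv",
    "table6": "table6.tsv",
    "table7": "table7.tsv",
    "table8": "table8.tsv",
    "class_proportions": "class_proportions.tsv",
}

PAIR_COLUMNS = ["pair2", "pair7", "pair9", "pair14", "total"]


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged per-factor fixture table as a DataFrame."""
    try:
        fname = _TABLES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; have {sorted(_TABLES)}")
    ref = resources.files("mosaic").joinpath("data", fname)
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t")


def table_aggregates(name: str) -> pd.Series | pd.DataFrame:
    """The 'Average of above' row of a fixture table.

    For the cell-line comparison (table5) returns a per-group frame with
    count, mean and the one-sided 95% lower confidence limit of each group
    mean; for the low-tag table (table4) the means of the ratio and the two
    proportion columns; otherwise the column means over the factors.
    """
    df = load_fixture(name)
    if name == "table5":
        rows = {}
        for group, sub in df.groupby("cell_group"):
            v = sub["value"].to_numpy()
            res = one_sided_t(v, 0.0)
            rows[group] = {"count": len(v), "mean": v.mean(),
                           "lower_cl": res.lower_cl}
        return pd.DataFrame(rows).T.loc[["GM128", "K562", "Other"]]
    if name == "table4":
        return df[["ratio", "prop_all", "prop_lowtag"]].mean()
    return df[PAIR_COLUMNS].mean()


def round_half_up(x: float, decimals: int = 3) -> float:
    """Decimal rounding as printed tables round (0.5 away from zero)."""
    factor = 10 ** decimals
    return np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)
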