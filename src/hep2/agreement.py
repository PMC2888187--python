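"""Inter-rater agreement statistics for categorical ANA calls.

Automated and visual interpretation of the same sera are cross-tabulated
into r×c contingency tables (rows = automated reading, columns = visual
reading).  This module provides the statistics customarily reported for
such comparisons: Pearson chi-square and the contingency coefficient
C = sqrt(chi2/(chi2+n)), Cohen's kappa with a large-sample (Fleiss)
confidence interval, overall percent agreement, and the McNemar test on
the discordant cells of a collapsed 2x2 table with a Newcombe score
interval for the paired-proportion difference.

Two published three-class comparison tables (university routine
laboratory, n=924, and private referral laboratory, n=298) ship as CSV
fixtures and are loadable via :func:`load_table1` / :func:`load_table2`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "AgreementResult",
    "McNemarResult",
    "load_table1",
    "load_table2",
    "collapse",
    "pool",
    "chi_square_test",
    "contingency_coefficient",
    "cohen_kappa",
    "mcnemar",
    "percent_agreement",
    "analyze",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ContingencyTable:
    """r×c cross-tabulation of automated (rows) vs visual (columns) calls."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("table must contain at least one observation")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match table shape")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def is_square(self) -> bool:
        return self.counts.shape[0] == self.counts.shape[1]

    @classmethod
    def from_csv(cls, path) -> "ContingencyTable":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), tuple(df.index.astype(str)), tuple(df.columns.astype(str)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels), columns=list(self.col_labels))


def _load_fixture(name: str) -> ContingencyTable:
    with resources.as_file(resources.files("hep2.data").joinpath(name)) as p:
        return ContingencyTable.from_csv(p)


def load_table1() -> ContingencyTable:
    """University routine laboratory comparison (n=924), as printed."""
    return _load_fixture("table1.csv")


def load_table2() -> ContingencyTable:
    """Private referral laboratory comparison (n=298), as printed."""
    return _load_fixture("table2.csv")


def collapse(table: ContingencyTable, merge_map: Mapping[str, str]) -> ContingencyTable:
    """Merge categories on both axes according to ``merge_map``.

    Every row and column label must be covered; counts are summed per
    group and the total n is preserved.  Group order follows first
    appearance in the original labels.
    """
    for lab in (*table.row_labels, *table.col_labels):
        if lab not in merge_map:
            raise KeyError(f"category {lab!r} not covered by merge_map")

    def groups(labels: Sequence[str]) -> list[str]:
        seen: list[str] = []
        for lab in labels:
            g = merge_map[lab]
            if g not in seen:
                seen.append(g)
        return seen

    rg, cg = groups(table.row_labels), groups(table.col_labels)
    out = np.zeros((len(rg), len(cg)), dtype=np.int64)
    for i, rlab in enumerate(table.row_labels):
        for j, clab in enumerate(table.col_labels):
            out[rg.index(merge_map[rlab]), cg.index(merge_map[clab])] += table.counts[i, j]
    return ContingencyTable(out, tuple(rg), tuple(cg))


def pool(tables: Sequence[ContingencyTable]) -> ContingencyTable:
    """Element-wise sum of identically shaped and labelled tables."""
    if not tables:
        raise ValueError("nothing to pool")
    first = tables[0]
    total = np.zeros_like(first.counts)
    for t in tables:
        if t.counts.shape != first.counts.shape:
            raise ValueError("tables must share shape")
        if t.row_labels != first.row_labels or t.col_labels != first.col_labels:
            raise ValueError("tables must share labels")
        total = total + t.counts
    return ContingencyTable(total, first.row_labels, first.col_labels)


def chi_square_test(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square of independence: (chi2, df, p)."""
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("table has an all-zero row or column")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)


def contingency_coefficient(table: ContingencyTable) -> float:
    """Pearson's C = sqrt(chi2 / (chi2 + n)); in [0, sqrt((k-1)/k))."""
    chi2, _, _ = chi_square_test(table)
    return float(np.sqrt(chi2 / (chi2 + table.n)))


def cohen_kappa(table: ContingencyTable) -> tuple[float, tuple[float, float]]:
    """Chance-corrected agreement for a square table.

    Returns (kappa, 95% CI).  The CI uses the Fleiss/Cohen/Everitt
    large-sample standard error of kappa-hat, kappa ± 1.96·SE.
    """
    if not table.is_square:
        raise ValueError("kappa requires a square table")
    p = table.counts / table.n
    pi, pj = p.sum(axis=1), p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(pi @ pj)
    if pe >= 1.0:
        raise ValueError("degenerate marginals: pe = 1")
    kappa = (po - pe) / (1.0 - pe)
    k = len(pi)
    a = sum(p[i, i] * (1 - (pi[i] + pj[i]) * (1 - kappa)) ** 2 for i in range(k))
    b = (1 - kappa) ** 2 * sum(
        p[i, j] * (pj[i] + pi[j]) ** 2 for i in range(k) for j in range(k) if i != j
    )
    c = (kappa - pe * (1 - kappa)) ** 2
    se = float(np.sqrt((a + b - c) / table.n) / (1 - pe))
    return float(kappa), (float(kappa - _Z95 * se), float(kappa + _Z95 * se))


def percent_agreement(table: ContingencyTable) -> float:
    """100 × trace / n for a square table."""
    if not table.is_square:
        raise ValueError("percent agreement requires a square table")
    return float(100.0 * np.trace(table.counts) / table.n)


@dataclass(frozen=True)
class McNemarResult:
    """Paired-proportion comparison on a 2x2 table.

    ``b`` and ``c`` are the discordant cells (row-positive/col-negative
    and row-negative/col-positive).  ``diff_percent`` is the column
    (visual) positive excess, (c−b)/n × 100.  Both the exact binomial and
    the continuity-corrected chi-square p are computed; ``p`` selects the
    exact one when b+c < 25, else the corrected one.
    """

    b: int
    c: int
    n: int
    diff_percent: float
    diff_ci95: tuple[float, float]
    chi_square_cc: float
    p_exact: float
    p_cc: float

    @property
    def p(self) -> float:
        return self.p_exact if (self.b + self.c) < 25 else self.p_cc


def _wilson(x: int, n: int) -> tuple[float, float]:
    z = _Z95
    ph = x / n
    mid = 2 * n * ph + z * z
    adj = z * np.sqrt(z * z + 4 * n * ph * (1 - ph))
    return (mid - adj) / (2 * (n + z * z)), (mid + adj) / (2 * (n + z * z))


def mcnemar(table: ContingencyTable) -> McNemarResult:
    """McNemar test plus Newcombe score CI for the paired difference."""
    if table.counts.shape != (2, 2):
        raise ValueError("McNemar requires a 2x2 table")
    a, b = (int(v) for v in table.counts[0])
    c, d = (int(v) for v in table.counts[1])
    n = a + b + c + d
    diff = (c - b) / n * 100.0

    if b + c == 0:
        return McNemarResult(b, c, n, 0.0, (0.0, 0.0), 0.0, 1.0, 1.0)

    chi2cc = (abs(b - c) - 1) ** 2 / (b + c)
    p_cc = float(stats.chi2.sf(chi2cc, 1))
    p_exact = float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), b + c, 0.5)))

    # Newcombe (1998) method 10: square-and-add Wilson limits with a
    # phi correction for the pairing.
    p1, p2 = (a + b) / n, (a + c) / n
    l1, u1 = _wilson(a + b, n)
    l2, u2 = _wilson(a + c, n)
    marg = (a + b) * (c + d) * (a + c) * (b + d)
    phi = 0.0 if marg == 0 else (a * d - b * c) / np.sqrt(marg)
    lo = (p2 - p1) - np.sqrt((p2 - l2) ** 2 + (u1 - p1) ** 2 - 2 * phi * (p2 - l2) * (u1 - p1))
    hi = (p2 - p1) + np.sqrt((u2 - p2) ** 2 + (p1 - l1) ** 2 - 2 * phi * (u2 - p2) * (p1 - l1))
    return McNemarResult(b, c, n, float(diff), (float(lo * 100), float(hi * 100)),
                         float(chi2cc), p_exact, p_cc)


@dataclass(frozen=True)
class AgreementResult:
    """Bundle of agreement statistics for one comparison table."""

    n: int
    chi_square: float
    df: int
    p_value: float
    contingency_coefficient: float
    kappa: float | None = None
    kappa_ci95: tuple[float, float] | None = None
    percent_agreement: float | None = None
    mcnemar: McNemarResult | None = None
    notes: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        out = {
            "n": self.n,
            "chi_square": self.chi_square,
            "df": self.df,
            "p_value": self.p_value,
            "contingency_coefficient": self.contingency_coefficient,
        }
        if self.kappa is not None:
            out["kappa"] = self.kappa
            out["kappa_ci95"] = list(self.kappa_ci95)
        if self.percent_agreement is not None:
            out["percent_agreement"] = self.percent_agreement
        if self.mcnemar is not None:
            m = self.mcnemar
            out["mcnemar"] = {
                "b": m.b, "c": m.c, "diff_percent": m.diff_percent,
                "diff_ci95": list(m.diff_ci95), "chi_square_cc": m.chi_square_cc,
                "p_exact": m.p_exact, "p_cc": m.p_cc, "p": m.p,
            }
        if self.notes:
            out["notes"] = list(self.notes)
        return out


def analyze(table: ContingencyTable) -> AgreementResult:
    """Compute every applicable statistic for one table."""
    chi2, df, p = chi_square_test(table)
    kappa = ci = pa = mc = None
    if table.is_square:
        kappa, ci = cohen_kappa(table)
        pa = percent_agreement(table)
        if table.counts.shape == (2, 2):
            mc = mcnemar(table)
    return AgreementResult(
        n=table.n, chi_square=chi2, df=df, p_value=p,
        contingency_coefficient=contingency_coefficient(table),
        kappa=kappa, kappa_ci95=ci, percent_agreement=pa, mcnemar=mc,
    )
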