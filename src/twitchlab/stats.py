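"""Group-level inference and robust outlier flagging.

Thin, explicit wrappers over scipy's classical tests (one-way ANOVA,
two-sample/paired t, chi-square without continuity correction) plus the
Bonferroni correction and the scaled-MAD outlier rule (flag points more
than 3 scaled median-absolute-deviations from the median; the scaling
constant 1.4826 makes the MAD a consistent SD estimate under normality).
Outlier exclusion is intended for summary displays only — tests run on
full data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidParameterError

MAD_SCALE = 1.4826


def mad_outlier_mask(values, factor: float = 3.0) -> np.ndarray:
    """True where |x - median| > factor x scaled MAD.

    All-equal input (scaled MAD 0) flags nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InvalidParameterError("mad_outlier_mask needs at least one value")
    med = np.median(x)
    smad = MAD_SCALE * np.median(np.abs(x - med))
    if smad == 0:
        return np.zeros(x.size, dtype=bool)
    return np.abs(x - med) > factor * smad


@dataclass
class TestResult:
    """One line of a statistics report."""

    contrast: str
    statistic_name: str
    statistic: float
    df: tuple
    p_raw: float
    p_adjusted: float
    n_per_group: tuple


@dataclass
class StatsReport:
    results: list[TestResult] = field(default_factory=list)
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "contrast": r.contrast, "statistic_name": r.statistic_name,
                "statistic": r.statistic, "df": "/".join(str(d) for d in r.df),
                "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
                "n_per_group": "/".join(str(n) for n in r.n_per_group),
            }
            for r in self.results
        ])


def bonferroni(p_values) -> np.ndarray:
    """Multiply by the number of comparisons in the family; cap at 1."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * p.size, 1.0)


def one_way_anova(groups: dict[str, np.ndarray]) -> TestResult:
    """One-way ANOVA across >= 2 groups."""
    labels = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in labels]
    _validate_groups(labels, data)
    f, p = sps.f_oneway(*data)
    k = len(data)
    n = sum(d.size for d in data)
    return TestResult(
        contrast="|".join(labels), statistic_name="F", statistic=float(f),
        df=(k - 1, n - k), p_raw=float(p), p_adjusted=float(p),
        n_per_group=tuple(d.size for d in data),
    )


def t_test(a, b, contrast: str = "a_vs_b", paired: bool = False) -> TestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _validate_groups([contrast, contrast], [a, b])
    if paired:
        t, p = sps.ttest_rel(a, b)
        df = (a.size - 1,)
    else:
        t, p = sps.ttest_ind(a, b)
        df = (a.size + b.size - 2,)
    if np.isnan(p):  # identical zero-variance groups
        t, p = 0.0, 1.0
    return TestResult(
        contrast=contrast, statistic_name="t_paired" if paired else "t",
        statistic=float(t), df=df, p_raw=float(p), p_adjusted=float(p),
        n_per_group=(a.size, b.size),
    )


def chi_square(table, contrast: str = "categorical") -> TestResult:
    """Chi-square test of independence, no continuity (Yates) correction."""
    table = np.asarray(table, dtype=float)
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(
        contrast=contrast, statistic_name="chi2", statistic=float(chi2),
        df=(int(dof),), p_raw=float(p), p_adjusted=float(p),
        n_per_group=tuple(int(n) for n in table.sum(axis=1)),
    )


def _validate_groups(labels, data) -> None:
    for label, d in zip(labels, data):
        if d.size == 0:
            raise InvalidParameterError(f"empty group {label!r} in design")
        if np.any(np.isnan(d)):
            raise InvalidParameterError(f"NaN values in group {label!r}")


def omnibus_and_posthoc(
    table: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    design: str = "one_way",
    alpha: float = 0.05,
) -> StatsReport:
    """Omnibus test plus Bonferroni-corrected pairwise post-hocs.

    ``design='one_way'`` runs a one-way ANOVA over the group levels and,
    when significant structure is plausible (>= 3 levels), all pairwise
    two-sample t tests corrected within the post-hoc family.
    ``design='two_sample'`` and ``design='paired'`` run a single t test.
    """
    report = StatsReport(alpha=alpha)
    groups = {
        str(g): sub[value].to_numpy(float) for g, sub in table.groupby(group, sort=True)
    }
    if design == "one_way":
        if len(groups) < 2:
            raise InvalidParameterError("one-way design needs >= 2 groups")
        report.results.append(one_way_anova(groups))
        labels = list(groups)
        if len(labels) >= 3:
            pairs = [
                (labels[i], labels[j])
                for i in range(len(labels)) for j in range(i + 1, len(labels))
            ]
            posthoc = [
                t_test(groups[a], groups[b], contrast=f"{a}_vs_{b}") for a, b in pairs
            ]
            adj = bonferroni([r.p_raw for r in posthoc])
            for r, p_adj in zip(posthoc, adj):
                r.p_adjusted = float(p_adj)
            report.results.extend(posthoc)
    elif design in ("two_sample", "paired"):
        if len(groups) != 2:
            raise InvalidParameterError(f"{design} design needs exactly 2 groups")
        (la, a), (lb, b) = groups.items()
        report.results.append(
            t_test(a, b, contrast=f"{la}_vs_{lb}", paired=(design == "paired"))
        )
    else:
        raise InvalidParameterError(f"unknown design {design!r}")
    return report
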