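"""Statistical comparisons and summary tables.

Three families of tests mirror the analyses of the pipeline: paired t-tests
between sub-movement-role ERD values, a variance-homogeneity check followed
by a two-independent-sample t-test for the initial vs non-initial PLV
contrast, and a two-sample t-test comparing decoding accuracies between the
two pacing conditions.  All tests are two-sided; no multiplicity correction
is applied by default (a Holm option exists behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .paradigm import RoleLabel

__all__ = [
    "TestResult",
    "paired_ttest",
    "independent_ttest_with_variance_check",
    "ERD_CONTRASTS",
    "erd_contrast_table",
    "plv_contrast_table",
    "accuracy_comparison",
    "report_tables",
]


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float
    pvalue: float
    note: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.pvalue <= 1:
            raise ValueError("p-value outside [0, 1]")

    @property
    def stars(self) -> str:
        return _stars(self.pvalue)


def paired_ttest(a, b, name: str = "paired t-test") -> TestResult:
    """Two-sided paired t-test of equal means.

    Rejects degenerate input (zero variance of the pairwise differences)
    rather than returning an undefined statistic.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors with >= 2 pairs")
    if np.any(np.isnan(a)) or np.any(np.isnan(b)):
        raise ValueError("missing values are not supported")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0):
        raise ValueError(
            "zero variance of the paired differences: t statistic undefined"
        )
    t, p = sps.ttest_rel(a, b)
    return TestResult(name, float(t), float(len(a) - 1), float(p))


def independent_ttest_with_variance_check(
    g1, g2, alpha_var: float = 0.05, name: str = "two-sample t-test"
) -> TestResult:
    """Variance-homogeneity check, then pooled or Welch two-sample t-test.

    A median-centered Levene test decides the branch: pooled-variance t when
    homogeneity is not rejected at ``alpha_var``, Welch's unequal-variance t
    otherwise.  The chosen branch is recorded in ``note``.
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs >= 2 values")
    if np.isclose(g1.std(ddof=1), 0) or np.isclose(g2.std(ddof=1), 0):
        equal_var = False
        note = "welch (zero-variance group forced)"
    else:
        with np.errstate(invalid="ignore"):
            _, p_var = sps.levene(g1, g2, center="median")
        if np.isnan(p_var):  # degenerate spread (e.g. mirrored samples)
            equal_var, note = True, "pooled (degenerate spread test)"
        else:
            equal_var = p_var >= alpha_var
            note = "pooled" if equal_var else "welch"
    t, p = sps.ttest_ind(g1, g2, equal_var=equal_var)
    if equal_var:
        df = len(g1) + len(g2) - 2.0
    else:
        v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
        n1, n2 = len(g1), len(g2)
        num = (v1 / n1 + v2 / n2) ** 2
        den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        df = num / den if den > 0 else float(n1 + n2 - 2)
    return TestResult(name, float(t), float(df), float(p), note)


#: Planned prior-limb contrasts: each hand role with a prior hand against the
#: same hand's prior-foot role.
ERD_CONTRASTS: tuple[tuple[RoleLabel, RoleLabel], ...] = (
    (RoleLabel.RH_PH_I, RoleLabel.RH_PF_I),
    (RoleLabel.RH_PH_II, RoleLabel.RH_PF_I),
    (RoleLabel.RH_PH_III, RoleLabel.RH_PF_I),
    (RoleLabel.LH_PH_I, RoleLabel.LH_PF_I),
    (RoleLabel.LH_PH_II, RoleLabel.LH_PF_I),
)


def erd_contrast_table(
    erd_values: pd.DataFrame, holm: bool = False
) -> pd.DataFrame:
    """Paired t-tests of the planned prior-hand vs prior-foot ERD contrasts.

    ``erd_values`` must be long-form with columns ``role``, ``value_db`` and a
    replicate identifier ``dataset`` (one row per role per subject-equivalent
    dataset).
    """
    if erd_values.empty:
        raise ValueError("empty ERD table")
    wide = erd_values.pivot(index="dataset", columns="role", values="value_db")
    rows = []
    for role_a, role_b in ERD_CONTRASTS:
        res = paired_ttest(
            wide[role_a.value], wide[role_b.value],
            name=f"{role_a.value} vs {role_b.value}",
        )
        rows.append(
            {
                "contrast": res.name,
                "mean_a": wide[role_a.value].mean(),
                "mean_b": wide[role_b.value].mean(),
                "t": res.statistic,
                "df": res.df,
                "p": res.pvalue,
                "sig": res.stars,
            }
        )
    table = pd.DataFrame(rows)
    if holm:
        table["p_holm"] = _holm(table["p"].to_numpy())
        table["sig"] = [_stars(p) for p in table["p_holm"]]
    return table


def plv_contrast_table(plv_groups, holm: bool = False) -> pd.DataFrame:
    """Initial vs non-initial PLV contrast per limb.

    ``plv_groups`` maps each :class:`~sclmi.paradigm.Limb` to its
    ``(initial, noninitial)`` :class:`~sclmi.plv.PLVResult` pair.
    """
    if not plv_groups:
        raise ValueError("empty PLV groups")
    rows = []
    for limb, (ini, non) in plv_groups.items():
        res = independent_ttest_with_variance_check(
            ini.per_trial, non.per_trial, name=f"{limb.value} initial vs non-initial"
        )
        rows.append(
            {
                "limb": limb.value,
                "pair": "-".join(ini.pair),
                "n_initial": len(ini.per_trial),
                "n_noninitial": len(non.per_trial),
                "mean_initial": ini.mean,
                "mean_noninitial": non.mean,
                "t": res.statistic,
                "df": res.df,
                "p": res.pvalue,
                "branch": res.note,
                "sig": res.stars,
            }
        )
    table = pd.DataFrame(rows)
    if holm:
        table["p_holm"] = _holm(table["p"].to_numpy())
        table["sig"] = [_stars(p) for p in table["p_holm"]]
    return table


def accuracy_comparison(acc_condition1, acc_condition2) -> pd.DataFrame:
    """Two-sample t-test row comparing decoding accuracies across conditions."""
    a1 = np.asarray(acc_condition1, float)
    a2 = np.asarray(acc_condition2, float)
    res = independent_ttest_with_variance_check(
        a1, a2, name="condition 1 vs condition 2 accuracy"
    )
    return pd.DataFrame(
        [
            {
                "comparison": res.name,
                "mean_condition1": a1.mean(),
                "mean_condition2": a2.mean(),
                "t": res.statistic,
                "df": res.df,
                "p": res.pvalue,
                "branch": res.note,
                "sig": res.stars,
            }
        ]
    )


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def report_tables(
    erd_values: pd.DataFrame | None = None,
    plv_groups=None,
    cv_accuracies: tuple | None = None,
    holm: bool = False,
) -> dict[str, pd.DataFrame]:
    """Assemble the summary tables of whichever analyses are available."""
    if erd_values is None and plv_groups is None and cv_accuracies is None:
        raise ValueError("no analysis inputs given")
    out: dict[str, pd.DataFrame] = {}
    if erd_values is not None:
        out["erd_contrasts"] = erd_contrast_table(erd_values, holm=holm)
    if plv_groups is not None:
        out["plv_contrasts"] = plv_contrast_table(plv_groups, holm=holm)
    if cv_accuracies is not None:
        out["accuracy_comparison"] = accuracy_comparison(*cv_accuracies)
    return out
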