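"""Group statistics: independent t-tests, mixed repeated-measures ANOVA
with partial eta squared, Bonferroni adjustment, and participant screening.

The ANOVA is the balanced univariate split-plot decomposition with subject
as the blocking unit: one between-subject factor (group) and one or two
within-subject factors (e.g. trial type and electrode site).  Each
between-  or within-level effect is tested against its own error stratum
(subjects within groups for the group effect; the factor x subject
interaction within groups for within effects).  Effect sizes are partial
eta squared, SS_effect / (SS_effect + SS_error), which equals
F*df_num / (F*df_num + df_den).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "AnovaResult",
    "MissingCellError",
    "independent_t_test",
    "mixed_rm_anova",
    "bonferroni_adjust",
    "pairwise_followup",
    "screen_participants",
    "VAT_VGA_MIN",
    "VAT_CONTROL_MAX",
]

VAT_VGA_MIN = 2.5
VAT_CONTROL_MAX = 1.5
VAT_RANGE = (0.0, 5.0)


class MissingCellError(ValueError):
    """A subject lacks one or more within-subject cells (no imputation)."""


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float
    correction: str = "none"


def independent_t_test(x, y, equal_var: bool = True) -> TTestResult:
    """Two-sided independent-samples t-test (pooled variance by default;
    ``equal_var=False`` gives Welch's test).

    Degenerate input with zero pooled variance and equal means returns
    t=0, p=1 rather than nan.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    import warnings
    with warnings.catch_warnings():
        # degenerate zero-variance input is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(x, y, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    df = float(res.df)
    if math.isnan(t):
        if np.isclose(x.mean(), y.mean()):
            t, p = 0.0, 1.0
        else:  # zero variance, unequal means: infinitely strong evidence
            t, p = math.copysign(math.inf, x.mean() - y.mean()), 0.0
    return TTestResult(t=t, df=df, p=p,
                       mean_a=float(x.mean()), sd_a=float(x.std(ddof=1)),
                       mean_b=float(y.mean()), sd_b=float(y.std(ddof=1)),
                       n_a=int(x.size), n_b=int(y.size))


def _check_balanced(table: pd.DataFrame, subject: str, within: list[str]) -> None:
    levels = [sorted(table[w].unique()) for w in within]
    expected = set(itertools.product(*levels))
    missing: list[str] = []
    for sub, g in table.groupby(subject):
        have = set(map(tuple, g[within].itertuples(index=False)))
        for cell in sorted(expected - have):
            missing.append(f"{sub}: {dict(zip(within, cell))}")
    if missing:
        raise MissingCellError(
            "unbalanced design; missing subject x cell combinations "
            f"(no imputation is attempted): {missing[:10]}")
    sizes = table.groupby([subject, *within]).size()
    if (sizes > 1).any():
        raise MissingCellError(
            "replicated subject x cell observations; aggregate to one value "
            "per cell first")


def _f_result(name: str, ss_eff: float, df_eff: int, ss_err: float,
              df_err: int) -> AnovaResult:
    ms_eff = ss_eff / df_eff if df_eff else np.nan
    ms_err = ss_err / df_err if df_err else np.nan
    F = ms_eff / ms_err if ms_err > 0 else (0.0 if ss_eff == 0 else np.inf)
    p = float(sps.f.sf(F, df_eff, df_err)) if np.isfinite(F) else 0.0
    peta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    return AnovaResult(effect=name, F=float(F), df_num=df_eff, df_den=df_err,
                       p=p, partial_eta_sq=float(peta),
                       ss_effect=float(ss_eff), ss_error=float(ss_err))


def mixed_rm_anova(table: pd.DataFrame, dv: str, subject: str,
                   between: str, within: list[str] | str) -> list[AnovaResult]:
    """Balanced mixed (split-plot) repeated-measures ANOVA.

    ``table`` is long-format with one row per subject x within-cell.  One
    or two within factors are supported.  Returns results for every main
    effect and interaction, each with its partial eta squared.
    """
    within = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("one or two within-subject factors are supported")
    cols = [subject, between, *within, dv]
    t = table[cols].copy()
    if t[dv].isna().any():
        raise MissingCellError("missing values in the dependent variable")
    groups_per_subject = t.groupby(subject)[between].nunique()
    if (groups_per_subject > 1).any():
        bad = groups_per_subject[groups_per_subject > 1].index.tolist()
        raise ValueError(f"subjects in more than one group: {bad[:5]}")
    if t.groupby(between)[subject].nunique().min() < 2:
        raise ValueError("need >= 2 subjects per group")
    _check_balanced(t, subject, within)

    y = t[dv].to_numpy()
    grand = y.mean()
    n_obs = y.size

    def mean_of(*factors: str) -> pd.Series:
        return t.groupby(list(factors), observed=True)[dv].mean()

    def ss_from_effect(factors: list[str], effect: pd.Series) -> float:
        # Weight each cell's squared deviation by its observation count;
        # exact for unequal group sizes (within design balanced per subject).
        counts = t.groupby(factors, observed=True).size()
        return float((effect ** 2 * counts.reindex(effect.index)).sum())

    g = between
    a = within[0]
    b = within[1] if len(within) == 2 else None
    subj_group = t.groupby(subject, observed=True)[between].first()
    n_subj = subj_group.size
    n_groups = t[g].nunique()
    la = t[a].nunique()
    lb = t[b].nunique() if b else 1

    m_g = mean_of(g)
    m_s = mean_of(subject)
    m_a = mean_of(a)
    m_ga = mean_of(g, a)
    m_sa = mean_of(subject, a)

    # Between-subject stratum.
    eff_g = m_g - grand
    ss_g = ss_from_effect([g], eff_g)
    dev_s = m_s - m_g.reindex(subj_group).to_numpy()  # subject minus its group
    ss_s = float((dev_s ** 2).sum() * la * lb)
    df_s = n_subj - n_groups

    results = [_f_result(g, ss_g, n_groups - 1, ss_s, df_s)]

    # Within stratum for factor A.
    ss_a = ss_from_effect([a], m_a - grand)
    inter_ga = (m_ga
                - m_g.reindex(m_ga.index.get_level_values(0)).to_numpy()
                - m_a.reindex(m_ga.index.get_level_values(1)).to_numpy()
                + grand)
    ss_ga = ss_from_effect([g, a], inter_ga)
    sa = m_sa.reset_index()
    sa["grp"] = subj_group.reindex(sa[subject]).to_numpy()
    sa_dev = (sa[dv].to_numpy()
              - m_s.reindex(sa[subject]).to_numpy()
              - m_ga.reindex(pd.MultiIndex.from_frame(sa[["grp", a]])).to_numpy()
              + m_g.reindex(sa["grp"]).to_numpy())
    ss_sa = float((sa_dev ** 2).sum() * lb)
    df_sa = (n_subj - n_groups) * (la - 1)
    results.append(_f_result(a, ss_a, la - 1, ss_sa, df_sa))
    results.append(_f_result(f"{g}:{a}", ss_ga, (n_groups - 1) * (la - 1),
                             ss_sa, df_sa))

    if b is not None:
        m_b = mean_of(b)
        m_gb = mean_of(g, b)
        m_sb = mean_of(subject, b)
        m_ab = mean_of(a, b)
        m_gab = mean_of(g, a, b)

        ss_b = ss_from_effect([b], m_b - grand)
        inter_gb = (m_gb
                    - m_g.reindex(m_gb.index.get_level_values(0)).to_numpy()
                    - m_b.reindex(m_gb.index.get_level_values(1)).to_numpy()
                    + grand)
        ss_gb = ss_from_effect([g, b], inter_gb)
        sb = m_sb.reset_index()
        sb["grp"] = subj_group.reindex(sb[subject]).to_numpy()
        sb_dev = (sb[dv].to_numpy()
                  - m_s.reindex(sb[subject]).to_numpy()
                  - m_gb.reindex(pd.MultiIndex.from_frame(sb[["grp", b]])).to_numpy()
                  + m_g.reindex(sb["grp"]).to_numpy())
        ss_sb = float((sb_dev ** 2).sum() * la)
        df_sb = (n_subj - n_groups) * (lb - 1)
        results.append(_f_result(b, ss_b, lb - 1, ss_sb, df_sb))
        results.append(_f_result(f"{g}:{b}", ss_gb,
                                 (n_groups - 1) * (lb - 1), ss_sb, df_sb))

        inter_ab = (m_ab
                    - m_a.reindex(m_ab.index.get_level_values(0)).to_numpy()
                    - m_b.reindex(m_ab.index.get_level_values(1)).to_numpy()
                    + grand)
        ss_ab = ss_from_effect([a, b], inter_ab)
        gab = m_gab.reset_index()
        gab_dev = (gab[dv].to_numpy()
                   - m_ga.reindex(pd.MultiIndex.from_frame(gab[[g, a]])).to_numpy()
                   - m_gb.reindex(pd.MultiIndex.from_frame(gab[[g, b]])).to_numpy()
                   - m_ab.reindex(pd.MultiIndex.from_frame(gab[[a, b]])).to_numpy()
                   + m_g.reindex(gab[g]).to_numpy()
                   + m_a.reindex(gab[a]).to_numpy()
                   + m_b.reindex(gab[b]).to_numpy()
                   - grand)
        gab_counts = t.groupby([g, a, b], observed=True).size()
        gab_idx = pd.MultiIndex.from_frame(gab[[g, a, b]])
        ss_gab = float((gab_dev ** 2 * gab_counts.reindex(gab_idx).to_numpy()).sum())
        ss_total = float(((y - grand) ** 2).sum())
        explained = (ss_g + ss_s + ss_a + ss_ga + ss_sa + ss_b + ss_gb
                     + ss_sb + ss_ab + ss_gab)
        ss_abs = max(ss_total - explained, 0.0)
        df_abs = (n_subj - n_groups) * (la - 1) * (lb - 1)
        results.append(_f_result(f"{a}:{b}", ss_ab, (la - 1) * (lb - 1),
                                 ss_abs, df_abs))
        results.append(_f_result(
            f"{g}:{a}:{b}", ss_gab, (n_groups - 1) * (la - 1) * (lb - 1),
            ss_abs, df_abs))
    return results


def anova_table(results: list[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def bonferroni_adjust(p_values, family_size: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, p * m); order-preserving."""
    p_values = list(p_values)
    m = family_size if family_size is not None else len(p_values)
    if m < len(p_values):
        raise ValueError(
            f"family_size={m} smaller than number of p-values ({len(p_values)})")
    return [min(1.0, float(p) * m) for p in p_values]


def pairwise_followup(table: pd.DataFrame, dv: str, between: str,
                      by: list[str]) -> pd.DataFrame:
    """Group comparisons within each cell of ``by``, Bonferroni-adjusted
    over the cells (the follow-up family for one ANOVA effect)."""
    rows = []
    cells = list(table.groupby(by, observed=True))
    for key, cell in cells:
        key = key if isinstance(key, tuple) else (key,)
        groups = sorted(cell[between].unique())
        if len(groups) != 2:
            continue
        res = independent_t_test(
            cell.loc[cell[between] == groups[0], dv],
            cell.loc[cell[between] == groups[1], dv])
        rows.append({**dict(zip(by, key)), "t": res.t, "df": res.df,
                     "p": res.p, f"mean_{groups[0]}": res.mean_a,
                     f"mean_{groups[1]}": res.mean_b})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_bonferroni"] = bonferroni_adjust(out["p"], len(out))
    return out


def screen_participants(table: pd.DataFrame, score_col: str = "vat",
                        group_col: str = "group") -> pd.DataFrame:
    """Eligibility flags from mean-item VAT scores.

    A subject is eligible for the gamer group at score >= 2.5 and for the
    control group at score <= 1.5; scores in between qualify for neither.
    Scores outside the instrument's 0-5 range raise.
    """
    scores = table[score_col].astype(float)
    bad = table.loc[(scores < VAT_RANGE[0]) | (scores > VAT_RANGE[1])]
    if not bad.empty:
        raise ValueError(
            f"VAT scores outside {VAT_RANGE}: {bad[score_col].tolist()[:5]}")
    out = table.copy()
    out["vga_eligible"] = scores >= VAT_VGA_MIN
    out["control_eligible"] = scores <= VAT_CONTROL_MAX
    if group_col in out.columns:
        assigned_ok = np.where(
            out[group_col].str.lower().isin(("vga", "gamer", "vg")),
            out["vga_eligible"], out["control_eligible"])
        out["eligible_for_assigned_group"] = assigned_ok
    return out
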