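"""Statistics layer: within-subject ANOVA, post hoc t-tests, correlations.

Implements the three analyses applied to the microstate parameters and the
evaluation scores:

* two-way fully-within-subject (repeated measures) ANOVA with
  Greenhouse-Geisser sphericity correction and both partial and
  generalized eta-squared,
* Bonferroni-corrected paired t-tests for post hoc contrasts,
* a Bonferroni-corrected Spearman correlation matrix between microstate
  parameters (per class) and evaluation dimensions.

The ANOVA is computed from first principles (sums-of-squares partition with
subject as the random blocking factor; each effect tested against its own
factor x subject interaction) so that the sphericity machinery is explicit
and auditable; tests cross-check it against an independent implementation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, stats as sst

DIMENSIONS = ("D1", "D2", "D3", "D4", "D5")


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def _cell_matrix(table: pd.DataFrame, dv: str, subject: str, a: str,
                 b: str) -> tuple[np.ndarray, list, list]:
    """Pivot a long table to subjects x (A x B) cells; no missing cells."""
    wide = table.pivot_table(index=subject, columns=[a, b], values=dv,
                             aggfunc="mean", dropna=False)
    if wide.isna().any().any():
        raise ValueError("missing cells in the within-subject design")
    a_levels = sorted(table[a].unique())
    b_levels = sorted(table[b].unique())
    cols = pd.MultiIndex.from_product([a_levels, b_levels])
    if set(cols) != set(wide.columns):
        raise ValueError("design is not fully crossed")
    return wide[cols].to_numpy(float), a_levels, b_levels


def _gg_epsilon(Y: np.ndarray, C: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of an effect with orthonormal contrasts C.

    eps = tr(M)^2 / (d * tr(M^2)) with M = C S C', S the covariance of the
    cell scores across subjects and d the effect's degrees of freedom.
    Bounded in [1/d, 1]; equals 1 exactly under sphericity.
    """
    S = np.cov(Y, rowvar=False, ddof=1)
    M = C @ S @ C.T
    d = C.shape[0]
    tr2 = np.trace(M @ M)
    if tr2 <= 0:
        return 1.0
    return float(np.clip(np.trace(M) ** 2 / (d * tr2), 1.0 / d, 1.0))


def rm_anova_2way(table: pd.DataFrame, dv: str, subject: str = "subject",
                  factor_a: str = "class", factor_b: str = "stage") -> pd.DataFrame:
    """Two-way fully repeated-measures ANOVA with GG correction.

    Expects a long table with one value per subject x factor_a x factor_b
    cell (no imputation: missing cells raise).  Returns one row per source
    (factor_a, factor_b, interaction) with columns:

    ``ss, ss_error, ddof1, ddof2, F, p_unc, eps_gg, p_gg, eta2_partial,
    eta2_generalized``.

    Each effect is tested against its own factor x subject interaction;
    ``p_gg`` scales both degrees of freedom by the effect's
    Greenhouse-Geisser epsilon.
    """
    Y, a_levels, b_levels = _cell_matrix(table, dv, subject, factor_a, factor_b)
    n, _ = Y.shape
    a, b = len(a_levels), len(b_levels)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    cells = Y.reshape(n, a, b)

    grand = cells.mean()
    m_subj = cells.mean(axis=(1, 2))
    m_a = cells.mean(axis=(0, 2))
    m_b = cells.mean(axis=(0, 1))
    m_ab = cells.mean(axis=0)
    m_as = cells.mean(axis=2)
    m_bs = cells.mean(axis=1)

    ss_subj = a * b * np.sum((m_subj - grand) ** 2)
    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_as - m_subj[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_bs - m_subj[:, None] - m_b[None, :] + grand) ** 2)
    ss_total = np.sum((cells - grand) ** 2)
    ss_abs = ss_total - (ss_subj + ss_a + ss_b + ss_ab + ss_as + ss_bs)
    ss_abs = max(ss_abs, 0.0)

    # orthonormal contrast bases (rows orthogonal to the constant vector)
    Qa = linalg.helmert(a)
    Qb = linalg.helmert(b)
    ua = np.full((1, a), 1.0 / np.sqrt(a))
    ub = np.full((1, b), 1.0 / np.sqrt(b))
    contrasts = {
        factor_a: np.kron(Qa, ub),
        factor_b: np.kron(ua, Qb),
        f"{factor_a} x {factor_b}": np.kron(Qa, Qb),
    }
    effects = {
        factor_a: (ss_a, ss_as, a - 1, (a - 1) * (n - 1)),
        factor_b: (ss_b, ss_bs, b - 1, (b - 1) * (n - 1)),
        f"{factor_a} x {factor_b}": (
            ss_ab, ss_abs, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1)),
    }
    ges_denom_extra = ss_subj + ss_as + ss_bs + ss_abs

    rows = []
    for source, (ss_eff, ss_err, df1, df2) in effects.items():
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        F = ms_eff / ms_err if ms_err > 0 else 0.0
        p_unc = float(sst.f.sf(F, df1, df2)) if ms_err > 0 else 1.0
        eps = _gg_epsilon(Y, contrasts[source])
        p_gg = float(sst.f.sf(F, eps * df1, eps * df2)) if ms_err > 0 else 1.0
        rows.append({
            "source": source, "ss": ss_eff, "ss_error": ss_err,
            "ddof1": df1, "ddof2": df2, "F": F, "p_unc": p_unc,
            "eps_gg": eps, "p_gg": p_gg,
            "eta2_partial": ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0,
            "eta2_generalized": ss_eff / (ss_eff + ges_denom_extra)
            if ss_eff + ges_denom_extra > 0 else 0.0,
        })
    out = pd.DataFrame(rows)
    out.attrs["ss_total"] = float(ss_total)
    out.attrs["ss_subject"] = float(ss_subj)
    out.attrs["ss_partition"] = float(
        ss_subj + ss_a + ss_b + ss_ab + ss_as + ss_bs + ss_abs)
    return out


# ---------------------------------------------------------------------------
# post hoc paired t-tests


def paired_t_bonferroni(table: pd.DataFrame, dv: str, condition: str,
                        contrasts: list[tuple], subject: str = "subject",
                        family_size: int | None = None) -> pd.DataFrame:
    """Classical paired t-tests with Bonferroni adjustment.

    ``contrasts`` is a list of (level_a, level_b) pairs of the ``condition``
    column; the family size defaults to the number of contrasts.  Identical
    samples give t = 0, p = 1 (rather than an undefined 0/0 statistic).
    """
    wide = table.pivot_table(index=subject, columns=condition, values=dv,
                             aggfunc="mean")
    if len(wide) < 2:
        raise ValueError("need at least 2 subjects for a paired t-test")
    m = family_size if family_size is not None else len(contrasts)
    rows = []
    for lev_a, lev_b in contrasts:
        diff = (wide[lev_a] - wide[lev_b]).to_numpy(float)
        if np.allclose(diff, diff[0]) and np.isclose(diff.std(ddof=1), 0.0):
            if diff[0] == 0:
                t, p = 0.0, 1.0
            else:  # constant nonzero difference: infinitely strong evidence
                t, p = np.inf * np.sign(diff[0]), 0.0
        else:
            t, p = sst.ttest_rel(wide[lev_a], wide[lev_b])
        rows.append({
            "contrast": f"{lev_a} vs {lev_b}", "level_a": lev_a, "level_b": lev_b,
            "n": len(diff), "t": float(t), "p_raw": float(p),
            "p_bonf": float(min(1.0, p * m)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# brain-behavior Spearman correlations


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with the t-approximation p."""
    res = sst.spearmanr(x, y)
    rho = float(res.statistic)
    if np.isnan(rho):
        return 0.0, 1.0
    return rho, float(res.pvalue)


def spearman_matrix(parameter_summary: pd.DataFrame, evaluations: pd.DataFrame,
                    parameters: tuple[str, ...] = ("coverage", "duration",
                                                   "occurrence"),
                    unit: str = "subject_stage", alpha: float = 0.05) -> pd.DataFrame:
    """Spearman correlations of parameter-per-class vs evaluation dimensions.

    Observations are (subject, stage) pairs by default — stage-mean
    parameters against per-stage scores — or per-subject means with
    ``unit="subject"``.  The Bonferroni family is all class x dimension
    cells within one parameter type (e.g. 7 x 5 = 35 tests per heatmap).

    Returns a tidy frame with one row per (parameter, class, dimension):
    ``rho, p_raw, p_bonf, significant``.
    """
    keys = ["subject", "stage"]
    evals = evaluations.pivot_table(index=keys, columns="dimension",
                                    values="score", aggfunc="mean")
    dims = list(evals.columns)
    classes = sorted(parameter_summary["class"].unique())
    family = len(classes) * len(dims)

    rows = []
    for param in parameters:
        par = parameter_summary.pivot_table(index=keys, columns="class",
                                            values=param, aggfunc="mean")
        joined = par.join(evals, how="inner")
        if unit == "subject":
            joined = joined.groupby(level="subject").mean()
        elif unit != "subject_stage":
            raise ValueError(f"unknown observation unit {unit!r}")
        for cls in classes:
            for dim in dims:
                pair = joined[[cls, dim]].dropna()
                if len(pair) < 4:
                    raise ValueError(
                        f"fewer than 4 paired observations for {param}/{cls}/{dim}")
                rho, p = spearman_with_p(pair[cls].to_numpy(),
                                         pair[dim].to_numpy())
                p_bonf = min(1.0, p * family)
                rows.append({
                    "parameter": param, "class": cls, "dimension": dim,
                    "n": len(pair), "rho": rho, "p_raw": p, "p_bonf": p_bonf,
                    "significant": p_bonf <= alpha,
                })
    return pd.DataFrame(rows)
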