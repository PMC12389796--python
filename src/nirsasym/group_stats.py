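"""Group and longitudinal statistics for asymmetry tables.

The inferential layer is nonparametric throughout: a repeated-measures
factorial ANOVA with aligned rank transform (ART) for the hand/hemisphere x
channel designs, Wilcoxon signed-rank tests per symmetric channel pair, and
Benjamini-Yekutieli (BY) false-discovery-rate adjustment - valid under
arbitrary dependence, inflating raw p by c(m) = sum_{i<=m} 1/i - within
each (index kind, chromophore) family.  Day-to-day dynamics are summarized
by per-channel ordinary linear regressions of the day-averaged index on the
day number, and clinical associations by Pearson correlation.

ART, per effect: decompose the balanced table into grand mean, subject,
main and interaction components; keep that effect's component plus the
residuals (stripping every other effect); rank the aligned values with
average ranks for ties; run a standard balanced factorial ANOVA on the
ranks and report only that effect's row.  The subject blocking term is
included by default (proper repeated measures); disabling it reproduces the
residual degrees of freedom of a plain two-way layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

AVERAGE_DROPS = {
    "sessions": {"session", "day"},
    "sessions_within_day": {"session"},
    "subjects": {"subject"},
    "channels": {"unit"},
}

_KEY_COLS = ["subject", "session", "day", "unit", "hemisphere", "chromophore", "index_kind"]


@dataclass
class StatsReport:
    anova: pd.DataFrame
    pair_tests: pd.DataFrame
    slopes: pd.DataFrame
    correlations: pd.DataFrame

    def to_csv_dir(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.anova.to_csv(outdir / "anova.csv", index=False)
        self.pair_tests.to_csv(outdir / "pair_tests.csv", index=False)
        self.slopes.to_csv(outdir / "slopes.csv", index=False)
        self.correlations.to_csv(outdir / "correlations.csv", index=False)

    def summary(self) -> str:
        lines = ["ART ANOVA", self.anova.to_string(index=False)]
        if len(self.pair_tests):
            lines += ["", "Pairwise Wilcoxon (BY-adjusted)", self.pair_tests.to_string(index=False)]
        if len(self.slopes):
            lines += ["", "Daily slopes", self.slopes.to_string(index=False)]
        if len(self.correlations):
            lines += ["", "Clinical correlations", self.correlations.to_string(index=False)]
        return "\n".join(lines)


def average_levels(table: pd.DataFrame, over: str) -> pd.DataFrame:
    """Arithmetic mean of ``value`` within groups after dropping a level.

    ``over``: "sessions" (drop session and day), "sessions_within_day"
    (drop session, keep day), "subjects", or "channels" (drop unit, keep
    hemisphere).  Group sizes are recorded in ``n_averaged``.
    """
    if over not in AVERAGE_DROPS:
        raise ValueError(f"unknown averaging level {over!r}")
    drop = AVERAGE_DROPS[over]
    keys = [c for c in _KEY_COLS if c in table.columns and c not in drop]
    if not keys:
        raise ValueError("no grouping keys left after dropping")
    out = (
        table.groupby(keys, as_index=False, sort=True)
        .agg(value=("value", "mean"), n_averaged=("value", "size"))
    )
    return out


def benjamini_yekutieli(pvals) -> np.ndarray:
    """BY-adjusted p-values (arbitrary-dependence FDR control)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_by")[1]


def _balanced_cube(
    data: pd.DataFrame, subject: str, factor_a: str, factor_b: str, value: str
) -> tuple[np.ndarray, list, list, list]:
    s_codes, subjects = pd.factorize(data[subject], sort=True)
    a_codes, a_levels = pd.factorize(data[factor_a], sort=True)
    b_codes, b_levels = pd.factorize(data[factor_b], sort=True)
    shape = (len(subjects), len(a_levels), len(b_levels))
    count = np.zeros(shape, dtype=int)
    cube = np.full(shape, np.nan)
    np.add.at(count, (s_codes, a_codes, b_codes), 1)
    if data[value].isna().any() or not np.all(count == 1):
        raise ValueError(
            "art_anova needs a complete balanced design with one value per "
            "(subject, A, B) cell; average over sessions first"
        )
    cube[s_codes, a_codes, b_codes] = data[value].to_numpy(dtype=float)
    return cube, list(subjects), list(a_levels), list(b_levels)


def _effects(cube: np.ndarray):
    grand = cube.mean()
    subj = cube.mean(axis=(1, 2)) - grand  # (ns,)
    a = cube.mean(axis=(0, 2)) - grand  # (na,)
    b = cube.mean(axis=(0, 1)) - grand  # (nb,)
    ab = cube.mean(axis=0) - grand - a[:, None] - b[None, :]  # (na, nb)
    resid = (
        cube
        - grand
        - subj[:, None, None]
        - a[None, :, None]
        - b[None, None, :]
        - ab[None, :, :]
    )
    return grand, subj, a, b, ab, resid


def _rank_anova(ranks: np.ndarray, effect: str, include_subject_term: bool):
    ns, na, nb = ranks.shape
    grand, subj, a, b, ab, resid = _effects(ranks)
    ss = {
        "A": ns * nb * float(np.sum(a**2)),
        "B": ns * na * float(np.sum(b**2)),
        "AB": ns * float(np.sum(ab**2)),
    }
    df = {"A": na - 1, "B": nb - 1, "AB": (na - 1) * (nb - 1)}
    ss_res = float(np.sum(resid**2))
    df_res = ns * na * nb - 1 - df["A"] - df["B"] - df["AB"]
    if include_subject_term:
        df_res -= ns - 1
    else:
        ss_res += na * nb * float(np.sum(subj**2))
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_res = ss_res / df_res
    if ms_res > 0:
        f = ss[effect] / df[effect] / ms_res
    else:
        f = 0.0 if ss[effect] == 0 else np.inf
    p = float(stats.f.sf(f, df[effect], df_res))
    return float(f), df[effect], df_res, p


def art_anova(
    data: pd.DataFrame,
    subject: str = "subject",
    factor_a: str = "factor_a",
    factor_b: str = "unit",
    value: str = "value",
    include_subject_term: bool = True,
    effect_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Aligned-rank-transform factorial ANOVA on a balanced within-subject table.

    ``data`` must hold exactly one value per (subject, factor_a, factor_b)
    cell.  Three separate alignments are performed, one per effect (A, B,
    A x B); each aligned set is ranked (average ranks for ties) and pushed
    through a balanced factorial ANOVA, of which only the aligned effect's
    row is reported.  Returns rows (effect, F, df, df_res, p).
    """
    cube, _, a_levels, b_levels = _balanced_cube(data, subject, factor_a, factor_b, value)
    _, subj, a, b, ab, resid = _effects(cube)
    comps = {
        "A": a[None, :, None] + np.zeros_like(cube),
        "B": b[None, None, :] + np.zeros_like(cube),
        "AB": ab[None, :, :] + np.zeros_like(cube),
    }
    names = effect_names or {"A": factor_a, "B": factor_b, "AB": f"{factor_a}:{factor_b}"}
    rows = []
    for eff in ("A", "B", "AB"):
        aligned = resid + comps[eff]
        ranks = stats.rankdata(aligned, axis=None).reshape(cube.shape)
        f, df1, df2, p = _rank_anova(ranks, eff, include_subject_term)
        rows.append({"effect": names[eff], "F": f, "df": df1, "df_res": df2, "p": p})
    return pd.DataFrame(rows)


def pairwise_wilcoxon(
    diffs_by_unit: dict[str, np.ndarray],
    min_n: int = 5,
) -> pd.DataFrame:
    """Two-sided Wilcoxon signed-rank per unit pair, BY-adjusted across units.

    ``diffs_by_unit`` maps each symmetric channel pair to the per-subject
    paired differences.  Zeros are dropped (signed-rank convention) and
    counted; the exact null distribution is used for n <= 25 without ties,
    the tie-corrected normal approximation otherwise.  Pairs with fewer
    than ``min_n`` nonzero differences are flagged underpowered; all-zero
    pairs get p = 1.
    """
    rows = []
    for unit, d in diffs_by_unit.items():
        d = np.asarray(d, dtype=float)
        nz = d[d != 0]
        n_zero = int(d.size - nz.size)
        flag = ""
        if nz.size == 0:
            p = 1.0
            flag = "all_zero"
            stat = 0.0
        else:
            has_ties = len(np.unique(np.abs(nz))) < nz.size
            method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
            res = stats.wilcoxon(nz, alternative="two-sided", method=method, correction=True)
            stat, p = float(res.statistic), float(res.pvalue)
            if nz.size < min_n:
                flag = "underpowered"
        rows.append(
            {"unit": unit, "n": int(nz.size), "n_zero": n_zero,
             "statistic": stat, "p_raw": p, "flag": flag}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = benjamini_yekutieli(out["p_raw"].to_numpy())
    return out


def daily_slopes(
    day_table: pd.DataFrame,
    alpha: float = 0.05,
    family_cols: tuple[str, ...] = ("index_kind", "chromophore"),
) -> pd.DataFrame:
    """Per-channel OLS slope of the day-averaged index on the day number.

    Requires >= 3 distinct days per series.  Slope p-values are t-test
    based and BY-adjusted across channels within each family (by default
    one family per index kind x chromophore).  Flags: "*" for raw p <
    alpha, "**" when the BY-adjusted p also clears alpha.
    """
    keys = [c for c in ("subject", "unit", "hemisphere", *family_cols) if c in day_table.columns]
    rows = []
    for keyvals, grp in day_table.groupby(keys, sort=True):
        if not isinstance(keyvals, tuple):
            keyvals = (keyvals,)
        days = grp["day"].to_numpy(dtype=float)
        if len(np.unique(days)) < 3:
            continue
        res = stats.linregress(days, grp["value"].to_numpy(dtype=float))
        rows.append(
            dict(zip(keys, keyvals))
            | {"slope": float(res.slope), "intercept": float(res.intercept),
               "p_raw": float(res.pvalue), "n_days": int(len(np.unique(days)))}
        )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("daily_slopes needs >= 3 distinct days for at least one series")
    fam = [c for c in family_cols if c in out.columns]
    if "subject" in out.columns:
        fam = ["subject"] + fam
    if fam:
        out["p_adj"] = out.groupby(fam)["p_raw"].transform(benjamini_yekutieli)
    else:
        out["p_adj"] = benjamini_yekutieli(out["p_raw"].to_numpy())
    out["flag"] = np.where(
        out["p_adj"] < alpha, "**", np.where(out["p_raw"] < alpha, "*", "")
    )
    return out


def clinical_correlation(
    metrics: pd.DataFrame, clinical: pd.DataFrame, on: str = "subject"
) -> pd.DataFrame:
    """Pearson r between each metric column and each clinical column.

    ``metrics`` and ``clinical`` are subject-level frames sharing the
    ``on`` key; every numeric column is used.  Zero-variance columns are
    reported with missing r and flagged.
    """
    merged = metrics.merge(clinical, on=on, suffixes=("_metric", "_clinical"))
    metric_cols = [c for c in metrics.columns if c != on]
    clin_cols = [c for c in clinical.columns if c != on]
    rows = []
    for mc in metric_cols:
        mc_m = mc if mc in merged.columns else f"{mc}_metric"
        for cc in clin_cols:
            cc_m = cc if cc in merged.columns else f"{cc}_clinical"
            sub = merged[[mc_m, cc_m]].dropna()
            x = sub[mc_m].to_numpy(dtype=float)
            y = sub[cc_m].to_numpy(dtype=float)
            if len(x) < 3:
                rows.append({"clinical": cc, "metric": mc, "r": np.nan, "p": np.nan,
                             "n": len(x), "flag": "too_few"})
                continue
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append({"clinical": cc, "metric": mc, "r": np.nan, "p": np.nan,
                             "n": len(x), "flag": "zero_variance"})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"clinical": cc, "metric": mc, "r": float(r), "p": float(p),
                         "n": len(x), "flag": ""})
    return pd.DataFrame(rows)
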