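"""Per-CpG dose (or time) association analysis.

For each probe, methylation is modeled as a linear function of radiation
dose, with time-after-exposure and chip row as fixed covariates and a
random intercept for chip; for the time analysis the roles of dose and
time are swapped.  Each probe yields a slope (beta-units per Gy or per
day), a Wald standard error and two-sided p-value; the table is then
corrected for multiplicity (Holm step-down family-wise control, plus
Benjamini-Hochberg q-values), direction-called, and tiered: Holm-corrected
p < 0.05 is "nominal", uncorrected p < 0.001 "moderate".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .mixedlm import MixedFitResult, RandomInterceptModel

__all__ = [
    "build_design",
    "fit_probe_mixed_model",
    "run_ewas",
    "holm_adjust",
    "fdr_adjust",
    "classify_dose_time_sites",
    "global_trend_test",
    "persistence_summary",
]


def build_design(sheet: pd.DataFrame, target_term: str) -> tuple[np.ndarray, list, np.ndarray]:
    """Fixed-effect design matrix for the per-probe model.

    Columns: intercept, target (dose or time), the other exposure variable,
    then chip-row indicator contrasts (first row level as reference).
    Returns (X, column names, chip grouping codes).
    """
    if target_term not in ("dose", "time"):
        raise ValueError("target_term must be 'dose' or 'time'")
    other = "time" if target_term == "dose" else "dose"
    cols = [np.ones(len(sheet)), sheet[target_term].to_numpy(float)]
    names = ["intercept", target_term]
    if sheet[other].nunique() > 1:
        cols.append(sheet[other].to_numpy(float))
        names.append(other)
    row_levels = sorted(sheet["row"].unique())
    for level in row_levels[1:]:
        cols.append((sheet["row"] == level).to_numpy(float))
        names.append(f"row_{level}")
    X = np.column_stack(cols)
    return X, names, sheet["chip"].to_numpy()


def fit_probe_mixed_model(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    target_index: int = 1,
    free_variance: bool = True,
) -> tuple[float, float, float]:
    """Fit one probe; returns (slope, standard error, two-sided Wald p).

    Constant responses and singular designs yield NaN statistics.  With
    ``free_variance=False`` the chip variance is constrained to zero and
    the result equals ordinary least squares on the fixed effects.
    """
    try:
        model = RandomInterceptModel(X, groups)
    except ValueError:
        return np.nan, np.nan, np.nan
    res = model.fit(np.asarray(y, float), free_variance=free_variance)
    if not res.ok:
        return np.nan, np.nan, np.nan
    return float(res.beta[target_index]), float(res.se[target_index]), res.wald_p(target_index)


def run_ewas(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    target_term: str = "dose",
    min_present_frac: float = 0.8,
    free_variance: bool = True,
) -> pd.DataFrame:
    """Per-probe mixed-model association scan for one exposure series.

    Missing beta values are handled by per-probe listwise sample deletion;
    probes with fewer than ``min_present_frac`` of samples present are
    skipped and flagged.  Returns an association table indexed by probe
    with columns slope, se, p, holm_p, fdr_q, direction, baseline_beta,
    tier, n_used, flag.
    """
    sheet = sheet.loc[beta.columns]
    if sheet[target_term].nunique() < 2:
        raise ValueError(f"series has a single {target_term} level; association undefined")

    values = beta.to_numpy(float)
    n_probes, n_samples = values.shape
    present = ~np.isnan(values)

    # group probes by missingness pattern so each design is decomposed once
    models: dict[bytes, tuple[RandomInterceptModel | None, np.ndarray, int]] = {}

    slopes = np.full(n_probes, np.nan)
    ses = np.full(n_probes, np.nan)
    pvals = np.full(n_probes, np.nan)
    n_used = present.sum(axis=1)
    flags = np.array([""] * n_probes, dtype=object)

    min_n = int(np.ceil(min_present_frac * n_samples))
    for i in range(n_probes):
        mask = present[i]
        if n_used[i] < min_n:
            flags[i] = "insufficient_samples"
            continue
        key = mask.tobytes()
        if key not in models:
            sub = sheet.loc[beta.columns[mask]]
            try:
                X, names, groups = build_design(sub, target_term)
                model = RandomInterceptModel(X, groups)
                t_idx = names.index(target_term)
                models[key] = (model, mask, t_idx)
            except ValueError:
                models[key] = (None, mask, -1)
        model, mask, t_idx = models[key]
        if model is None:
            flags[i] = "singular_design"
            continue
        res = model.fit(values[i, mask], free_variance=free_variance)
        if not res.ok:
            flags[i] = res.flag
            continue
        slopes[i] = res.beta[t_idx]
        ses[i] = res.se[t_idx]
        pvals[i] = res.wald_p(t_idx)

    zero_dose = sheet["dose"].to_numpy(float) == 0.0
    if zero_dose.any():
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            baseline = np.nanmean(values[:, zero_dose], axis=1)
    else:
        baseline = np.full(n_probes, np.nan)

    table = pd.DataFrame(
        {
            "slope": slopes,
            "se": ses,
            "p": pvals,
            "holm_p": holm_adjust(pvals),
            "fdr_q": fdr_adjust(pvals),
            "direction": np.where(np.isnan(slopes), "", np.where(slopes > 0, "hyper", "hypo")),
            "baseline_beta": baseline,
            "n_used": n_used,
            "flag": flags,
        },
        index=beta.index.rename("probe_id"),
    )
    table["tier"] = "none"
    table.loc[table["p"] < 0.001, "tier"] = "moderate"
    table.loc[table["holm_p"] < 0.05, "tier"] = "nominal"
    return table


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down (step-down Bonferroni) adjusted p-values.

    Sorted ascending, p(i) is multiplied by (m - i + 1), a running maximum
    is enforced, and values are capped at 1.  Missing entries are excluded
    from m and returned as NaN; input order is restored.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = q.size
    if m:
        order = np.argsort(q, kind="stable")
        adj = q[order] * (m - np.arange(m))
        adj = np.maximum.accumulate(adj)
        adj = np.minimum(adj, 1.0)
        restored = np.empty(m)
        restored[order] = adj
        out[ok] = restored
    return out


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1).

    Missing entries are excluded from m and returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = q.size
    if m:
        order = np.argsort(q, kind="stable")
        scaled = q[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(scaled[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        restored = np.empty(m)
        restored[order] = adj
        out[ok] = restored
    return out


def classify_dose_time_sites(
    dose_table: pd.DataFrame,
    time_table: pd.DataFrame,
    p_threshold: float = 0.001,
) -> dict:
    """Partition probes into dose-only, time-only, and dual-associated sets.

    A probe is dose- (time-) significant when its uncorrected p in the
    corresponding table is below ``p_threshold``.  dose_only is the dose
    set minus the dual set.
    """
    if not dose_table.index.equals(time_table.index):
        raise ValueError("dose and time tables must share the same probe universe")
    dose_sig = set(dose_table.index[dose_table["p"] < p_threshold])
    time_sig = set(time_table.index[time_table["p"] < p_threshold])
    return {
        "dose_only": dose_sig - time_sig,
        "time_only": time_sig - dose_sig,
        "both": dose_sig & time_sig,
    }


def global_trend_test(sample_means: pd.Series, sheet: pd.DataFrame) -> tuple[float, float]:
    """Regression of per-sample mean beta on dose, adjusting for time, chip
    ("batch") and chip row ("array"); returns (dose slope, two-sided p)."""
    sheet = sheet.loc[sample_means.index]
    if len(sample_means) < 3 or sheet["dose"].nunique() < 2:
        raise ValueError("need >= 3 samples and >= 2 dose levels")
    cols = {"const": np.ones(len(sheet)), "dose": sheet["dose"].to_numpy(float)}
    if sheet["time"].nunique() > 1:
        cols["time"] = sheet["time"].to_numpy(float)
    for level in sorted(sheet["chip"].unique())[1:]:
        cols[f"chip_{level}"] = (sheet["chip"] == level).to_numpy(float)
    for level in sorted(sheet["row"].unique())[1:]:
        cols[f"row_{level}"] = (sheet["row"] == level).to_numpy(float)
    X = pd.DataFrame(cols, index=sheet.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear design for the global trend test")
    fit = sm.OLS(sample_means.to_numpy(float), X).fit()
    return float(fit.params["dose"]), float(fit.pvalues["dose"])


def persistence_summary(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    probe_ids,
) -> pd.DataFrame:
    """Per dose x time distribution of methylation change versus the
    unexposed earliest-time reference.

    For each affected probe, delta-beta of a sample is its beta minus the
    mean beta of the 0-dose, earliest-time replicates for that probe.
    Returns quartile summaries (q25, median, q75, n) per (dose, time) cell.
    """
    sheet = sheet.loc[beta.columns]
    ref_mask = (sheet["dose"] == 0.0) & (sheet["time"] == sheet["time"].min())
    if not ref_mask.any():
        raise ValueError("missing 0-dose earliest-time reference group")
    sub = beta.loc[beta.index.intersection(pd.Index(probe_ids))]
    if sub.empty:
        raise ValueError("no affected probes present in the beta matrix")
    ref = sub.loc[:, ref_mask.to_numpy()].mean(axis=1)
    delta = sub.sub(ref, axis=0)

    rows = []
    for (dose, time), cell in sheet.groupby(["dose", "time"]):
        vals = delta[cell.index].to_numpy().ravel()
        vals = vals[~np.isnan(vals)]
        q25, med, q75 = np.percentile(vals, [25, 50, 75]) if vals.size else (np.nan,) * 3
        rows.append(
            {"dose": dose, "time": time, "q25": q25, "median": med, "q75": q75, "n": vals.size}
        )
    return pd.DataFrame(rows).sort_values(["dose", "time"]).reset_index(drop=True)
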