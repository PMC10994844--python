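"""Integration of the expression atlas with gene sets and mutant fitness:
co-expression summaries, fitness-phenotype categorization, sRNA
prioritization, and the one-site binding-curve fit.

Fitness phenotypes follow the transposon-insertion reanalysis scheme:
``significant`` iff |t| > 4 in a successful experiment, ``strong`` iff
|fit| > 2 and |t| > 5, ``combined`` iff both. The categories are
independent predicates (a phenotype with |t| in (4, 5] and |fit| > 2 is
significant but not strong).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .models import ExpressionMatrix, FitnessTable

T_SIGNIFICANT = 4.0
T_STRONG = 5.0
FIT_STRONG = 2.0
MEDIAN_R_LABEL = 0.5
MIN_SET_SIZE = 10


def zscore_profiles(
    matrix: ExpressionMatrix, by_condition: bool = True
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene z-scored CPM profiles.

    With ``by_condition`` (default), replicates are first averaged per
    condition, matching correlation across profiled conditions; otherwise
    profiles run over samples. Returns (profiles, zero_variance_gene_ids);
    flagged genes are excluded from the profile table.
    """
    values = matrix.cpm()
    if by_condition:
        groups = {c: matrix.samples_of(c) for c in matrix.conditions}
        values = pd.DataFrame({c: values[cols].mean(axis=1) for c, cols in groups.items()})
    if values.shape[1] < 3:
        raise ValueError("need >= 3 profile points to z-score")
    sd = values.std(axis=1, ddof=0)
    flagged = list(values.index[sd == 0])
    kept = values.loc[sd > 0]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    return z, flagged


@dataclass
class CoexpressionSummary:
    query: str
    table: pd.DataFrame  # index set; columns median_r, n_members_used, labelled


def gene_set_correlation(
    query: str,
    gene_sets: dict[str, list[str]],
    profiles: pd.DataFrame,
    min_set_size: int = MIN_SET_SIZE,
    label_threshold: float = MEDIAN_R_LABEL,
) -> CoexpressionSummary:
    """Median Pearson correlation between the query gene's profile and each
    gene set's member profiles.

    The query is excluded from its own sets; sets with fewer than
    ``min_set_size`` usable members are dropped. Sets with
    |median r| > ``label_threshold`` are labelled.
    """
    if query not in profiles.index:
        raise KeyError(f"query gene {query!r} absent from profiles")
    q = profiles.loc[query].to_numpy(float)
    rows = []
    for name, members in gene_sets.items():
        usable = [g for g in members if g != query and g in profiles.index]
        if len(usable) < min_set_size:
            continue
        sub = profiles.loc[usable].to_numpy(float)
        qz = (q - q.mean()) / q.std()
        sz = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)
        rs = sz @ qz / len(q)
        med = float(np.median(rs))
        rows.append(
            {
                "set": name,
                "median_r": med,
                "n_members_used": len(usable),
                "labelled": abs(med) > label_threshold,
            }
        )
    table = (
        pd.DataFrame(rows).set_index("set")
        if rows
        else pd.DataFrame(columns=["median_r", "n_members_used", "labelled"])
    )
    return CoexpressionSummary(query=query, table=table)


def categorize_fitness(table: FitnessTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the significant/strong/combined thresholds.

    Returns (calls, per_srna_summary). Unsuccessful experiments receive no
    category. The summary counts experiments per category per sRNA and
    carries the max |fit| over successful experiments.
    """
    df = table.to_frame()
    ok = df["success"].astype(bool)
    significant = ok & (df["t"].abs() > T_SIGNIFICANT)
    strong = ok & (df["fit"].abs() > FIT_STRONG) & (df["t"].abs() > T_STRONG)
    combined = significant & strong
    calls = df.assign(significant=significant, strong=strong, combined=combined)
    grouped = calls.groupby("srna")
    summary = pd.DataFrame(
        {
            "n_significant": grouped["significant"].sum().astype(int),
            "n_strong": grouped["strong"].sum().astype(int),
            "n_combined": grouped["combined"].sum().astype(int),
            "max_abs_fit": calls.assign(
                absfit=calls["fit"].abs().where(ok, 0.0)
            ).groupby("srna")["absfit"].max(),
        }
    )
    summary["any_significant"] = summary["n_significant"] > 0
    return calls, summary


def prioritize_srnas(
    summary: pd.DataFrame, expression: ExpressionMatrix | None = None
) -> pd.DataFrame:
    """Rank sRNAs by (significant-experiment count desc, max |fit| desc,
    id asc) and attach expression context where available."""
    out = summary.copy()
    out["max_cpm"] = np.nan
    out["peak_condition"] = None
    out["missing_expression"] = True
    if expression is not None:
        values = expression.cpm()
        cond_means = pd.DataFrame(
            {c: values[expression.samples_of(c)].mean(axis=1) for c in expression.conditions}
        )
        for srna in out.index:
            if srna in cond_means.index:
                prof = cond_means.loc[srna]
                out.loc[srna, "max_cpm"] = float(prof.max())
                out.loc[srna, "peak_condition"] = str(prof.idxmax())
                out.loc[srna, "missing_expression"] = False
    out = out.sort_values(
        by=["n_significant", "max_abs_fit"], ascending=[False, False]
    )
    # deterministic tie-break on the id
    out["_id"] = out.index
    out = out.sort_values(
        by=["n_significant", "max_abs_fit", "_id"], ascending=[False, False, True]
    ).drop(columns="_id")
    return out


@dataclass
class BindingFit:
    bmax: float
    kd: float
    rss: float

    def __post_init__(self) -> None:
        if not (self.bmax > 0 and self.kd > 0):
            raise ValueError("binding fit requires bmax > 0 and kd > 0")


def _one_site(x: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    return bmax * x / (kd + x)


def fit_binding_curve(
    x: np.ndarray, y: np.ndarray, start: tuple[float, float] | None = None
) -> BindingFit:
    """Least-squares fit of the one-site binding hyperbola
    Y = Bmax * X / (Kd + X).

    The default start is Bmax = max(y) and Kd = the x at half-max by linear
    interpolation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x[x > 0])) < 3:
        raise ValueError("need >= 3 distinct positive concentrations")
    if np.allclose(y, 0):
        raise ValueError("no binding signal: response is all zero")
    if start is None:
        bmax0 = float(y.max())
        half = bmax0 / 2
        order = np.argsort(x)
        kd0 = float(np.interp(half, y[order], x[order]))
        if not np.isfinite(kd0) or kd0 <= 0:
            kd0 = float(np.median(x[x > 0]))
        start = (bmax0, kd0)
    try:
        popt, _ = curve_fit(
            _one_site, x, y, p0=start, bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"binding-curve fit did not converge: {exc}") from exc
    resid = y - _one_site(x, *popt)
    return BindingFit(bmax=float(popt[0]), kd=float(popt[1]), rss=float(resid @ resid))
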