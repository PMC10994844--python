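"""Count normalization, expressed-gene filtering, a negative-binomial
differential-expression test, and preranked gene-set enrichment.

The DE engine is a deliberately simple stand-in for a full tagwise GLM
framework: a two-group exact-style conditional test under a negative
binomial with a single common dispersion, estimated by method of moments
from the within-condition replicate scatter. Counts are first rescaled to a
common library size. Externally computed DE tables can be fed to the
downstream thresholding and ranking operations unchanged.

Enrichment uses the weighted Kolmogorov–Smirnov-style running sum over a
preranked gene list (weight = |score|), with a gene-label permutation null
and Benjamini–Hochberg correction across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import ExpressionMatrix

CPM_THRESHOLD = 0.6635
LFC_CUT = 2.0
FDR_CUT = 0.05


def cpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Counts per million reads, using the matrix's library sizes."""
    return matrix.cpm()


def filter_expressed(
    matrix: ExpressionMatrix,
    cpm_threshold: float = CPM_THRESHOLD,
    scheme: str = "any_condition",
) -> list[str]:
    """Genes with CPM above threshold in all replicates of at least one
    condition (``any_condition``) or in every sample (``all_samples``)."""
    values = matrix.cpm()
    if scheme == "all_samples":
        keep = (values > cpm_threshold).all(axis=1)
    elif scheme == "any_condition":
        keep = pd.Series(False, index=values.index)
        for cond in matrix.conditions:
            cols = matrix.samples_of(cond)
            keep |= (values[cols] > cpm_threshold).all(axis=1)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return list(values.index[keep])


@dataclass
class DEResult:
    table: pd.DataFrame  # index gene; columns log2fc, pvalue, fdr
    test_condition: str
    control_condition: str
    dispersion: float


def estimate_common_dispersion(matrix: ExpressionMatrix) -> float:
    """Method-of-moments common NB dispersion from within-condition scatter.

    Counts are rescaled to the mean library size; for each gene x condition
    cell with >= 2 replicates, E[s^2 - m] = phi * mu^2 and mu^2 is estimated
    by m^2 - s^2/n, pooled across cells by a regression through the origin.
    """
    ref = np.mean(list(matrix.library_sizes.values()))
    scaled = matrix.counts.astype(float) * (
        ref / pd.Series(matrix.library_sizes)[matrix.counts.columns]
    )
    num = 0.0
    den = 0.0
    for cond in matrix.conditions:
        cols = matrix.samples_of(cond)
        if len(cols) < 2:
            continue
        sub = scaled[cols].to_numpy()
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        mu2 = np.maximum(m**2 - v / len(cols), 0.0)
        num += float((v - m).sum())
        den += float(mu2.sum())
    if den <= 0:
        return 0.0
    return max(num / den, 0.0)


def _exact_nb_pvalue(ya: float, yb: float, na: int, nb: int, phi: float) -> float:
    """Two-sided conditional test of equal means given the total count.

    Under H0 the group sums are NB with sizes na/phi and nb/phi and shared
    per-replicate mean; the conditional distribution of the group-A sum
    given the total is evaluated exactly and the p-value is the summed
    probability of outcomes no more likely than the observed one.
    """
    t = int(round(ya + yb))
    if t == 0:
        return 1.0
    y = np.arange(t + 1)
    if phi < 1e-12:
        logp = stats.binom.logpmf(y, t, na / (na + nb))
    else:
        mu = t / (na + nb)  # per-replicate mean under H0
        ra, rb = na / phi, nb / phi
        la = stats.nbinom.logpmf(y, ra, ra / (ra + na * mu))
        lb = stats.nbinom.logpmf(t - y, rb, rb / (rb + nb * mu))
        logp = la + lb
    logp -= _lse(logp)
    p_obs = logp[int(round(ya))]
    mask = logp <= p_obs + 1e-10
    return float(np.exp(_lse(logp[mask])))


def _lse(x: np.ndarray) -> float:
    m = np.max(x)
    return float(m + np.log(np.exp(x - m).sum()))


def nb_de_test(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str],
    dispersion: float | None = None,
    pseudocount: float = 0.5,
) -> DEResult:
    """Two-group NB test of ``contrast = (test, control)``.

    log2 fold changes come from mean CPM with a pseudocount; p-values from
    the exact-style conditional NB test with a common dispersion; FDR by
    Benjamini–Hochberg.
    """
    test_cond, control_cond = contrast
    cols_a = matrix.samples_of(test_cond)
    cols_b = matrix.samples_of(control_cond)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each contrast group needs >= 2 replicates")
    if (matrix.counts[cols_a].to_numpy().sum() == 0) or (
        matrix.counts[cols_b].to_numpy().sum() == 0
    ):
        raise ValueError("a contrast group has all-zero counts")
    if dispersion is None:
        dispersion = estimate_common_dispersion(matrix)

    ref = np.mean([matrix.library_sizes[s] for s in cols_a + cols_b])
    scale = {s: ref / matrix.library_sizes[s] for s in cols_a + cols_b}
    a = np.rint(
        matrix.counts[cols_a].to_numpy(float) * [scale[s] for s in cols_a]
    )
    b = np.rint(
        matrix.counts[cols_b].to_numpy(float) * [scale[s] for s in cols_b]
    )
    ya, yb = a.sum(axis=1), b.sum(axis=1)
    pvals = np.array(
        [_exact_nb_pvalue(ya[i], yb[i], len(cols_a), len(cols_b), dispersion)
         for i in range(len(ya))]
    )
    cpm_all = matrix.cpm()
    mean_a = cpm_all[cols_a].mean(axis=1).to_numpy()
    mean_b = cpm_all[cols_b].mean(axis=1).to_numpy()
    log2fc = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)
    fdr = multipletests(np.clip(pvals, 0, 1), method="fdr_bh")[1]
    table = pd.DataFrame(
        {"log2fc": log2fc, "pvalue": np.clip(pvals, 0, 1), "fdr": fdr},
        index=matrix.counts.index,
    )
    return DEResult(
        table=table,
        test_condition=test_cond,
        control_condition=control_cond,
        dispersion=float(dispersion),
    )


def significant_de(
    de: DEResult | pd.DataFrame, lfc_cut: float = LFC_CUT, fdr_cut: float = FDR_CUT
) -> pd.Series:
    """Call each gene up / down / neither at the study thresholds."""
    table = de.table if isinstance(de, DEResult) else de
    calls = pd.Series("neither", index=table.index)
    calls[(table["log2fc"] > lfc_cut) & (table["fdr"] < fdr_cut)] = "up"
    calls[(table["log2fc"] < -lfc_cut) & (table["fdr"] < fdr_cut)] = "down"
    return calls


def rank_metric(de: DEResult | pd.DataFrame) -> pd.Series:
    """-log10(p) x sign(log2FC), descending; ties broken by gene id."""
    table = de.table if isinstance(de, DEResult) else de
    p = table["pvalue"].to_numpy(float)
    floored = p <= 0
    p = np.where(floored, np.finfo(float).tiny, p)
    score = -np.log10(p) * np.sign(table["log2fc"].to_numpy(float))
    s = pd.Series(score, index=table.index)
    s = s.iloc[np.lexsort((s.index, -s.to_numpy()))]
    s.attrs["pvalue_floored"] = bool(floored.any())
    return s


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # index set; columns es, pvalue, fdr, size
    n_perm: int


def enrichment_score(scores: np.ndarray, member_mask: np.ndarray) -> float:
    """Weighted KS-style running-sum enrichment score, in [-1, 1]."""
    w = np.abs(scores)
    hit = w * member_mask
    hit_total = hit.sum()
    n_miss = (~member_mask).sum()
    if hit_total == 0 or n_miss == 0:
        return 0.0
    p_hit = np.cumsum(hit) / hit_total
    p_miss = np.cumsum(~member_mask) / n_miss
    dev = p_hit - p_miss
    return float(dev[np.argmax(np.abs(dev))])


def preranked_gsea(
    ranking: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 10_000,
    min_size: int = 10,
    exempt_sets: list[str] | None = None,
    seed: int = 0,
) -> EnrichmentResult:
    """Preranked enrichment over ``gene_sets`` with a gene-label
    permutation null.

    Sets with fewer than ``min_size`` members present in the ranking are
    dropped unless named in ``exempt_sets``; members absent from the
    ranking are dropped with a note in the result table.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable permutation p")
    exempt = set(exempt_sets or [])
    rng = np.random.default_rng(seed)
    genes = list(ranking.index)
    pos = {g: i for i, g in enumerate(genes)}
    scores = ranking.to_numpy(float)
    n = len(genes)
    rows = []
    for name, members in gene_sets.items():
        present = [g for g in members if g in pos]
        dropped = len(members) - len(present)
        k = len(present)
        if k == 0 or (k < min_size and name not in exempt):
            continue
        mask = np.zeros(n, dtype=bool)
        mask[[pos[g] for g in present]] = True
        es = enrichment_score(scores, mask)
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = np.zeros(n, dtype=bool)
            perm[rng.choice(n, size=k, replace=False)] = True
            null[i] = enrichment_score(scores, perm)
        p = (1 + np.sum(np.abs(null) >= abs(es))) / (n_perm + 1)
        rows.append(
            {"set": name, "es": es, "pvalue": p, "size": k, "dropped_members": dropped}
        )
    table = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["es", "pvalue", "size", "dropped_members"]
    )
    if len(table):
        table["fdr"] = multipletests(table["pvalue"], method="fdr_bh")[1]
    else:
        table["fdr"] = []
    return EnrichmentResult(table=table, n_perm=n_perm)
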