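"""Association statistics between dnd systems and prophages.

Two complementary views, mirroring how comparative analyses of gene-content
co-occurrence are usually run:

* **across taxa** — each genus (or species) contributes one point: the
  fraction of its genomes carrying a feature. Prophage occurrence (x) is
  regressed against dnd occurrence (y) by ordinary least squares, with the
  Pearson coefficient and its two-sided p from the t distribution (n-2 df).
  The evidence bar for a *significant* negative association is
  R^2 > 0.5, p < 0.001 and r < -0.7.
* **within a taxon** — per-genome feature counts are ordinal, zero-inflated
  and heavily tied, so the association between prophage abundance and dnd
  abundance is measured with Kendall's tau-b (tie-corrected). The two-sided
  p-value is computed by exact enumeration over all permutations of one
  vector for n <= 10 and otherwise by the tie-corrected normal approximation
  with a continuity correction; significance is p < 0.05 with the sign of tau.

Taxa enter the analysis only when well sampled (>= 100 genomes per genus,
>= 30 per species by default) and when at least 30 of their genomes carry a
prophage or a dnd feature; a (taxon, feature) pair is "statistically
unachievable" when the taxon is too small or the feature is entirely absent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .dnd_detect import CLUSTER_FAMILIES, DND_FAMILIES, GenomeDndProfile, profiles_to_frame
from .genome_io import ValidationError

__all__ = [
    "CorrelationResult",
    "DegenerateInputError",
    "FEATURES",
    "occurrence_by_taxon",
    "across_taxon_association",
    "within_taxon_association",
    "eligibility_filter",
    "pair_unachievable",
    "students_t_test",
    "bh_fdr",
]

FEATURES = tuple(DND_FAMILIES) + tuple(CLUSTER_FAMILIES)


class DegenerateInputError(ValueError):
    """Statistic undefined on this input (e.g. zero variance, all ties)."""


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "ols_pearson" | "kendall_tau_b"
    statistic: float
    p_value: float
    n: int
    classification: str
    r_squared: float | None = None
    slope: float | None = None
    intercept: float | None = None


NOT_COMPUTABLE = "not_computable"


# ---------------------------------------------------------------------------
# occurrence tables
# ---------------------------------------------------------------------------


def occurrence_by_taxon(
    profiles: list[GenomeDndProfile] | pd.DataFrame,
    prophage_counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    rank: str = "genus",
    min_genomes: int = 100,
) -> pd.DataFrame:
    """Per-taxon occurrence fractions and mean abundances.

    One row per taxon with at least ``min_genomes`` genomes (inclusive).
    Columns ``occ_<feature>`` hold the fraction of genomes carrying >= 1 copy,
    ``mean_<feature>`` the mean per-genome count; ``prophage`` is included as a
    feature. Genomes without a value at ``rank`` are dropped.
    """
    if rank not in ("genus", "species"):
        raise ValueError("rank must be 'genus' or 'species'")
    if not isinstance(profiles, pd.DataFrame):
        profiles = profiles_to_frame(profiles)
    df = profiles.merge(
        prophage_counts[["genome_id", "n_prophages"]], on="genome_id", how="left"
    )
    df["n_prophages"] = df["n_prophages"].fillna(0).astype(int)
    df = df.merge(taxonomy[["genome_id", rank]], on="genome_id", how="left")
    df = df[df[rank].notna() & (df[rank].astype(str).str.len() > 0)]

    rows = []
    for taxon, grp in df.groupby(rank, sort=True):
        n = len(grp)
        if n < min_genomes:
            continue
        row: dict[str, object] = {"taxon": taxon, "rank": rank, "n_genomes": n}
        for feat in FEATURES:
            row[f"occ_{feat}"] = float((grp[f"n_{feat}"] >= 1).mean())
            row[f"mean_{feat}"] = float(grp[f"n_{feat}"].mean())
        row["occ_prophage"] = float((grp["n_prophages"] >= 1).mean())
        row["mean_prophage"] = float(grp["n_prophages"].mean())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# across-taxon OLS / Pearson
# ---------------------------------------------------------------------------


def across_taxon_association(x, y) -> CorrelationResult:
    """OLS of dnd occurrence (y) on prophage occurrence (x) plus Pearson r.

    Classification follows the stated evidence bar: ``significant_negative``
    when R^2 > 0.5, p < 0.001 and r < -0.7 (mirrored for the positive side);
    otherwise the sign of r. Zero variance in either vector makes the
    association not computable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("need n >= 3 finite points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            "ols_pearson", float("nan"), float("nan"), n, NOT_COMPUTABLE
        )
    fit = sps.linregress(x, y)
    r = float(fit.rvalue)
    r2 = r * r
    p = float(fit.pvalue)
    if r2 > 0.5 and p < 1e-3 and r < -0.7:
        cls = "significant_negative"
    elif r2 > 0.5 and p < 1e-3 and r > 0.7:
        cls = "significant_positive"
    elif r < 0:
        cls = "negative"
    elif r > 0:
        cls = "positive"
    else:
        cls = "zero"
    return CorrelationResult(
        "ols_pearson", r, p, n, cls,
        r_squared=r2, slope=float(fit.slope), intercept=float(fit.intercept),
    )


# ---------------------------------------------------------------------------
# within-taxon Kendall tau-b
# ---------------------------------------------------------------------------


def _tau_b_s_and_denominator(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Kendall S (= concordant - discordant) and the tau-b denominator."""
    n = len(x)
    n0 = n * (n - 1) / 2.0
    _, tx = np.unique(x, return_counts=True)
    _, ty = np.unique(y, return_counts=True)
    t1 = float(np.sum(tx * (tx - 1)) / 2.0)
    t2 = float(np.sum(ty * (ty - 1)) / 2.0)
    denom = np.sqrt((n0 - t1) * (n0 - t2))
    tau = sps.kendalltau(x, y, variant="b").statistic
    s = float(np.round(tau * denom))
    return s, denom


def _tie_corrected_var_s(x: np.ndarray, y: np.ndarray) -> float:
    """Variance of S under the null, corrected for ties (standard formula)."""
    n = len(x)
    _, tx = np.unique(x, return_counts=True)
    _, ty = np.unique(y, return_counts=True)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = np.sum(tx * (tx - 1) * (2 * tx + 5))
    vu = np.sum(ty * (ty - 1) * (2 * ty + 5))
    v1 = (
        np.sum(tx * (tx - 1)) * np.sum(ty * (ty - 1))
        / (2.0 * n * (n - 1))
    )
    v2 = (
        np.sum(tx * (tx - 1) * (tx - 2)) * np.sum(ty * (ty - 1) * (ty - 2))
        / (9.0 * n * (n - 1) * (n - 2))
        if n > 2
        else 0.0
    )
    return float((v0 - vt - vu) / 18.0 + v1 + v2)


def _exact_perm_p(x: np.ndarray, y: np.ndarray, s_obs: float) -> float:
    """Two-sided p by enumerating all permutations of y (n <= 10).

    Permuting y preserves its tie structure, so the tau-b denominator is
    constant and comparing |S| is equivalent to comparing |tau|.
    """
    n = len(x)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    yp = y[perms]  # (n!, n)
    s = np.zeros(len(perms))
    for i in range(n - 1):
        for j in range(i + 1, n):
            sx = np.sign(x[i] - x[j])
            if sx == 0:
                continue
            s += sx * np.sign(yp[:, i] - yp[:, j])
    return float(np.mean(np.abs(s) >= abs(s_obs) - 1e-9))


def within_taxon_association(abundance_x, abundance_y) -> CorrelationResult:
    """Kendall tau-b between two per-genome count vectors, with p-value.

    Exact permutation p for n <= 10; tie-corrected normal approximation with
    continuity correction otherwise. All-tied input in either vector makes the
    association not computable.
    """
    x = np.asarray(abundance_x, dtype=float)
    y = np.asarray(abundance_y, dtype=float)
    n = len(x)
    if n < 2 or len(y) != n:
        raise ValidationError("need two equal-length vectors with n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            "kendall_tau_b", float("nan"), float("nan"), n, NOT_COMPUTABLE
        )
    s, denom = _tau_b_s_and_denominator(x, y)
    tau = s / denom
    if n <= 10:
        p = _exact_perm_p(x, y, s)
    else:
        var_s = _tie_corrected_var_s(x, y)
        z = (abs(s) - 1.0) / np.sqrt(var_s) if var_s > 0 else 0.0
        z = max(z, 0.0)
        p = float(2.0 * sps.norm.sf(z))
    p = min(p, 1.0)
    if p < 0.05:
        cls = "significant_negative" if tau < 0 else "significant_positive"
    elif tau < 0:
        cls = "negative"
    elif tau > 0:
        cls = "positive"
    else:
        cls = "zero"
    return CorrelationResult("kendall_tau_b", float(tau), p, n, cls)


# ---------------------------------------------------------------------------
# inclusion filters
# ---------------------------------------------------------------------------


def eligibility_filter(carries_feature, min_carrying: int = 30) -> bool:
    """True when >= ``min_carrying`` genomes carry a prophage or dnd feature.

    ``carries_feature`` is one boolean per genome of the taxon (>= 1 prophage
    or >= 1 dnd gene/cluster).
    """
    return int(np.asarray(carries_feature, dtype=bool).sum()) >= min_carrying


def pair_unachievable(
    n_genomes: int,
    feature_counts,
    prophage_counts,
    min_genomes: int = 30,
) -> bool:
    """Whether a (taxon, feature) association is statistically unachievable.

    Mirrors the crossed-out cells of the within-taxon heatmap: too few genomes,
    or the feature (or prophage) entirely absent from the taxon.
    """
    if n_genomes < min_genomes:
        return True
    if int(np.sum(np.asarray(feature_counts) > 0)) == 0:
        return True
    if int(np.sum(np.asarray(prophage_counts) > 0)) == 0:
        return True
    return False


# ---------------------------------------------------------------------------
# generic tests
# ---------------------------------------------------------------------------


def students_t_test(a, b) -> tuple[float, int, float]:
    """Two-sided unpaired Student's t with pooled variance.

    Returns ``(t, df, p)`` with ``df = n_a + n_b - 2``. Zero pooled variance
    with equal means yields ``(0, df, 1)``; with unequal means the input is
    degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each sample needs n >= 2")
    df = len(a) + len(b) - 2
    pooled = ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)) / df
    if pooled == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, df, 1.0
        raise DegenerateInputError(
            "zero pooled variance with unequal means: t undefined"
        )
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), df, float(res.pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
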