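"""Survey statistics: conservation percentages, exact tests, positional and phase
bias batteries, clade enrichment and MIG comparisons.

Conventions: the two-sided Fisher test sums hypergeometric probabilities no larger
than the observed table's (log-space, stable for extreme tables); the two-tailed
binomial test uses the same minimum-likelihood definition; multiple testing is
corrected with Benjamini-Hochberg, and batteries report both corrected and
uncorrected outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, ParameterError


def conservation_percentage(n_cons: int, n_var: int) -> float:
    """100 * conserved / (conserved + variable)."""
    if n_cons < 0 or n_var < 0:
        raise ParameterError("counts must be non-negative")
    if n_cons + n_var == 0:
        raise ParameterError("at least one intron required")
    return 100.0 * n_cons / (n_cons + n_var)


_LOG_TIE_TOL = 1e-9     # log-space tolerance for pmf ties across the support


def hypergeom_support_logpmf(r1: int, c1: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Support of the (0,0) cell and its log-pmf for fixed 2x2 margins."""
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    return support, sps.hypergeom.logpmf(support, n, c1, r1)


def minlike_pvalues(logpmf: np.ndarray) -> np.ndarray:
    """Two-sided (minimum-likelihood) p for every point of a discrete support.

    p(a) = sum of pmf over all support points whose pmf does not exceed pmf(a)
    (ties included, with a small log-space tolerance).  Summation is done in log
    space relative to the largest retained term, so extreme tables stay finite.
    """
    order = np.argsort(logpmf, kind="mergesort")
    sorted_lp = logpmf[order]
    # cumulative sum of pmf in ascending-probability order, log-space stabilised
    ref = sorted_lp[-1]
    csum = np.cumsum(np.exp(sorted_lp - ref))
    # for each point, include everything with logpmf <= its own + tolerance
    idx = np.searchsorted(sorted_lp, logpmf + _LOG_TIE_TOL, side="right") - 1
    return np.minimum(1.0, csum[idx] * np.exp(ref))


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Exact hypergeometric p for a 2x2 table, summed in log space.

    Two-sided: sum of all tables (margins fixed) whose probability does not exceed
    the observed one (minimum-likelihood definition).  One-sided alternatives
    condition on the (0, 0) cell being large ('greater') or small ('less').
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ParameterError("table must be 2x2 with non-negative integer cells")
    if t.sum() == 0:
        raise ParameterError("all-zero table")
    a = t[0, 0]
    r1, c1, n = t[0].sum(), t[:, 0].sum(), t.sum()
    support, logpmf = hypergeom_support_logpmf(r1, c1, n)
    pos = int(np.searchsorted(support, a))
    if alternative == "two-sided":
        return float(minlike_pvalues(logpmf)[pos])
    obs = logpmf[pos]
    if alternative == "greater":
        keep = support >= a
    elif alternative == "less":
        keep = support <= a
    else:
        raise ParameterError(f"unknown alternative {alternative!r}")
    return float(min(1.0, np.exp(logpmf[keep] - obs).sum() * np.exp(obs)))


def binomial_two_tailed(k: int, n: int, p: float = 0.5) -> float:
    """Two-tailed exact binomial p (minimum-likelihood definition)."""
    if not 0 <= k <= n:
        raise ParameterError("k must be in 0..n")
    return float(sps.binomtest(k, n, p).pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, never below raw p)."""
    return sps.false_discovery_control(np.asarray(pvalues, dtype=float))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (rho, p); equals rank-Pearson on tie-free data."""
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# positional bias
# ---------------------------------------------------------------------------

@dataclass
class BiasTestResult:
    species: str
    n_5prime: int
    n_total: int
    p_binomial: float
    p_mwu: float
    median_minor: float
    median_major: float
    flagged_5prime_minor_bias: bool


def positional_bias_battery(
    minor_positions,
    major_positions,
    alpha: float = 0.05,
    species: str = "sp",
) -> BiasTestResult:
    """Three-part 5' bias test for one species.

    (a) two-tailed exact binomial on minor introns in the 5' half (position < 0.5),
    (b) two-tailed Mann-Whitney U between minor and major relative positions,
    (c) the minor median must be more 5' than the major median.  The species is
    flagged only when all three hold at ``alpha``.
    """
    minor = np.asarray(minor_positions, dtype=float)
    major = np.asarray(major_positions, dtype=float)
    if minor.size == 0 or major.size == 0:
        raise InsufficientDataError("both intron types need >= 1 position")
    if ((minor < 0) | (minor > 1)).any() or ((major < 0) | (major > 1)).any():
        raise ParameterError("relative positions must lie in [0, 1]")
    n5 = int((minor < 0.5).sum())
    p_binom = binomial_two_tailed(n5, minor.size, 0.5)
    method = "exact" if min(minor.size, major.size) <= 20 else "asymptotic"
    p_mwu = float(sps.mannwhitneyu(minor, major, alternative="two-sided",
                                   method=method).pvalue)
    med_minor, med_major = float(np.median(minor)), float(np.median(major))
    flagged = (p_binom < alpha) and (p_mwu < alpha) and (med_minor < med_major)
    return BiasTestResult(species, n5, int(minor.size), p_binom, p_mwu,
                          med_minor, med_major, flagged)


def positional_bias_batch(
    positions_by_species: dict[str, tuple],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Battery over species with BH correction of both component tests.

    Reports uncorrected flags and flags recomputed from BH-adjusted p-values.
    """
    results = [positional_bias_battery(minor, major, alpha, species=sp)
               for sp, (minor, major) in sorted(positions_by_species.items())]
    df = pd.DataFrame([r.__dict__ for r in results])
    df["q_binomial"] = bh_adjust(df["p_binomial"])
    df["q_mwu"] = bh_adjust(df["p_mwu"])
    df["flagged_corrected"] = (
        (df["q_binomial"] < alpha) & (df["q_mwu"] < alpha)
        & (df["median_minor"] < df["median_major"])
    )
    return df


def clade_enrichment(
    flags: pd.Series,
    clades: pd.Series,
    focal_clade: str,
) -> tuple[np.ndarray, float]:
    """2x2 enrichment of flagged species in a focal clade, with two-sided Fisher p.

    Table rows: focal clade / all other clades; columns: flagged / unflagged.
    """
    clades = np.asarray(pd.Series(clades), dtype=object)
    flags = np.asarray(pd.Series(flags), dtype=bool)
    if flags.shape != clades.shape:
        raise ParameterError("flags and clades must have one entry per species")
    if focal_clade not in set(clades):
        raise ParameterError(f"focal clade {focal_clade!r} absent from data")
    in_focal = clades == focal_clade
    table = np.array([
        [int((flags & in_focal).sum()), int((~flags & in_focal).sum())],
        [int((flags & ~in_focal).sum()), int((~flags & ~in_focal).sum())],
    ])
    return table, fisher_exact_2x2(table)


# ---------------------------------------------------------------------------
# phase distributions
# ---------------------------------------------------------------------------

def phase_distribution(phases) -> tuple[float, float, float]:
    """Proportions of phases 0/1/2."""
    arr = np.asarray(list(phases))
    if arr.size == 0:
        raise InsufficientDataError("empty intron set")
    if not set(np.unique(arr)) <= {0, 1, 2}:
        raise ParameterError("phases must be 0, 1 or 2")
    return tuple(float((arr == k).sum() / arr.size) for k in (0, 1, 2))


def compare_phase0(
    counts_a: tuple[int, int],
    counts_b: tuple[int, int],
) -> tuple[float, str]:
    """Phase-0 vs other-phase comparison between two species.

    ``counts_x`` = (n_phase0, n_other).  Uses Boschloo's exact unconditional test;
    falls back to Fisher (flagged in the returned method) if the unconditional test
    is degenerate for the table.
    """
    table = np.array([counts_a, counts_b])
    if (table.sum(axis=1) == 0).any():
        raise ParameterError("each species needs at least one intron")
    try:
        res = sps.boschloo_exact(table, alternative="two-sided")
        p = float(res.pvalue)
        if np.isnan(p):
            raise ValueError
        return min(1.0, p), "boschloo"
    except ValueError:
        return fisher_exact_2x2(table), "fisher_fallback"


# ---------------------------------------------------------------------------
# MIG vs non-MIG comparisons
# ---------------------------------------------------------------------------

def mig_comparisons(
    per_gene: pd.DataFrame,
    n_minor_by_species: dict[str, int],
    min_minor: int = 10,
    age_column: str | None = None,
) -> pd.DataFrame:
    """Minor intron-containing genes vs others: genic density and coding length.

    ``per_gene`` is tidy with columns species, gene_id, is_mig, genic_intron_density,
    coding_length.  Species with fewer than ``min_minor`` minor introns are excluded
    (guard against spurious minor calls).  With ``age_column`` set, comparisons run
    within each age category and BH correction is applied across all tests.
    """
    required = {"species", "is_mig", "genic_intron_density", "coding_length"}
    if not required <= set(per_gene.columns):
        raise ParameterError(f"per-gene table needs columns {sorted(required)}")
    rows = []
    group_cols = ["species"] + ([age_column] if age_column else [])
    for keys, g in per_gene.groupby(group_cols):
        keys = keys if isinstance(keys, tuple) else (keys,)
        sp = keys[0]
        if n_minor_by_species.get(sp, 0) < min_minor:
            continue
        mig = g[g["is_mig"].astype(bool)]
        non = g[~g["is_mig"].astype(bool)]
        if mig.empty or non.empty:
            continue
        row = {"species": sp}
        if age_column:
            row[age_column] = keys[1]
        for metric in ("genic_intron_density", "coding_length"):
            u = sps.mannwhitneyu(mig[metric], non[metric], alternative="two-sided")
            row[f"median_mig_{metric}"] = float(mig[metric].median())
            row[f"median_non_mig_{metric}"] = float(non[metric].median())
            row[f"p_{metric}"] = float(u.pvalue)
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        for metric in ("genic_intron_density", "coding_length"):
            df[f"q_{metric}"] = bh_adjust(df[f"p_{metric}"])
    return df
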