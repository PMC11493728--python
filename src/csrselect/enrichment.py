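"""Variant enrichment scores and the E-test for two Poisson means.

The enrichment score of a variant m is the natural log of its frequency
ratio across selection, ``E_m = ln(freq_m,r1 / freq_m,r0)``.  Significance
of the underlying count change is assessed with the unconditional E-test of
Krishnamoorthy & Thomson for comparing two Poisson means, treating the two
rounds' counts as Poisson observations with the callable read totals as
exposures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import VariantCountTable

ENRICHED = "enriched"
DEPLETED = "depleted"
NEUTRAL = "neutral"


def enrichment_score(
    c0: int, n0: int, c1: int, n1: int, zero_policy: str = "add_half"
) -> float:
    """E = ln((c1/n1) / (c0/n0)).

    With ``zero_policy="add_half"`` a pseudocount of 0.5 is added to *both*
    counts whenever either is zero (score only; tests always use raw
    counts).  Both counts zero -> NaN (undefined, flagged upstream).
    """
    if n0 <= 0 or n1 <= 0:
        raise ValueError("round totals must be positive")
    if c0 < 0 or c1 < 0:
        raise ValueError("counts must be non-negative")
    if c0 == 0 and c1 == 0:
        return float("nan")
    a0, a1 = float(c0), float(c1)
    if a0 == 0.0 or a1 == 0.0:
        if zero_policy == "add_half":
            a0 += 0.5
            a1 += 0.5
        elif zero_policy == "strict":
            return float("nan")
        else:
            raise ValueError(f"unknown zero_policy {zero_policy!r}")
    return math.log((a1 / n1) / (a0 / n0))


def calibrate_total_ratio(c0_ref: int, c1_ref: int, e_ref: float) -> float:
    """Recover the ln(N0/N1) offset from one reference record.

    Given a record with known counts and known enrichment (e.g. a published
    WT row), ``offset = E_ref - ln(c1_ref / c0_ref)``; the enrichment of any
    other variant in the same selection is then ``ln(c1/c0) + offset``,
    independent of whether rejected reads entered the published totals.
    """
    if c0_ref <= 0 or c1_ref <= 0:
        raise ValueError("reference counts must be positive")
    return e_ref - math.log(c1_ref / c0_ref)


def score_with_offset(c0: int, c1: int, offset: float) -> float:
    """Enrichment from raw counts plus a calibrated total-ratio offset."""
    if c0 <= 0 or c1 <= 0:
        raise ValueError("counts must be positive for offset scoring")
    return math.log(c1 / c0) + offset


def poisson_e_test(c0: int, t0: float, c1: int, t1: float) -> float:
    """Two-sided E-test p-value for H0: the two Poisson rates are equal.

    The statistic is ``T = (c1/t1 - c0/t0) / sqrt(lam*(1/t0 + 1/t1))`` with
    pooled ``lam = (c0+c1)/(t0+t1)``.  The p-value sums the joint Poisson
    probability (rates ``lam*t0``, ``lam*t1``) of every outcome pair whose
    |T| is at least the observed |T|; each marginal sum is truncated at
    mean +/- max(10*sqrt(mean), 50), leaving omitted tail mass below 1e-8.
    """
    if t0 <= 0 or t1 <= 0:
        raise ValueError("exposures must be positive")
    if c0 < 0 or c1 < 0:
        raise ValueError("counts must be non-negative")
    lam = (c0 + c1) / (t0 + t1)
    if lam == 0.0:
        return 1.0
    denom = math.sqrt(lam * (1.0 / t0 + 1.0 / t1))
    t_obs = abs((c1 / t1 - c0 / t0) / denom)

    def support(mean: float) -> np.ndarray:
        half = max(10.0 * math.sqrt(mean), 50.0)
        lo = max(0, int(math.floor(mean - half)))
        hi = int(math.ceil(mean + half))
        return np.arange(lo, hi + 1)

    m0, m1 = lam * t0, lam * t1
    y0 = support(m0)
    y1 = support(m1)
    p0 = stats.poisson.pmf(y0, m0)
    p1 = stats.poisson.pmf(y1, m1)
    t_grid = np.abs(
        (y1[None, :] / t1 - y0[:, None] / t0) / denom
    )
    mask = t_grid >= t_obs - 1e-12
    p = float(p0 @ mask @ p1)
    # the observed pair itself can fall outside the truncated grid when the
    # two rates are wildly different; its own probability is a lower bound
    p_obs = float(stats.poisson.pmf(c0, m0) * stats.poisson.pmf(c1, m1))
    return min(1.0, max(p, p_obs, 1e-300))


@dataclass(frozen=True)
class EnrichmentRecord:
    genotype: str
    count_r0: int
    count_r1: int
    freq_r0: float
    freq_r1: float
    E: float
    p_value: float
    klass: str


def classify_variants(
    table: VariantCountTable,
    alpha: float = 0.05,
    bh: bool = False,
    min_post_count: int | None = None,
) -> pd.DataFrame:
    """Score and classify every variant as enriched / depleted / neutral.

    Enriched: p < alpha and E > 0; depleted: p < alpha and E < 0; else
    neutral.  No multiple-testing correction by default; ``bh=True`` applies
    Benjamini-Hochberg to the p-values before thresholding.
    ``min_post_count`` is a reporting filter only (drops variants at or
    below the given post-selection count after classification).  Variants
    with zero counts in both rounds are dropped.  Records are sorted by E
    descending, ties broken by post-selection count then label.
    """
    df = table.df
    keep = (df["count_r0"] > 0) | (df["count_r1"] > 0)
    df = df.loc[keep]
    n0, n1 = table.n_r0, table.n_r1
    scores = [
        enrichment_score(int(r.count_r0), n0, int(r.count_r1), n1)
        for r in df.itertuples()
    ]
    pvals = np.array(
        [
            poisson_e_test(int(r.count_r0), n0, int(r.count_r1), n1)
            for r in df.itertuples()
        ]
    )
    p_adj = stats.false_discovery_control(pvals, method="bh") if bh else pvals
    out = df.copy()
    out["E"] = scores
    out["p"] = p_adj
    out["class"] = NEUTRAL
    out.loc[(out["p"] < alpha) & (out["E"] > 0), "class"] = ENRICHED
    out.loc[(out["p"] < alpha) & (out["E"] < 0), "class"] = DEPLETED
    out = out.reset_index().sort_values(
        by=["E", "count_r1", "genotype_label"],
        ascending=[False, False, True],
        kind="mergesort",
    ).set_index("genotype_label")
    if min_post_count is not None:
        out = out.loc[out["count_r1"] > min_post_count]
    return out


def enriched_set(classified: pd.DataFrame) -> set[str]:
    return set(classified.index[classified["class"] == ENRICHED])
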