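"""Sequencing-coverage subsampling analysis.

Coverage C is the number of sequencing reads divided by the theoretical
protein library size (stop-excluded variant count).  Random read subsets at
a grid of (pre, post) coverage pairs are drawn with replacement for N
trials; the enrichment analysis is re-run on each pair of subsets, and the
per-mutant detection probability P(E_m, C) = (detections over N trials)/N
summarizes how reliably a significantly enriched mutant is recovered.
Against the full-coverage "truth" set this yields true/false-positive
probabilities and precision = TP / (TP + FP).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enrichment import classify_variants, enriched_set
from .genotypes import build_count_table


def reads_for_coverage(library_size: int | float, coverage: float) -> int:
    """Read count needed for a coverage level: ceil(C * library size)."""
    if library_size <= 0 or coverage <= 0:
        raise ValueError("library size and coverage must be positive")
    return int(math.ceil(coverage * library_size))


def subsample_reads(
    reads: Sequence,
    coverage: float,
    library_size: int,
    rng: int | np.random.Generator = 0,
    replace: bool = True,
) -> list:
    """Draw ceil(C * library_size) reads, with replacement by default.

    ``reads`` may be raw sequences or per-read genotype labels; genotype
    calling is deterministic per read, so sampling pre-called labels is
    equivalent to re-calling a sampled read set.
    """
    if len(reads) == 0:
        raise ValueError("empty read set")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = reads_for_coverage(library_size, coverage)
    if not replace and n > len(reads):
        raise ValueError("cannot draw more reads than available without replacement")
    idx = rng.choice(len(reads), size=n, replace=replace)
    return [reads[i] for i in idx]


def detection_trials(
    labels_r0: Sequence[str | None],
    labels_r1: Sequence[str | None],
    coverage_pairs: Iterable[tuple[float, float]],
    truth_set: set[str],
    library_size: int,
    n_trials: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    replace: bool = True,
) -> pd.DataFrame:
    """Run the enrichment analysis on subsampled read pairs.

    ``labels_r0``/``labels_r1`` are per-read genotype labels (``None`` for
    uncallable reads).  Per-trial seeds are spawned from the master seed
    with a counter, so trials are independent and the whole grid is
    reproducible.  Returns one row per (pair, trial, detected genotype).
    """
    pairs = list(coverage_pairs)
    streams = np.random.SeedSequence(seed).spawn(len(pairs) * n_trials)
    rows = []
    stream = iter(streams)
    for c0, c1 in pairs:
        for trial in range(n_trials):
            rng = np.random.default_rng(next(stream))
            try:
                sub0 = subsample_reads(labels_r0, c0, library_size, rng, replace)
                sub1 = subsample_reads(labels_r1, c1, library_size, rng, replace)
                table = build_count_table(sub0, sub1)
                detected = enriched_set(classify_variants(table, alpha=alpha))
            except ValueError as err:
                raise ValueError(
                    f"trial {trial} at coverage ({c0}, {c1}) failed: {err}"
                ) from err
            for genotype in sorted(detected):
                rows.append((c0, c1, trial, genotype))
    df = pd.DataFrame(rows, columns=["c_r0", "c_r1", "trial", "genotype"])
    df["detected"] = 1
    df.attrs["n_trials"] = n_trials
    df.attrs["truth_set"] = set(truth_set)
    return df


def detection_probability(trials: pd.DataFrame) -> pd.DataFrame:
    """P(E_m, C) per mutant per coverage pair: detections / N."""
    n_trials = trials.attrs["n_trials"]
    truth = trials.attrs["truth_set"]
    pairs = (
        trials[["c_r0", "c_r1"]].drop_duplicates().itertuples(index=False)
        if len(trials)
        else []
    )
    rows = []
    for c0, c1 in pairs:
        sub = trials[(trials["c_r0"] == c0) & (trials["c_r1"] == c1)]
        counts = sub.groupby("genotype")["trial"].nunique()
        genotypes = sorted(truth | set(counts.index))
        for g in genotypes:
            rows.append((c0, c1, g, counts.get(g, 0) / n_trials, g in truth))
    return pd.DataFrame(
        rows, columns=["c_r0", "c_r1", "genotype", "P", "in_truth_set"]
    )


def precision_summary(prob: pd.DataFrame) -> pd.DataFrame:
    """TP/FP probabilities and precision per coverage pair.

    TP is the mean detection probability over truth-set mutants; FP the
    mean over non-truth mutants that were ever detected (0 if none).
    Precision is TP/(TP+FP), NaN (flagged) when both are zero.
    """
    rows = []
    for (c0, c1), sub in prob.groupby(["c_r0", "c_r1"], sort=True):
        tp_probs = sub.loc[sub["in_truth_set"], "P"]
        fp_probs = sub.loc[~sub["in_truth_set"] & (sub["P"] > 0), "P"]
        tp = float(tp_probs.mean()) if len(tp_probs) else 0.0
        fp = float(fp_probs.mean()) if len(fp_probs) else 0.0
        precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
        rows.append((c0, c1, tp, fp, precision))
    return pd.DataFrame(rows, columns=["c_r0", "c_r1", "TP", "FP", "precision"])
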