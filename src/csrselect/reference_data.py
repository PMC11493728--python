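"""Published KOD DNAP CSR selection summary data used as worked examples.

Two small tables from a published KOD DNA polymerase directed-evolution
campaign (2-point and 5-point saturation libraries at the L403/D404 active
site) are bundled as plain data:

* per-mutant read counts and enrichment scores for the three positive
  selections of the 5-point-library design ("D4", selections 4, 8, 20),
  used to demonstrate the calibrated total-ratio reconstruction of
  enrichment scores from counts alone; and
* library-level per-base error rates for the five successful selections of
  the 2-point-library design ("D1"), used to check the baseline-corrected
  error-rate arithmetic.

These are inputs for validation and worked examples, not test fixtures
generated by this package.
"""

from __future__ import annotations

#: Per-mutant counts: label -> (R0 count, {selection: post count}).
#: Counts are reads observed pre-selection (R0) and in each positive
#: selection of the 5-point-library design.
D4_COUNTS: dict[str, tuple[int, dict[str, int]]] = {
    "L-403-P; R-406-S": (1, {"sel4": 102_137, "sel8": 43, "sel20": 10}),
    "L-403-A; D-404-K": (1, {"sel4": 78_143, "sel8": 7, "sel20": 3}),
    "L-403-A; D-404-A": (1, {"sel4": 51_782, "sel8": 25, "sel20": 2}),
    "L-403-V; D-404-S": (2, {"sel4": 85_927, "sel8": 11, "sel20": 7}),
    "L-403-H": (2, {"sel4": 53_781, "sel8": 18, "sel20": 7}),
    "R-406-K": (1, {"sel4": 25_461, "sel8": 8, "sel20": 75}),
    "L-403-F": (16, {"sel4": 73_651, "sel8": 241_875, "sel20": 25}),
    "L-403-T": (25, {"sel4": 44_223, "sel8": 414_115, "sel20": 12}),
    "WT": (2_584, {"sel4": 51_615, "sel8": 2_391, "sel20": 510_249}),
    "Y-409-S": (14, {"sel4": 95, "sel8": 8, "sel20": 1_213}),
}

#: Published enrichment scores corresponding to D4_COUNTS (2 d.p.).
D4_ENRICHMENT: dict[str, dict[str, float]] = {
    "L-403-P; R-406-S": {"sel4": 12.42, "sel8": 4.50, "sel20": 3.21},
    "L-403-A; D-404-K": {"sel4": 12.15, "sel8": 2.69, "sel20": 2.00},
    "L-403-A; D-404-A": {"sel4": 11.74, "sel8": 3.96, "sel20": 1.60},
    "L-403-V; D-404-S": {"sel4": 11.55, "sel8": 2.44, "sel20": 2.16},
    "L-403-H": {"sel4": 11.09, "sel8": 2.94, "sel20": 2.16},
    "R-406-K": {"sel4": 11.03, "sel8": 2.82, "sel20": 5.22},
    "L-403-F": {"sel4": 9.32, "sel8": 10.36, "sel20": 1.35},
    "L-403-T": {"sel4": 8.36, "sel8": 10.45, "sel20": 0.17},
    "WT": {"sel4": 3.88, "sel8": 0.66, "sel20": 6.19},
    "Y-409-S": {"sel4": 2.80, "sel8": 0.18, "sel20": 5.37},
}

#: Library-level error rates (errors/bp) for the 2-point-library design:
#: selection -> (total bases, deletion, insertion, substitution, total,
#: published corrected total, published fold, frameshift frequency).
D1_ERROR_RATES: dict[str, dict[str, float]] = {
    "R0": dict(total_bases=9.21e7, rate_del=2.20e-4, rate_ins=9.69e-6,
               rate_sub=5.60e-4, total=7.89e-4, corrected=0.0, fold=1,
               frameshift_freq=5.42e-3),
    "sel2": dict(total_bases=2.21e7, rate_del=5.78e-4, rate_ins=1.41e-4,
                 rate_sub=1.15e-2, total=1.23e-2, corrected=1.15e-2, fold=16,
                 frameshift_freq=7.33e-3),
    "sel5": dict(total_bases=1.22e7, rate_del=3.66e-4, rate_ins=8.62e-5,
                 rate_sub=7.71e-3, total=8.16e-3, corrected=7.37e-3, fold=10,
                 frameshift_freq=6.61e-3),
    "sel7": dict(total_bases=1.15e7, rate_del=3.45e-4, rate_ins=9.95e-5,
                 rate_sub=8.79e-3, total=9.23e-3, corrected=8.44e-3, fold=12,
                 frameshift_freq=7.07e-3),
    "sel8": dict(total_bases=1.74e7, rate_del=3.70e-4, rate_ins=7.80e-5,
                 rate_sub=9.76e-3, total=1.02e-2, corrected=9.41e-3, fold=13,
                 frameshift_freq=7.85e-3),
    "sel11": dict(total_bases=2.66e7, rate_del=4.27e-4, rate_ins=7.65e-5,
                  rate_sub=7.98e-3, total=8.48e-3, corrected=7.69e-3, fold=11,
                  frameshift_freq=7.78e-3),
}

#: Theoretical protein library sizes (stop-codon variants excluded).
TWO_POINT_LIBRARY_SIZE = 400
FIVE_POINT_LIBRARY_SIZE = 3_200_000
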