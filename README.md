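# csrselect

Selection-output analysis for directed polymerase evolution.

In compartmentalized self-replication (CSR) selections, each polymerase
variant amplifies its own encoding gene inside an emulsion compartment, so
a variant's activity maps to its copy number. Sequencing the library before
(r0) and after (r1) selection turns the screen into counts, and the
questions a selection campaign actually has to answer become statistical
ones: *which variants enriched significantly, what did selection conditions
do to polymerase fidelity, how much sequencing coverage is enough, and
which reaction factors drive selection yield?* This package implements that
analysis pipeline for amplicon-sequenced saturation-mutagenesis libraries
(e.g. the KOD DNA polymerase L403/D404 active-site libraries it was
developed around), together with a synthetic CSR-selection generator so
every stage is testable end to end without external data.

Intended users: protein engineers and sequencing bioinformaticians running
targeted directed-evolution screens.

## The statistics at the core

**Enrichment.** For mutant *m* with counts c_{m,r} out of N_r callable
reads per round, the enrichment score is the log frequency ratio

    E_m = ln( Freq_{m,r1} / Freq_{m,r0} ),   Freq_{m,r} = c_{m,r} / N_r

Significance of the count change is assessed with the unconditional E-test
for two Poisson means (Krishnamoorthy–Thomson): with pooled rate
λ̂ = (c0+c1)/(t0+t1) and statistic

    T = (c1/t1 − c0/t0) / sqrt( λ̂ (1/t0 + 1/t1) )

the two-sided p-value sums the joint Poisson probability of every outcome
pair at least as extreme as the observed |T|. Variants are *enriched*
(p < α, E > 0), *depleted* (p < α, E < 0) or *neutral*.

**Fidelity.** Reads are globally aligned to the reference amplicon (match
+1, mismatch −1, gap open −2, gap extend −1) and errors tallied by type per
aligned base. Frameshifted reads are counted in the frameshift frequency
but excluded from rate aggregation; selection error rates are corrected by
subtracting the pre-selection baseline, and the fold change is the ratio of
raw totals. Per-mutant rates exclude the targeted codons (a variant's
defining codons are not errors).

**Coverage.** Coverage C = reads / theoretical protein library size
(stop-excluded; 400 for a 2-site NNK library, 3.2×10⁶ for 5 sites).
Random read subsets at a grid of (C_r0, C_r1) pairs are drawn with
replacement for N trials; the per-mutant detection probability is
P(E_m, C) = Σ_i D_{m,Ci} / N against the full-coverage truth set, and
precision = TP / (TP + FP) over mean true/false-positive probabilities.

**Factor importance.** Selection-yield responses are background-corrected
against negative controls, min–max scaled to 0–100 %, and regressed on the
(optionally interaction/quadratic-expanded) design with the Lasso; λ is
chosen by cross-validation and the whole fit repeated 100 times with
reshuffled folds. Mean (absolute) coefficients rank the factors.

## Worked example

The analysis is organised as numbered drivers over the library in
`src/csrselect/`:

```
python analysis/01_simulate_selection.py --seed 1     # reads + truth
python analysis/02_count_genotypes.py                 # genotype counts
python analysis/03_score_enrichment.py                # E_m, E-test, classes
python analysis/04_profile_fidelity.py                # error spectra
python analysis/05_coverage_subsampling.py            # P(E_m, C), precision
python analysis/06_doe_importance.py                  # CV-Lasso factor ranks
```

With the default 20,000 reads/round this prints (abridged):

```
winners' expected share of the post-selection pool: 63.1%
r0: 20,000 reads, 19,971 callable (99.9%)
400 variants scored; 10 enriched, 367 depleted at alpha = 0.05
winners recovered: 10/10; false positives: 0
r0 baseline: total 8.02e-04 errors/bp ...
r1 selection: total 8.10e-03 errors/bp, corrected 7.30e-03 (10x baseline)
r1 transition rate 5.12e-03, transversion rate 2.56e-03 (ratio 2.00)
balanced grids: TP probability rises with coverage (0.13 at 0.1x -> 1.00 at 20.0x)
top factors by mean |coefficient|: ntp_mM +24.87, mg_mM +15.52, mn_mM -9.80
```

That is the whole story in miniature: the ten designated winners are
recovered with no false positives; the post-selection error rate sits ~10×
above the sequencing baseline with the configured 2:1 transition bias; the
probability of detecting a truly enriched mutant saturates by a few-fold
coverage while precision stays near 1 on balanced grids; and the factor
screen ranks the three generating effects first with the right signs.

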