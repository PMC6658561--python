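# stressprofiler

Tools for phenotyping stress-susceptible animals by **cutoff-based extreme
behavior criteria**, and for the statistics that surround that
classification in a prenatal-stress / trauma-susceptibility study design:
contingency analysis of PTSD-like prevalence, variance-partitioning ANOVA
of a glucocorticoid-pathway expression panel, qPCR quantification,
methylation–expression coupling, and a CpG-filtered glucocorticoid
response element (GRE) promoter scan.

## Who this is for

Behavioral neuroscientists and biostatisticians working with rodent
trauma models (e.g. stress-enhanced fear learning) who subcategorize
animals into *PTSD-like* vs *resilient* subpopulations, and need the
entire downstream analysis to be scriptable, auditable and testable
without access to the original raw data. A synthetic-cohort module
generates cohorts with the statistical structure the analyses assume, so
every procedure can be validated end-to-end.

## The classifier

For each test *t* in a battery of *m* tests (default *m* = 5: risk
assessment time, startle peak latency, % pre-pulse inhibition — extreme
when **low**; dark-phase home-cage activity, % marbles buried — extreme
when **high**), the cutoff is the nearest-rank empirical quantile of the
reference cohort at tail fraction *q* (default 0.20):

    c_t = x_(⌈qn⌉)   (low direction; mirrored for high)

An animal is flagged extreme on test *t* when its value falls in the
boundary-inclusive tail (x ≤ c_t or x ≥ c_t), scored

    S_i = #{ t : flagged }          (0 ≤ S_i ≤ m)

and labeled **PTSD-like** iff S_i ≥ k (default k = 3 of 5). Under
independent continuous tests the null prevalence is the Binomial(5, 0.2)
tail at k ≥ 3, ≈ 5.79%; correlated extremes (a shared susceptibility
factor) push it above that.

Group-wise prevalence is compared by the Yates continuity-corrected
chi-square on the 2×2 group × label table,

    χ²_c = Σ (|O−E| − ½)₊² / E ,   φ = √(χ²_uncorrected / N),

with φ deliberately computed from the *uncorrected* statistic (the
convention that matches published effect sizes reported alongside
corrected test statistics).

Also included: tie-corrected Kruskal–Wallis with Dunn–Bonferroni
post-hocs, Type III two-way ANOVA with η² variance partitioning, a
split-plot three-way ANOVA (2×2 between-subject × one repeated
within-subject factor), a Shapiro–Wilk/Levene-gated two-group dispatcher,
the permutation-of-regressor-residuals association test, 2^−ΔΔCt qPCR
quantification with dual-reference knockdown efficiency, a 1–5
infection-area rubric, and an IUPAC-consensus GRE scanner with CpG
filtering and TSS-relative coordinates.

## Worked example

```sh
$ stressprofiler simulate --seed 7 --out cohort.csv
wrote 97 rows to cohort.csv
$ stressprofiler classify cohort.csv --out labels.csv
18/97 animals PTSD-like; wrote labels.csv
PNS: 15/54  control: 3/43  chi2(Yates)=5.546 p=0.019 phi=0.266
```

The simulated cohort carries a 2×2 design (prenatal stress × adult
trauma). `classify` computes the five pooled 20% cutoffs, flags extremes,
applies the 3-of-5 rule, and prints the per-group prevalence with the
corrected chi-square: here 15 of 54 prenatally stressed animals are
PTSD-like versus 3 of 43 controls (χ²(1) = 5.546, p = 0.019, φ = 0.266),
i.e. prenatal stress raised susceptibility.

From Python, the published contingency table is reproduced exactly:

```python
>>> from stressprofiler import yates_chi_square, ContingencyTable2x2
>>> r = yates_chi_square(ContingencyTable2x2(3, 32, 12, 34))
>>> print(f"chi2={r.statistic_corrected:.3f} phi={r.phi:.3f}")
chi2=2.964 phi=0.223
```

Other subcommands: `stats` (gated two-group / Kruskal–Wallis reports),
`quant` (ΔΔCt fold changes), `grescan` (GRE scan on a promoter FASTA),
`run` (the full simulate → classify → stats → report pipeline; every
artifact is written with the seed and a config hash for provenance).

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch — cohort
simulation, classification, prevalence contingency statistics, per-gene
and split-plot ANOVA, methylation–expression coupling — under a given
seed and writes the results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The per-run report bundle lands in `scratch/acceptance_run/`
(`summary.json`, classification and ANOVA tables as CSV).
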