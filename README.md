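# sebyl

Sequencing-based estimation of yeast replicative lifespan (RLS) for pooled,
barcoded mutant collections.

In a pooled mother-enrichment screen, thousands of barcoded deletion strains
are biotin-labeled, aged together in liquid culture, and the original mother
cells are re-captured on streptavidin beads over several consecutive sorting
rounds. Barcode sequencing of the unsorted culture (USC) and of the young
(daughter) and old (mother) fractions of each round (S1Y–S4Y, S1O–S4O) tells
how each strain's abundance changes as the pool ages: long-lived mutants are
enriched among old mothers, short-lived mutants are depleted. `sebyl` turns
those barcode counts into per-strain survival curves, fits a lifespan model,
scores every strain, and tests it against a wild-type reference. It is
written for groups running (or re-analysing) such screens and for anyone who
wants to study the statistical behaviour of the method itself through the
bundled forward simulator.

## Model

Survival of strain *i* at sorting round *n* follows the recurrence

    S_n = S_{n-1} · (Fo_n · To_n) / (Fo_{n-1} · To_{n-1} · r_n),   S_0 = 1

where `Fo` is the strain's fraction of the mother pool (from barcode
counts), `To` the microscope-counted mother-pool total, and `r_n` the
bead recovery rate. The generations grown in round *n* come from the
daughter pool:

    G_n = log2(Fy_n / Fy_{n-1}) + log2(Ty_n / To_{n-1})

with the unsorted culture as the round-0 baseline. The (cumulative G, S)
points are fitted with the modified Gompertz model

    S(G) = a · e^{−b·c^G},   a = 1 (100%), b > 0, c > 1

by nonlinear least squares, and the **RLS score** is the median lifespan

    G_median = ln(ln 2 / b) / ln c ,

the generation count at which fitted survival crosses 50%. Each mutant is
compared with the wild-type reference through an extra-sum-of-squares F-test
(pooled versus separate fits), and strains more than one standard deviation
above/below the mean score are called long-/short-lived. A separate module
relates the screen's extremes (top/bottom 10% by score) to quantitative
cell-morphology traits with Mann–Whitney tests and Benjamini–Hochberg
correction.

## Worked example

Simulate a 60-strain pool (true median lifespans uniform on 15–40
generations, four sorting rounds, bead recovery 0.6, one million reads per
sample) and estimate lifespans from the simulated counts, using three
strains as the wild-type reference:

```sh
sebyl simulate --out-dir sim --seed 42 --n-strains 60 --depth 1000000 --n0 1e6
sebyl estimate --counts-up sim/counts_up.tsv --counts-dn sim/counts_dn.tsv \
    --meta sim/meta.tsv --wildtype strain0000,strain0001,strain0002 \
    --out results.tsv
```

Joining `results.tsv` with the simulator's truth table and sorting by score
gives (shortest, middle and longest lived shown):

```
            rls_score      b      c  p_value  q_value classification  true_median
strain_id
strain0054     14.345  0.033  1.237    0.000    0.000          short       15.188
strain0051     15.463  0.023  1.247    0.000    0.000          short       16.084
strain0016     22.382  0.008  1.222    0.460    0.929         normal       27.805
strain0029     41.980  0.003  1.138    0.378    0.906           long       38.898
strain0037     45.109  0.003  1.133    0.322    0.840           long       39.646

Spearman(estimate, truth) = 0.815 over 60 scored strains
```

`rls_score` is the fitted median lifespan in generations (mean over
replicates when several are supplied), `b`/`c` the Gompertz parameters of
the fit, `p_value`/`q_value` the F-test against the wild-type reference and
its Benjamini–Hochberg adjustment, and `classification` the ±1 SD call.
Short-lived strains deplete fast and are measured precisely; long-lived
strains barely die within four rounds, so their medians are extrapolations
with wider spread — the ranking is what the screen is designed to deliver.

Raw FASTQ can be decoded into count tables with `sebyl decode` (fuzzy
barcode matching, edit distance ≤ 3 by default, UPTAG and DNTAG counted
separately), and `sebyl morph` runs the morphology-trait association on a
results table plus a strain × trait TSV.

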