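# prrnet

Sex-stratified disproportionality analysis of spontaneous adverse-event
reports, with drug–gene network topology and gene-set over-representation
on the side. The motivating use case is the safety comparison of the two
approved alopecia drugs — oral finasteride versus topical minoxidil — in
FAERS/openFDA data, where the question is whether an adverse event (say,
erectile dysfunction among male patients, or induced abortion among female
patients) is reported disproportionately often for one drug.

## Who it is for

Pharmacovigilance and pharmacoepidemiology analysts who have openFDA-style
drug-event records (or want realistic synthetic ones) and need a tested,
reproducible pipeline from raw reports to publication-style comparison
tables, rather than a one-off notebook.

## The statistics

For adverse effect X reported by A₁ of A₀ cases exposed to the drug of
interest and by B₁ of B₀ comparator cases, the **proportional reporting
ratio** is

```
PRR_X = (A1/A0) / (B1/B0)
```

with the delta-method 95% confidence interval

```
exp( ln PRR_X ± 1.96 · sqrt(1/A1 + 1/B1 − 1/A0 − 1/B0) )
```

Significance is a two-tailed Fisher exact test; following the construction
used in the published comparison tables this package reproduces, each
drug's row of the 2×2 enters as (affected, total). Degenerate rows keep
table conventions: B₁ = 0 renders "N/A", A₁ = 0 renders "0.00", and the CI
is suppressed in both cases. Cohort gender composition is summarised as the
male/female odds ratio against a reference population (ORM-F). The network
side computes topological coefficients and pair-normalized betweenness
centrality of a drug-centered gene network and fits power laws y = a·xᵇ on
the log-log scale; enrichment is the hypergeometric upper tail P(X ≥ k)
with Benjamini–Hochberg adjustment.

## Worked example

```python
from prrnet import (ContingencyTable, prr, prr_ci, fisher_exact_two_tailed)

# erectile dysfunction: 1046/2076 finasteride vs 4/92 minoxidil male cases
t = ContingencyTable(a1=1046, a0=2076, b1=4, b0=92)
print(round(prr(t), 2))                     # 11.59
print(tuple(round(x, 2) for x in prr_ci(t)))  # (4.44, 30.25)
print(f"{fisher_exact_two_tailed(t):.3g}")  # 8.31e-12
```

The PRR of 11.59 (95% CI 4.44–30.25, p = 8.31×10⁻¹²) says erectile
dysfunction is reported about twelve times more frequently, per exposed
case, with finasteride than with minoxidil in this stratum — a strong
male-reproductive safety signal for finasteride.

The same numbers fall out of the full pipeline from a report corpus:

```
prrnet synth   --config spec.yaml --out corpus.jsonl
prrnet disprop --input corpus.jsonl --drug FINASTERIDE \
               --comparator MINOXIDIL --sex male --out tables/
prrnet network --associations assoc.tsv --ppi ppi.tsv \
               --drug FINASTERIDE --out net/
prrnet enrich  --query genes.txt --gmt pathways.gmt --out enrich.csv
```

`synth` writes a seeded openFDA-dialect JSON-lines corpus plus a truth file
of analytic expected PRRs; `disprop` writes the gender-composition table
and the drug-vs-drug comparison table (CSV and text renderings); `network`
writes edge/node tables, per-degree metric profiles and power-law fits;
`enrich` writes the over-representation table.

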