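# semark

Rule-based discovery and RT-qPCR validation of somatic-embryogenesis
(SE) marker genes from FPKM expression tables.

## The problem

Somatic embryogenesis — the in-vitro reprogramming of somatic plant
cells into embryos — is the main regeneration route for the medicinal
herb *Centaurium erythraea*, but reliable molecular markers for its
stages are scarce. Given a transcript × tissue FPKM matrix over six
pooled libraries (organogenic: rosette leaf `rl`, rosette root `rr`,
adventitious bud `abl`; embryogenic: embryogenic callus `ec`, globular
embryo `gse`, cotyledonary embryo `cse`), `semark`:

1. classifies every transcript into seven marker subsets with explicit
   FPKM rules — a transcript is e.g. *rl-specific* when
   FPKM(rl) ≥ 1 and FPKM(rl) ≥ 8 · FPKM(t) for every other tissue t,
   and *SE-stage-specific* by analogous rules over the embryogenic
   tissues (four subsets: ec induction, early SE, late SE, all SE);
2. summarizes subset sizes, multiplicity-based share percentages, and
   unique/overlap (Venn-region) counts;
3. joins Swiss-Prot / NCBI-nt annotation exports and per-transcript GO
   assignments: coverage, best-hit species tallies, top-10 GO terms per
   category, and candidate selection by the E < 10⁻¹⁵ Swiss-Prot-first
   priority rule;
4. quantifies candidate expression across a nine-tissue RT-qPCR panel
   by the Livak method — ΔCt against the mean of two reference genes
   (RPL2, TBP1), ΔΔCt against the rosette-leaf calibrator,
   log2 FC = −ΔΔCt — with dilution-series standard curves for
   efficiency QC (90–110%) and y-intercept imputation of undetected
   Cts, followed by one-way ANOVA + Tukey HSD compact letter displays;
5. clusters tissues (Euclidean + Ward) and genes (1 − Pearson r +
   complete linkage) over log2 fold-change profiles and renders the
   clustered heatmap (red = decreased, blue = increased).

A synthetic-data module generates FPKM matrices with planted subset
members and Ct panels with planted fold changes, so the entire pipeline
runs and validates without any external download.

## Worked example

Library use — reproduce the study-scale subset accounting from the
seven subset sizes:

```python
from semark import summarize_sizes

summary = summarize_sizes(dict(
    rl_specific=8687, rr_specific=3294, abl_specific=727,
    ec_induction=764, early_se=1989, late_se=1203, all_se=84,
))
print(summary.total_hits, summary.organogenesis_total, summary.se_total)
for k, pct in summary.percentages.items():
    print(f"{k:14s} {summary.sizes[k]:6d}  {pct:6.2f}%")
```

```
16748 12708 4040
rl_specific      8687   51.87%
rr_specific      3294   19.67%
abl_specific      727    4.34%
ec_induction      764    4.56%
early_se         1989   11.88%
late_se          1203    7.18%
all_se             84    0.50%
```

16,748 is the total hit count with multiplicity (a transcript counts
once per subset it belongs to); 12,708 hits fall in the organogenic
subsets and 4,040 in the SE subsets; the percentages are each subset's
share of the 16,748. (The recomputed `abl` share is 4.34%; see
`docs/methods.md` for the documented discrepancy with the published
4.56%.)

CLI use — simulate, filter, summarize:

```console
$ semark --seed 7 --out-dir sim simulate fpkm --n-background 300 --n-per-subset 4
wrote 328 transcripts to sim/fpkm.tsv
$ semark --out-dir filt filter --fpkm sim/fpkm.tsv
classified 328 transcripts; rl_specific=4, rr_specific=4, abl_specific=4, ec_induction=4, early_se=12, late_se=4, all_se=4
$ semark --out-dir sum summarize --membership filt/membership.json
total hits 36 (organogenesis 12, SE 24)
```

Early SE reports 12 members, not 4: the 4 ec-induction plants and the 4
all-SE plants necessarily satisfy the early-SE rule too (a structural
theorem of the rule set), and `sum/report.json` accordingly shows
`unique_counts` of 0 for both ec induction and all SE here. The
remaining subcommands (`annotate`, `candidates`, `qpcr`, `cluster`,
`simulate ct`) follow the same pattern; see `semark --help`.

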