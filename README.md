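# simenrich

Statistical analysis of SUMO-interacting-motif (SIM) enrichment in
protein lists, plus a Perseus-style differential-enrichment stage for
label-free quantitative (LFQ) proteomics.

## The problem

Proximity-labeling interactomics (BioID/TurboID and derivatives)
produces short lists of candidate interactors — for instance, the
SUMO-dependent interactors of a SUMOylated substrate such as PML.  Many
such interactors are expected to dock onto SUMO through SIMs: short
hydrophobic β-strand motifs with core patterns

```
ψ-ψ-X-ψ     ψ-X-ψ-ψ     ψ-ψ-ψ        ψ ∈ {L, I, V},  X = any residue
```

`simenrich` answers the question *"is my protein list enriched in SIMs
relative to the proteome?"* with a resampling test:

1. Scan every protein for SIM motifs and normalize the count by length:
   **STAA** = SIMs per thousand amino acids = `1000 · n_SIM / L`.
   A list is summarized by the median member STAA and by the percentage
   of members with ≥ 1 (single) and ≥ 2 (multiple) SIMs.
2. Draw *R* random lists of the same size *k* from the proteome (the
   null), summarize each the same way.
3. Remove outlier lists with the ROUT method (robust Lorentzian fit +
   FDR at rate *Q* on residuals), log2-transform the retained null STAA
   values and check their normality with the D'Agostino–Pearson
   omnibus test.
4. Report **fold enrichment** = observed STAA / null-median STAA, and a
   one-sided **empirical p-value**: the fraction of retained null
   values ≥ the observed one (reported as the bound `1/R_retained` when
   no null value reaches it).

The LFQ stage reproduces the conventional label-free differential
workflow on MaxQuant-style protein-groups tables: filtering (≥ 2
peptides, ≥ 2 valid values of 3 replicates in a group), log2 transform,
optional median normalization, downshifted-normal imputation
(mean − 1.8 SD, width 0.3 SD), a two-sided Student's *t*-test per
protein, and the high-confidence call `|log2 diff| > 1 OR p < 0.05`.

Everything is also exercisable on seeded synthetic data — proteomes
with planted SIMs, hit lists with a planted enrichment factor, LFQ
matrices with planted effects — so the full pipeline is testable with
no downloads.

## Worked example

```python
import simenrich as se
from simenrich.simulate import ProteomeModel, HitListModel, generate_hit_list

# a 2000-protein synthetic proteome; 59 "hit" proteins carry SIMs at
# 4x the background planting rate of 5 motifs per 1000 aa
proteome, hits, _ = generate_hit_list(
    ProteomeModel(n_proteins=2000, sim_rate=5.0, alphabet="liv_free", seed=77),
    HitListModel(k=59, enrichment_factor=4.0, seed=77))

res = se.SimEnrichment(proteome, hits).fit(n_lists=1000, seed=13)
print(res.summary())
```

```
SIM enrichment analysis
============================================================
query list:            planted_hits (n=59)
proteome:              synthetic(seed=77) (2000 proteins)
counting mode:         collapsed
random lists:          1000 x 59 (seed 13)
ROUT outliers removed: 0 (Q=0.01)
normality (log2 null): K2=24.215, p=5.52e-06 (n=1000)
------------------------------------------------------------
observed STAA:         18.26 (log2 4.19)
null median STAA:      4.74 (log2 2.24)
fold enrichment:       3.85
empirical p:           < 0.001 (0/1000 null lists >= observed)
% single SIM:          98.31 observed vs 81.36 null median
% multiple SIM:        93.22 observed vs 57.63 null median
```

The planted 4× enrichment is recovered as a 3.85-fold ratio of observed
to null-median STAA, and none of the 1000 random lists reaches the
observed density, so the empirical p is reported as the bound < 0.001.
`res.matches()` gives the per-motif table (position, pattern class,
acidic/Ser flank flag) and `res.null_table()` the per-random-list
statistics with outlier flags.

The same objects work from files (`SimEnrichment.from_files(fasta,
list_txt)`) and from the command line:

```bash
simenrich enrich --proteome proteome.fasta --list hits.txt \
    --lists 1000 --seed 13 --out-dir results/
simenrich diff --table proteinGroups.txt --groups groups.yaml \
    --seed 1 --out-dir results/
simenrich simulate proteome --n-proteins 1000 --sim-rate 5 \
    --seed 1 --out-dir sim/
```

For the differential stage:

```python
from simenrich.simulate import LFQModel, generate_lfq
table, truth = generate_lfq(LFQModel(n_proteins=400, n_hits=40,
                                     effect=2.0, noise_sd=0.5, seed=3005))
print(se.LFQDifferential(table).fit(seed=5).summary())
```

```
Label-free differential enrichment
============================================================
comparison:          WT vs control (3 vs 3 replicates)
proteins loaded:     400
proteins tested:     387 (>= 2 peptides, >= 2 valid in a group)
imputation:          width 0.3 SD, shift 1.8 SD (seed 5)
classification:      |log2 diff| > 1 OR p < 0.05
------------------------------------------------------------
high-confidence:     68 (56 enriched in WT, 12 in control)
```

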