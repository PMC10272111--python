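# secseq

Analysis of **SEC-seq** experiments — secretion-encoded single-cell
sequencing, in which each cell's transcriptome is captured together with a
feature barcode reporting how much antibody that cell secreted while held in
a hydrogel nanovial. The package takes CellRanger-style sparse count
matrices (gene expression + antibody-capture features) and answers the
questions such an experiment poses about antibody-secreting plasma cells:

* which cells express which immunoglobulin heavy-chain isotype (IGHM,
  IGHA1, or one of the IGHG1–4 subclasses), gated in transcript space;
* which cells are *high* or *low* IgG secretors, classified against a null
  distribution;
* which genes are surrogate markers of high secretion, by cross-donor
  consensus correlation;
* what distinguishes high from low secretors transcriptionally
  (rank-sum differential expression);
* for validation runs, how often two cells share one droplet (two-species
  "barnyard" classification) and which cells sat on a nanovial at all.

A fully seeded synthetic-data generator produces ground-truth-labeled
fixtures with the same statistical structure, so every stage is testable
without sequencing data.

## The core statistic: null-anchored secretion thresholds

Cells positive for IGHM or IGHA1 cannot secrete IgG, so their SEC-IgG
barcode counts form an empirical null. On the `log10(1 + count)` scale with
null sample `x_1..x_n`:

```
t_hi = x_(ceil(0.9 n))            # nearest-rank 90% quantile of the null
t_lo = mean(x) - (t_hi - mean(x)) # mirrored about the null mean
```

A cell is **SEC-hi** when its transformed barcode value is strictly above
`t_hi`, **SEC-lo** strictly below `t_lo`, otherwise **SEC-mid**. By
construction ~10% of null cells land above `t_hi`, so the SEC-hi fraction
of any population reads directly as enrichment over the non-secreting
baseline.

Isotype gates are placed at the local minimum of a Gaussian KDE between the
two dominant modes of each channel's (bimodal) expression distribution —
the transcript-space analogue of drawing flow-cytometry gates. Surrogate
markers are genes whose Pearson correlation `r` between normalized
expression and the log barcode is at least `r_min = 0.1` in *every* donor,
ranked by mean `r` across donors.

## Worked example

```sh
secseq run --demo --seed 5 --out run/
```

generates a 6,000-cell, 3-donor fixture and runs the full pipeline. The
report (`run/report.md`) begins:

```
## Secretion thresholds (log10(1+count) scale)

- SEC-hi cutoff (t_hi): 1.4472 (nearest-rank 90% quantile of the IGHM/A null)
- SEC-lo cutoff (t_lo): 0.5604 (null mean minus the t_hi excess)
- null mean 1.0038 over 2272 IGHM/A+ cells

## SEC class composition by isotype_call

    group    n  pct_hi  pct_lo  pct_mid
DN_nonIgG   13   38.46    7.69    53.85
 IGHA_pos  539    9.46    9.83    80.71
 IGHM_pos 1733    9.58    9.64    80.78
      IgG 3715   28.53    7.05    64.41
```

Read: the IGHM/IGHA populations sit at the calibrated ~10% SEC-hi baseline
(they cannot secrete IgG), while ~29% of IgG cells exceed the high cutoff —
the generator plants a 1-log10 barcode shift in true secretors, whose
frequency rises with pseudotime from 10% to 40%. Further down, the
consensus-marker table recovers the five planted surrogate markers (CD38,
CD59, MZB1, XBP1, SUB1) as the top non-immunoglobulin genes, and the
differential-expression table shows the same genes upregulated in SEC-hi
IgG cells at q < 0.1.

The same analysis runs on real data via
`secseq run --data <cellranger_dir> --out run/` where the directory holds
`matrix.mtx`, `features.tsv`, `barcodes.tsv` and optionally `cells.tsv`
(donor / timepoint / cluster / pseudotime per barcode). Individual stages
are exposed as `secseq preprocess | gate | secretion | markers | de |
barnyard | convert | validate | report`.

## Layout

| module | contents |
| --- | --- |
| `secseq.synthetic` | ground-truth generator (main ASC fixture + barnyard) |
| `secseq.io_formats` | MTX/TSV readers/writers, config loading |
| `secseq.preprocess` | QC filter, chain-exclusivity filter, log normalization |
| `secseq.gating` | bimodal KDE gates, isotype/subclass assignment |
| `secseq.secretion` | barcode transform, thresholds, SEC classes, profiles |
| `secseq.association` | correlations, consensus markers, z-score tables, DE |
| `secseq.mixing` | barnyard species calls, on/off-nanovial calls |
| `secseq.pipeline` / `secseq.cli` | orchestration, manifest, reports, CLI |

See `docs/methods.md` for the model, parameter choices, and limitations.
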