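# Methods

## Analysis model

SEC-seq couples two measurements per cell barcode: a UMI count matrix over
genes, and antibody-capture feature counts, one of which (`SEC-IgG`)
reports the amount of IgG captured on the cell's nanovial during a fixed
secretion-accumulation window. The analysis treats the barcode as a
relative, not absolute, secretion readout and therefore anchors every
classification to an *internal null*: cells gated IGHM+ or IGHA1+ express
a non-IgG isotype, cannot contribute secreted IgG, and so their barcode
distribution measures ambient capture plus technical noise.

### Normalization

Counts are depth-normalized to `target_sum` (default 1e4) per cell and
transformed with the natural `log1p` — the standard single-cell convention,
so gates and fold changes are on the familiar log-transcript scale. Cells
with zero total counts are kept all-zero and flagged rather than dropped at
this stage. The secretion barcode is transformed as `log10(1 + count)`;
base 10 keeps thresholds readable as "one log above the null".

### Quality and chain-exclusivity filtering

Defaults: `min_genes_per_cell = 200`, `min_counts_per_cell = 500`. These
are conventional droplet-QC values, configurable and reported in the run
manifest; no mitochondrial-fraction filter is applied by default. A second
filter removes barcodes violating immunoglobulin chain exclusivity — more
than one heavy-chain channel (IGHM, IGHA1, pooled IGHG1–4, and, when
subclass gates are supplied, two IGHG subclasses) above its gate, or both
light chains (IGKC, IGLC) above theirs. Such barcodes are biologically
implausible for a single plasma cell and are the expected signature of
droplet doublets.

### Gating

For each channel, a Gaussian KDE (Silverman bandwidth, 512-point grid over
the data padded by three bandwidths) is evaluated; the two highest-density
local maxima are taken as the off/on modes and the threshold is the density
argmin strictly between them. If the distribution is not bimodal the gate
falls back to a configurable quantile (default 0.5) with an explicit
warning, and the gate's method is recorded so downstream consumers can see
which rule produced each threshold. Gates are computed on pooled donors by
default (a per-donor switch exists); gating uses normalized log values,
whereas the "IgG cell" rule is a raw-count statement: a double-negative
cell is IgG iff its summed IGHG1–4 raw counts are non-zero, with the
subclass the argmax of subclass counts (ties broken IGHG1 < … < IGHG4 and
flagged). This gating-scale choice is recorded in the gates YAML.

### Secretion thresholds and classes

With null sample `x` (transformed barcode of IGHM/IGHA cells, at least
`min_null_cells = 50` of them):

* `t_hi` — nearest-rank quantile: the sorted value at index `ceil(q·n)`,
  `q = 0.90` by default. Nearest-rank is deterministic, sample-valued, and
  makes the calibration property exact: the fraction of null cells at or
  below `t_hi` is `ceil(q·n)/n`.
* `t_lo = null_mean − (t_hi − null_mean)`, the mirror of the high cutoff
  about the *null* mean (the only distribution in scope at that point of
  the derivation); an override to the IgG-population mean exists for
  sensitivity analysis.
* Classification is strict on both sides; a value exactly at a cutoff is
  `sec_mid`, because "above the quantile" excludes the boundary.

Composition tables report %hi/%lo/%mid per cluster, isotype, subclass, or
donor. The pseudotime profile bins cells into half-open `[k·w, (k+1)·w)`
windows (`w = 0.05`, the final bin closed at 1.0) and reports the SEC-hi
fraction per donor per bin; bins under `min_bin_cells = 10` are missing,
not zero. A confidence-interval variant of the threshold derivation is not
implemented: no procedure is specified for it and the quantile rule
supersedes it.

### Marker discovery and differential expression

Per donor, each gene's normalized expression is Pearson-correlated with the
transformed barcode; p-values come from `t = r·sqrt((n−2)/(1−r²))` against
Student's t (two-tailed), zero-variance genes are flagged with `r = 0, p = 1`.
A gene is a consensus marker when `r ≥ r_min` (default 0.10) in every
donor (or `≤ −r_min` for the negative direction); candidates are ranked by
mean r and the top 40 reported. Heatmap summaries z-score each gene within
each donor across *all* cells using the population (ddof = 0) standard
deviation — a fixed, documented convention — then average within SEC
groups; constant genes and empty groups are missing, not zero.

Differential expression between SEC-hi and SEC-lo IgG cells uses the
two-sided Wilcoxon rank-sum test: exact enumeration when both groups have
at most 8 tie-free values, the tie-corrected normal approximation otherwise
(the reported statistic is always the tie-corrected z). Benjamini–Hochberg
adjustment is applied across tested genes with significance at `q < 0.1`;
the fold change is the difference of group means on the normalized log
scale.

### Barnyard and nanovial calls

Species totals come from gene-symbol prefixes (`GRCh38_` / `mm10_`). A
barcode with fewer than `min_total = 100` combined counts is uninformative;
otherwise it is `mixed` when the minor-species fraction reaches
`minor_threshold = 0.10`, else the majority species. No numeric rule is
specified for the published mixed-percentage, so these defaults are
deliberately conservative, config-exposed, and echoed in the output; the
mixed fraction over informative barcodes estimates the doublet rate.
On/off-nanovial calls reuse the bimodal gate detector on the log nanovial
barcode; a unimodal distribution requires an explicit threshold.

## Synthetic data: what it emulates, and what it does not

The generator emulates the statistical structure the analysis assumes, not
sequencing physics. Per cell: a population label (activated B, IGHM-, IGHA-,
or IgG-secreting ASC), mutually exclusive heavy-chain isotype genes and one
light chain, marker genes for the activated/ASC distinction, surrogate
marker genes whose mean scales with latent secretion, negative-binomial
counts, and a log-normal secretion barcode.

Defaults are the study conditions the package targets:

| parameter | default | rationale |
| --- | --- | --- |
| donors | 3, equal sizes | three-donor consensus design |
| pop_weights (IgG fraction) | 0.629 | matches an 8,106-of-12,892 IgG cohort |
| IgG subclass mixture | 76.5 / 8.2 / 12.7 / 2.7 % | printed subclass composition (normalized; the printed values sum to 100.1%) |
| secretor_fraction_range | (0.10, 0.40) | secretor probability rising linearly over pseudotime 0.85→1.0 |
| secretor_log_shift | 1.0 log10 | one-log median barcode increase in secretors |
| null_barcode_log_mean / sd | 1.0 / 0.35 | null centered at ~10 counts; with the 1-log shift this places ~30% of IgG cells above the 90% null quantile |
| nb_dispersion | 2.0 (NB shape) | visible overdispersion without drowning structure |
| marker_effect | 2.0 | marker mean × (1 + effect · latent rate); secretors ~3× base |
| library_size_mean | 2,000 | modest droplet library |
| pseudotime | activated U[0, 0.2]; ASC U[0.85, 1.0] | differentiation mass sits above 0.85 |

The latent secretion rate of a secretor is uniform on [0.5, 1.5] (mean 1),
so the median barcode shift equals `secretor_log_shift` and markers vary
*within* secretors too. The null barcode family (log-normal) is a modeling
choice; no distributional family is implied by the assay itself.

Not emulated: read-level sequencing, UMI collisions, ambient RNA, isotype
leakage (off by default; a config switch adds it to exercise gating
robustness), batch effects, or capture saturation of the nanovial surface.
Passing recovery tests therefore shows the *estimators* are correct under
the assumed structure — not that real data satisfy that structure.

One consequence worth stating: with the default ramp only ~25% of IgG cells
are secretors, so the *median* IgG barcode sits well under one log above
the null even though every true secretor is shifted a full log. The
qualitative one-log median separation is exhibited (and tested) on a
high-secretor-fraction configuration (`secretor_fraction_range=(0.9, 1.0)`).

The barnyard fixture uses disjoint 25-gene panels per species; a doublet
barcode adds the counts of one cell of the other species, and the nanovial
barcode is Poisson(200) on-vial vs Poisson(2) off.

## Numerical choices and degenerate inputs

* Nearest-rank quantiles and argmax tie-breaks make every threshold a
  deterministic function of the data; no interpolation anywhere.
* `t_lo` is computed as `null_mean − (t_hi − null_mean)` so the symmetry
  identity holds to machine precision, and is validated on construction.
* Pseudotime binning adds a 1e-9 epsilon before flooring so boundary values
  like 0.85/0.05 bin correctly despite floating-point division.
* Degenerate cases are explicit: constant gate channels fall back with a
  warning; an all-zero cell normalizes to zeros and is flagged; an empty
  IgG population yields a report that says so; too few null cells is an
  error directing the user to explicit thresholds, not a silent guess.
* Problem sizes in the test-suite recovery experiments (15,000 cells for
  marker recovery, 8,106 for subclass recovery, 5,000 for barnyard, 4,000
  for profiles) are chosen so binomial noise sits well inside the asserted
  tolerances while a full run stays desk-scale.

## Known limitations

* Pseudotime and cluster labels are consumed, never computed; trajectory
  inference, embedding, and batch correction live upstream.
* The barcode is relative: no saturation correction or absolute
  molecules-per-second calibration is attempted.
* The mixed-call rule is a defaulted heuristic; its numeric output depends
  on `min_total` and `minor_threshold` and is not claimed to reproduce any
  particular published mixing percentage.
* Subclass assignment by raw-count argmax is deliberately simple; low-depth
  IgG cells with zero subclass counts drop to double-negative rather than
  being imputed.
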