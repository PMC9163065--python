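# Methods

## Data model

Beta values are methylated-signal fractions in [0, 1]; NaN marks a missing
call in memory and `NA` on disk. Missing values are excluded pairwise from
every summary and call, and a probe with a missing beta is never called
highly methylated in that sample — a masked probe carries no evidence.
Probe coordinates are 1-based point positions (Illumina manifest
convention); the BED export converts each to the 0-based half-open
interval `[pos−1, pos)`. Quantiles use linear interpolation between order
statistics so oracle tests can be exact. Probes whose `genomic_context` is
TSS200, TSS1500 or 5'UTR are flagged as promoter-proximal (the standard
Infinium annotation reading of "vicinity of promoters"); the set is
configurable in `read_manifest`. chrY probes are carried through IO and
retention tables but excluded from the enrichment population by default
(`include_chry=True` restores them), since the cell-line analyses cover
chr1–22 and chrX.

## QC filter

`apply_detection_filter` keeps a probe only when its detection p-value is
≤ 0.05 (threshold configurable) in **every** sample of the matrix being
filtered. Filtering is applied per analysis set (the matrix you pass in);
whether cell-line and tissue panels should be pooled before filtering is a
study-design question the library leaves to the caller, and the pipeline
records the probe counts before/after in its run manifest.

## Retention

A probe *retains* methylation at cutoff *c* when β ≥ *c* (inclusive) in
both the parental and the DNMT-compromised sample. The per-chromosome
percentage uses parental-high probes as the denominator. The conjunctive
numerator (high in **both** samples) is one of two readings of
"probes retaining high methylation out of all highly methylated probes";
it is adopted because it matches the enrichment bookkeeping, where q ≤ m
must hold per chromosome. Chromosome ranking is ascending by percent
retained at a reference cutoff (default 0.7), ties broken by label, and
chromosomes with no parental-high probes are reported as undefined (NaN),
never as 0%, and sort last. `parental_high_fraction` reports the baseline
fraction of high probes per chromosome — near-uniform (~0.6) baselines
rule out unequal starting methylation as the source of retention
differences.

Note `pct_retained` need not be monotone in the cutoff (both numerator and
denominator shrink); only the denominator's monotonicity is guaranteed and
asserted.

## Enrichment bias and hypergeometric testing

The population is the genome-wide set of parental-high probes (m + n),
not all array probes: only under that reading does e = (m/(m+n))·k give
the expected *retained* count per chromosome, consistent with comparing
retention "to the number of methylated probes on each individual
chromosome in the parental line". Because Σq = k and Σe = k, percent
biases sum to zero analytically; this is asserted on every run at 10⁻⁹
relative tolerance.

The tail is direction-matched and one-sided: upper P(X ≥ q) (computed as
`sf(q−1)` to avoid the off-by-one) when q ≥ e, lower P(X ≤ q) otherwise,
X ~ Hypergeom(m+n, m, k). Reported p-values are raw, flagged at a fixed
α = 10⁻⁶ across 23 chromosomes; a Bonferroni-adjusted column is emitted
as a labeled extra but does not drive the flag.

## Classification of retained promoter probes

Selected probes have `is_promoter` true and β ≥ 0.7 in both parental and
resistant samples. Normal-tissue evidence is the per-sex mean beta across
the `normal_tissue` panel (no aggregation rule beyond the mean is
imposed). Categories, in precedence order:

* **methylated_in_normal** — mean β ≥ 0.7 in both sexes;
* **unmethylated_in_normal** (de novo in cancer) —
  * autosomes: mean β ≤ 0.3 in both sexes (symmetric extension of the
    chrX rule);
  * chrX: male mean ≤ 0.3 **and** female mean either ≤ 0.3 (site escapes
    X inactivation) or within the monoallelic band [0.3, 0.7] (one
    methylated inactive X). The male-unmethylated requirement is the
    anchor; accepting a female-unmethylated X site keeps escape genes
    classifiable. The male cell line's single X means the female
    monoallelic pattern is evidence about tissues only — the cell-line
    side of the rule uses just the two β ≥ 0.7 checks;
* **unclassified** — anything else, including probes that fail the
  cell-line cutoffs; unclassified probes stay in `n_total` but are
  excluded from the `pct_de_novo` denominator.

The bounds 0.3 / [0.3, 0.7] / 0.7 quantify the verbal categories
"unmethylated", "50% methylated" and "methylated" (only the last is
stated numerically in the source analysis); all are configurable via
`ClassificationThresholds`. At band edges (e.g. female mean exactly 0.7)
the methylated rule wins by precedence.

## Synthetic data

`simulate_dataset` draws each sample's betas from a mixture of Beta
components: low (2, 18), high (18, 2), monoallelic (12, 12), intermediate
shoulder (6, 6). Defaults: 60% of probes per chromosome parental-high;
retention probability 0.05 on autosomes, 0.25 on chrX, 0.02 on
chr16/17/19/22; shoulder probability 0.15 for demethylated probes in the
drug-resistant line only (the knockout line has none); 70% of chrX probes
subject to X inactivation; 75% of probes methylated in normal tissue
(typical of array CpGs, most of which sit in methylated genomic
background); tumors methylate de novo probes with penetrance 0.7. The
default manifest holds ~18,700 probes allocated roughly in EPIC
chromosome proportions — large enough for the chrX enrichment to reach
p ≪ 10⁻⁶ while keeping full-pipeline runs at a few seconds.

One RNG stream is seeded once; the manifest, latent truth and samples are
drawn in a fixed order (cell lines, normal males, normal females, tumors,
adjacent normals; four component vectors plus one uniform vector per
sample) so outputs are bit-identical across platforms. `simulate_cohort`
derives a second stream from `(seed, 9157)` so cohorts are reproducible
but independent of the main dataset's draws.

What the generator does **not** emulate: probe-level intensity noise and
detection failures (betas are exact component draws), batch and dye
effects, copy-number artifacts, spatial correlation along the genome, and
realistic inter-tumor heterogeneity beyond independent per-probe
penetrance. Passing tests therefore demonstrate the correctness and
calibration of the statistics on data satisfying the model's assumptions,
not robustness to array artefacts — on real data, upstream preprocessing
(e.g. SeSAMe) is assumed to have handled those.

## Cohort validation

The cohort layer is descriptive. Sample ordering is sex-major then tissue
type (the heatmap layout contract); per-probe cells with zero samples are
NaN, never 0. The default tumor "hypermethylated" call is relative —
β at least 0.3 above the sex-matched adjacent-normal mean — because chrX
baselines differ by sex; an absolute call (β ≥ 0.7) is selectable. Rows
are sorted by `tumor_hyper_fraction` descending (a concrete choice where
the visual ordering of published heatmaps is not specified).

## Pipeline and reproducibility

`run_pipeline` executes filter → summaries → retention → enrichment →
classification (→ cohort when cohort inputs are given). Config parsing is
strict (unknown keys are errors, preventing silent threshold typos);
defaults are the published parameter values (detection 0.05, cutoffs
0.6/0.7/0.85, enrichment cutoff 0.7, α = 10⁻⁶). Every stage TSV carries
`#` header comments with its generating parameters; the run manifest JSON
records package version, seed, parameters and SHA-256 checksums of all
inputs. An `_INCOMPLETE` marker file exists for the duration of a run and
is removed only on success.

## Known limitations

* The per-analysis-set QC choice (joint vs separate filtering of panels)
  can change probe universes between stages if callers filter
  inconsistently; the pipeline filters once, up front.
* The hypergeometric tail convention is a documented choice; a two-sided
  convention would roughly double borderline p-values.
* Classification accuracy claims hold for well-separated beta components;
  the test suite demonstrates monotone degradation as components merge,
  but no attempt is made to model real panel heterogeneity.
* Acceptance-style checks run at ~2,000–19,000 probes, the package's
  desk-scale default; array-scale (~850k probes) runs are supported by the
  same code paths but not exercised in the suite.
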