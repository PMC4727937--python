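# bulkscan

Bulk-segregant allele-frequency scanning for mapping parent-of-origin
effects on seed viability. The package models a cross in which a mother
(accession background `A`) carrying a maternal-effect lethal mutation is
pollinated by an `A/B` F1 hybrid: seeds that maternally inherit the mutant
allele survive only when the paternal gamete carries rescuing `B` alleles
at one or more modifier loci. Sequencing pools of surviving seedlings from
this cross and from a wild-type control cross, and scanning the genome for
windows where `B`-allele reads are enriched in the selected pool, localises
the rescue loci.

Everything runs end to end without external data: the simulator generates
pooled per-SNP read counts under a configurable genetic map, viability
model, coverage model and segregation-distortion loci, and the analysis
stack recovers the planted loci.

## What is implemented

- **`cross_model`** — genetic maps (piecewise-linear cM/bp interpolation),
  cross designs (`mea_pool`, `wt_pool`, `f2_selfing`), a multiplicative
  viability model (per-locus rescue factors, capped at 1, `inf` = fully
  required locus), Haldane recombination, and *two independent routes* to
  every expectation: exact enumeration of gamete classes and forward Monte
  Carlo. Closed-form anchors: 50% viable seeds for an unrescuable selfed
  heterozygote, 75% with one fully penetrant unlinked rescue locus, 25%
  pooled paternal-allele fraction in the control pool, 50% at a fully
  required locus in the selected pool.
- **`pool_sim`** — rejection-sampled survivor populations over a SNP panel
  (gametes simulated with linkage; transmission distortion applied as an
  importance weight), then pooled read counts with Poisson or
  negative-binomial depth and a base-error rate.
- **`snp_filter`** — the quality cascade: drop panel-flagged positions,
  drop coverage above the 99th percentile of Poisson(median coverage),
  combine replicates by summing counts per SNP, drop positions missing
  either allele, trim the 1% coverage tails. Every stage logs row counts.
- **`enrichment`** — 50-SNP rolling-window allele proportions per pool,
  the relative enrichment `(p_sel − p_ctl) / p_ctl`, 100-window rolling
  median smoothing, and two peak callers: simple threshold/separation
  local maxima, and the default non-negative deconvolution against an
  exponential linkage kernel (separates closely linked loci on a ridge of
  long-range linkage).
- **`seedstats`** — Clopper–Pearson exact binomial intervals,
  Bonferroni-corrected one-sided exact binomial rescue tests against a
  control line, cube-root transform.
- **`io_cli`** — TSV/BED readers and writers (1-based internally, BED
  exports 0-based half-open), YAML configs, a deterministic end-to-end
  pipeline with a JSON manifest, and the CLI.

## CLI

```sh
# closed-form design expectations for a config
bulkscan expect --config config.yaml

# full pipeline: simulate two pools (3 replicates each), filter, window,
# smooth, call peaks; outputs + manifest.json under out/
bulkscan run --config config.yaml --seed 1 --out out/

# individual stages
bulkscan simulate --config config.yaml --out sim/
bulkscan filter --panel sim/panel.tsv --out mea.tsv sim/counts.mea.rep*.tsv
bulkscan enrich --mea mea.tsv --wt wt.tsv --out tracks/
bulkscan peaks --track tracks/enrichment.smoothed.tsv --out peaks.tsv
bulkscan stats --counts seed_counts.tsv --control Ler --out report.tsv
```

A ready-made configuration with six planted rescue loci (multipliers tuned
so viability spans 3% with no rescue alleles to 85% with all six) is
available programmatically:

```python
import yaml
from bulkscan.io_cli import demo_config
yaml.safe_dump(demo_config(seed=1), open("config.yaml", "w"))
```

Config keys (see `demo_config()` for a complete example): `seed`,
`simulate.map`, `simulate.n_snps`, `simulate.coverage`
(`distribution`/`mean`/`dispersion`/`error_rate`),
`simulate.baseline_viability`, `simulate.wildtype_viability`,
`simulate.rescue_loci` (`chrom`, `pos_bp` or `pos_cm`, `multiplier`),
`simulate.distortions` (`chrom`, position, `bias`), survivor counts per
replicate, `filter.*`, `enrichment.*`, and `peak_caller`
(`deconvolution` | `local_maxima`). Replace the `simulate` section with
`input` (`panel`, `mea`, `wt` table paths) to analyse existing count
tables.

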