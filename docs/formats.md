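# File formats

All interchange files are plain text. Coordinates are 0-based half-open
internally; VCF positions (1-based) are converted on read.

## GWAS summary statistics (TSV)

Header: `SNP  CHR  POS  A1  A2  BETA  SE  P  N`

`A1` is the effect (counted) allele; `BETA` is the additive effect in trait
units per copy of `A1`; `P` in (0, 1]; `SE > 0`. Other layouts map through
the `dialect` argument of `read_summary_stats` (canonical name -> file
column). Malformed rows are dropped with a logged count.

## Population frequency table (TSV + YAML)

Header: `CHR  POS  SNP  A1  A2  <POP1>  <POP2> ...`

One column per population holding the `A1` frequency in [0, 1]. Population
latitude/longitude live in a side YAML:

```yaml
populations:
  POP1: {latitude: 36.0, longitude: -9.0}
  POP2: {latitude: 41.2, longitude: -2.0}
```

## SDS table (TSV)

Header: `CHR  POS  ID  AA  DA  DAF  SDS`

`AA`/`DA` ancestral and derived allele, `DAF` derived-allele frequency,
`SDS` the raw score polarized to the derived allele.

## LD Scores (whitespace-delimited)

Header: `CHR  SNP  BP  L2` with optional `MAF` (the `.l2.ldscore` layout).

## LD blocks and masks (BED3)

`chrom  start  end`, 0-based half-open, sorted, non-overlapping within a
chromosome.

## VCF

Frequencies are computed from `GT` fields of biallelic SNP records; the
counted allele is ALT; per-population frequency = ALT allele count /
(2 x non-missing diploids). Sample-to-population assignment is supplied as a
mapping.

## Results

Test results serialize as JSON (`method`, `statistic`, `df`, `p_value`,
`axis_label`, `snp_count`); curves and lead-SNP sets as TSV with the column
names shown by each command.
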