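# Table schemas

All files are delimited text (comma or tab; sniffed on read) with a header
row. Compound columns accept the typographic prime (`IIa′`) or an ASCII
apostrophe (`IIa'`).

## Peak-area / abundance table
- 15 compound columns: `Ia Ib Ic IIa IIa′ IIb IIb′ IIc IIc′ IIIa IIIa′ IIIb IIIb′ IIIc IIIc′`
- optional: `sample_id`, `depth_m`, `standard_area`, `standard_micrograms`

## Calibration table
- the 15 compound columns (fractional abundances, each row summing to 1;
  rows within ±0.02 of 1 may be renormalized with the `renormalize` flag)
- `MAP_mm` (alias `MAP`): observed mean annual precipitation, mm/yr
- optional: `MAP_alt_mm` (gridded-climate cross-check), `MAT_C`, `pH`, `source`

## Downcore profile
- `depth_m`: strictly increasing depth, metres (0 at top, increasing down)
- optional: `sample_id`, `susceptibility` (SI instrument units),
  `mean_grain_size_um`, the 15 compound columns, n-alkane homolog
  concentrations `C23` … `C34`, `age_ka` (added by the age model)

## Control points
- `depth_m`, `age_ka` (ka before present); or any two-column file in that order

## Time series
- `age_ka`, `value`; or any two-column file in that order
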