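# Bundled example datasets

Small, publicly printed clinical tables used as smoke fixtures.

- `copd.csv` — complete arm-level network meta-analysis of 3 studies
  comparing 4 treatments for chronic obstructive pulmonary disease
  (1 placebo, 2 fluticasone, 3 salmeterol, 4 salmeterol+fluticasone
  combination); extracted from Woods et al., BMC Med Res Methodol 2009.
- `ad_head.csv` — first six of 347 antidepressant acceptability
  (all-cause dropout) trials collected by Cipriani et al., Lancet 2018.
- `ns_head.csv` — first six studies of the first of 564 nutrition-support
  meta-analyses (all-cause mortality) from Feinberg et al., BMJ 2017.
- `sc_head.csv` — first six arms of the 24-study smoking-cessation network
  (1 no contact, 2 self-help, 3 individual counselling, 4 group
  counselling) analysed by Lu & Ades, JASA 2006, originally reported by
  Hasselblad, Med Decis Making 1998.

Only `copd.csv` is a complete dataset; the other three are 6-row excerpts
for format validation. The full source collections are not redistributed
here; obtain them from the publications above and pass them to the readers
in `fragility.io`.
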