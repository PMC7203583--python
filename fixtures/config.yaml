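# Default synthetic scenario; regenerate the CSVs with:
#   surrogatefrax simulate --out fixtures --seed 0
tables:
  source_incidence: fixtures/source_incidence.csv
  source_mortality: fixtures/source_mortality.csv
  target_mortality: fixtures/target_mortality.csv
  mof_ratio: fixtures/mof_ratio.csv
  population: fixtures/population.csv
seed: 0
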