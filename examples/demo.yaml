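# Demo pipeline configuration: simulate a small checkup cohort and run
# the full seasonal analysis.  Usage:
#   metseason all --config examples/demo.yaml --outdir demo_out
n_subjects: 6000
seed: 42
window: [[2012, 4], [2017, 12]]
trim_percentile: 0.005
strata: true
make_plots: true
stl:
  seasonal_span: 7
  trend_span: 23
  lowpass_span: 13
  inner_iterations: 2
  outer_iterations: 5
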