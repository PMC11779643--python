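# Template signature config. Weights and threshold are supplied by the user
# from the signature's source publication; the affine batch coefficients map
# scores from an updated preprocessing pipeline back onto the scale the
# threshold was defined on (set slope 1 / intercept 0 when not needed).
name: example
risk_threshold: 10.199
batch_slope: 1.04
batch_intercept: -0.081
min_coverage: 0.75
genes:
  GENE1: 0.25
  GENE2: -0.10
  GENE3: 0.42
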