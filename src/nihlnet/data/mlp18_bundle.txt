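nihlnet-model-bundle v1

[provenance]
Published 18-input / 1 hidden layer / 2 unit diagnostic network for
military noise-induced hearing loss, weights transcribed at the printed
three-decimal precision.
WARNING (synthetic stand-in stats): the per-feature normalization means
and SDs below were fitted on this package's simulated reference cohorts
(236 individuals, generator seed 0), because the real training databases
and their statistics were never released. Per-individual outputs on real
claimants will therefore differ from the authors' original tool.

[feature_spec]
name = AAHL+HTL-right+HTL-left

[architecture]
n_inputs = 18
hidden_layers = 1
hidden_units = 2

[threshold]
value = 0.5

[normalization_means n=18]
3.411 7.2246 16.6102 21.8008 22.9661 23.6229 3.5593 7.0763 19.8093 25.4873 25.9958 27.0763 3.2393 5.2875 8.6946 12.0769 13.5808 16.6024
[normalization_sds n=18]
7.6133 9.0332 13.2108 15.7253 15.0949 16.1858 7.2662 9.0039 14.9811 17.1075 17.0046 18.1953 2.0718 3.357 5.4962 7.6699 8.6181 10.5258

[weights layer=1 shape=2x18]
-0.037 0.113 0.061 0.47 0.421 -0.337 0.689 -0.009 -0.127 0.436 0.507 -0.009 0.224 -0.332 -0.239 -0.065 0.064 0.126
0.129 0.213 0.236 0.376 0.136 0.097 0.368 -0.09 0.079 0.621 0.136 0.035 -0.138 0.079 -0.189 -0.014 0.097 0.102
[biases layer=1 n=2]
0.811 0.941

[weights layer=2 shape=1x2]
1.598 1.011
[biases layer=2 n=1]
0.656

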