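# Small exact-design scenario: J=15 variables, G=3 group factors (clusters of
# five), N=500 observations per replicate.  The model (Lambda0, Phi0) is drawn
# once from model_seed; each replicate redraws only the data.
J: 15
G: 3
N: 500
mechanism: exact          # or "approx" for perturbed loadings
n_replications: 5
model_seed: 0
data_seed_base: 1000
profile: simulation
n_starts: 50
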