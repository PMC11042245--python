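# Shared configuration for the analysis scripts (01-06).
# One master seed determines every artifact; see docs/methods.md.
seed: 1
output_dir: results/study
synthetic_n: 400
synthetic_noise_sd: 0.4
synthetic_active_fraction: 0.57
activity_threshold: 7.0
fingerprint_radius: 3
fingerprint_bits: 512
cv_k: 5
cv_inner_k: 3
train_fraction: 0.9
screening_mode: threshold
screening_threshold: 7.0
screening_top_k: 200
tsne_perplexity: 30
tsne_iterations: 1000
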