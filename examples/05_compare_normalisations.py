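"""Why normalise with a subproteome trend instead of a single marker?

Three strategies are compared on synthetic truth: no correction, division
by one content-tracking marker protein (the citrate-synthase-activity
analogue, degraded with realistic assay noise), and the BESt chain. The
uncorrected analysis inherits the full content trend as bias; the single
marker is unbiased on average but propagates its own noise into every
protein; BESt pools the trend over hundreds of proteins.
"""

from mitonorm import CohortConfig, PipelineConfig, compare_normalisations

cfg = PipelineConfig(simulation=CohortConfig(), out_dir="unused", seed=1)
summary, details = compare_normalisations(cfg, marker_noise_sd=0.5)
print(summary.drop(columns="marker").round(4).to_string(index=False))
print(
    "\nmean_abs_bias: average |estimated - true| log2 deviation "
    "(delta = 0 cohort);\nfpr_null: fraction of truly unchanged proteins "
    "called at adjusted p < 0.01.\nThe uncorrected strategy is biased by "
    "the content trend; the noisy marker\nis unbiased but unstable "
    "(its noise shifts every protein in a sample);\nBESt is both "
    "nearly unbiased and stable."
)
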