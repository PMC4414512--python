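"""Detect minority species at a 1:50 DNA dilution.

Pig and horse DNA enter the pool at 1/50 of the five majority mammals; the
question is whether a 2-read threshold across at least two primer pairs
still calls them present.
"""

from ampliconid import RunConfig, run_pipeline

config = RunConfig(
    out_dir="scratch_dilution_run",
    seed=3,
    species=["pig", "horse", "cattle", "sheep", "rabbit", "human", "rat"],
    pool="e",  # built-in 1:50 pool design
    n_reads=10_000,
    min_reads=2,
    min_pairs=2,
)
bundle = run_pipeline(config)

print(bundle["counts"].to_frame())
for call in bundle["detection"]:
    if call.species in ("pig", "horse"):
        print(call.species, "detected" if call.detected else "NOT detected",
              dict(call.supporting))
# each minority species contributes roughly 10000/3 * 2/504 ~ 13 reads per
# primer pair, comfortably above the 2-read threshold in all three markers.
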