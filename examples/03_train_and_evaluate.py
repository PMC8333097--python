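"""Train the frame classifier end to end on a synthetic corpus.

Synthesizes a 5-species corpus, crops the labeled calls, splits 75:25,
trains a scaled-down sinc-frontend model, and evaluates by frame-posterior
voting.  Takes about half a minute on one CPU.
"""

from sincbird import run_experiment, scaled_synthetic_experiment

cfg = scaled_synthetic_experiment(master_seed=0, frontend="sinc",
                                  n_replicates=1)
manifest = run_experiment(cfg, "example_output/experiment", verbose=True)

print("\nmetrics (mean over replicates):")
for name, agg in manifest["summary"].items():
    print(f"  {name:10s} {agg['mean']:.3f}")
# With 5 species in disjoint frequency bands the task is easy by design:
# accuracy should approach 1.0 after 10 epochs (chance level is 0.2).
# The accuracy-vs-epoch figure and per-run history CSVs are written next
# to the manifest.
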