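"""Generate a synthetic two-task study and write it as CSV.

Builds an 11-participant study in which the first five participants have a
narrow temporal-order-judgment window combined with reaction-time
coactivation out to +/-80 ms SOA — the configuration in which the two
task-defined windows dissociate — and writes it in the package's native
CSV dialect together with the ground-truth parameters.
"""

from twindow import make_malleable_study_config, make_study, write_native

cfg = make_malleable_study_config(seed=7)
dataset = make_study(cfg)
paths = write_native(dataset, "scratch/example_study")

print(f"participants: {len(dataset)}")
first = dataset.participants[0]
print(f"first participant, bisensory SOA 0 trials: {first.av(0).n_total}")
print(f"catch-trial guess responses: {first.catch.finite.size} of "
      f"{first.catch.n_total} catch trials")
for name, path in paths.items():
    print(f"wrote {name}: {path}")
# The rt.csv file has one row per trial (misses are the token "inf");
# toj.csv has per-SOA counts of "visual first" responses; metadata.json
# records the generating parameters so analyses can be scored against truth.
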