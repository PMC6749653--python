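"""Curate raw pKa records and build the three modeling-set options.

Generates a synthetic record set (with salts, mixtures, inorganics and
replicates injected), standardizes it to QSAR-ready parent structures,
and shows how the replicate-handling options change the modeling sets.
"""

from pkaqsar import FixtureSpec, build_option_dataset, curate_records, generate_fixture

fx = generate_fixture(FixtureSpec(n_structures=150, seed=0))
print(f"raw records: {len(fx.records)}")

cur = curate_records(fx.records)
print(f"unique QSAR-ready structures: {cur.n_unique_structures}")
print(f"rejected: {cur.n_rejected}  (mixtures and carbon-free species)")
print(f"amphoteric structures (acidic AND basic pKa): {cur.n_amphoteric}")

for option in (1, 2, 3):
    sets = build_option_dataset(cur.groups, option)
    sizes = {name: len(ds) for name, ds in sets.items()}
    print(f"Option {option}: {sizes}")

# Option 1 keeps only single-measurement chemicals; Option 2 adds
# averaged replicates with SD < 2 pKa units; Option 3 keeps everything,
# averaging tight replicates (SD <= 1) and otherwise taking the
# strongest acidic (min) / basic (max) value.  The combined set
# (Options 1-2) excludes amphoterics, so it is smaller than acidic+basic.
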