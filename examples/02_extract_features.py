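"""Extract the five curve-shape features from each sensor channel.

Curves are normalized to their first resistance value R0; the features are
the response depth (delta R/R0), the exposure spike of the first derivative,
the area under the curve up to the extremum, the total area, and the 10-90%
fall (or rise) time.
"""

import moxnose as mx

manifest = mx.DesignManifest(
    rows=mx.build_manifest("published_counts").rows[:5], provenance="custom"
)
dataset = mx.simulate_dataset(manifest, seed=1)
table = mx.extract_table(dataset)

feature_cols = [c for c in table.columns if "." in c]
print(f"feature table: {table.shape[0]} replicas x {len(feature_cols)} features")

row = table.iloc[0]
print(f"replica {row.replica_id} ({row.seasoning}, {row.process}, {row.rind_pct}% rind):")
for col in feature_cols[:5]:
    print(f"  {col:<34} {row[col]: .4f}")
# delta_r is dimensionless, deriv_extremum is 1/s (negative for n-type
# channels), both areas are in seconds, transition_time is the 10-90% fall
# time in seconds.
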