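"""Generate a contaminated synthetic survey and cleanse it.

The generator plants duplicates, missing cells, out-of-range values, and
straight-line responders with recorded counts; the cleansing report should
recover exactly those counts.
"""

from climacop import SyntheticConfig, cleanse, generate_dataset, summarize

cfg = SyntheticConfig(n_respondents=656, seed=42)
ds, truth = generate_dataset(cfg)
print(f"emitted rows: {ds.n_respondents} "
      f"(clean {truth.clean_rows} + planted contamination)")

clean, report = cleanse(ds, ("duplicates", "missing", "out_of_range", "straight_line"))
print("cleansing report:", report.to_dict())
planted = {rule: len(idx) for rule, idx in truth.contamination_indices.items()}
print("planted counts:  ", planted)
# Each removal count matches what the generator planted; retained equals the
# clean block size.

print("\nage distribution of the retained sample:")
print(summarize(clean, "age").to_string(index=False))
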