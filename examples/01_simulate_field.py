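"""Generate a synthetic soybean breeding field and inspect its plots.

Builds a small orthomosaic-like image of four-row plots at a strong class
imbalance, prints the class histogram and a few plot records.
"""

from lodgetex import FieldConfig, generate_field

cfg = FieldConfig(
    class_counts={"NL": 40, "ML": 10, "HL": 5, "SL": 3}, rng_seed=42
)
img, records = generate_field(cfg)

hist = {c: sum(r.lodging_class == c for r in records) for c in ("NL", "ML", "HL", "SL")}
print(f"field image: {img.shape[0]} x {img.shape[1]} px, {len(records)} plots")
print("class histogram:", hist)
for rec in records[:3]:
    print(rec.plot_id, rec.bbox, "score", rec.score, "->", rec.lodging_class)

# The histogram equals the configured counts exactly; each record's class is
# determined by its visual score (1.0-1.5 NL ... 4.0-5.0 SL).
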