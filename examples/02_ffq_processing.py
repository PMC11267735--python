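"""Process raw questionnaire records: frequencies, quality, portions.

Ordinal frequency levels become intakes/day through the frequency mapping
(0 for "never" up to 4 for "4 times a day or more"); records are quality-
scored on the three-tier exclude scale; and portion photos / natural units /
sex-age medians yield per-category gram portions.
"""
import ffqval as fv

schema = fv.FFQSchema.default()
mapping = fv.FrequencyMapping.default()

# a hand-built record: everything answered "2-3 times a week" (level 5)
record = fv.FFQRecord(
    participant_id="demo",
    responses={i: 5 for i in schema.item_ids},
    portion_indications={"starch": 3, "protein": 2, "vegetable": 4},
)
freqs = fv.frequencies_to_daily(record, mapping, schema)
print(f"level 5 ('2-3 times a week') -> {freqs.iloc[0]:.4f} intakes/day "
      "(the 2.5/7 midpoint convention)")

quality = fv.assign_exclude_level(record, schema)
print(f"exclude level: {quality.exclude_level} "
      f"(0 = usable; missing fraction {quality.missing_fraction:.0%})")

profile = fv.ParticipantProfile(id="demo", sex="female", age=47,
                                height_cm=166, weight_kg=64)
portions = fv.assign_portion_sizes(record, fv.PortionTable.default(),
                                   profile, schema)
print(f"\nportion for 'veg_tomatoes' (vegetable plate, photo level 4): "
      f"{portions['veg_tomatoes']:.0f} g")
print(f"portion for 'egg_boiled_fried' (natural unit):            "
      f"{portions['egg_boiled_fried']:.0f} g")
print("Portions weight the frequencies when energy and nutrients are "
      "estimated (see example 05).")
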