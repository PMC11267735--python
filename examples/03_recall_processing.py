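"""Harmonise 24-hour recall days to the questionnaire's category space.

Each recall day lists consumed foods with gram amounts; foods map onto the
108 questionnaire categories, occasions are totalled across days and divided
by the number of completed days — the reference method's intakes/day.
"""
import ffqval as fv
from ffqval.recall import identity_map

schema = fv.FFQSchema.default()

days = [
    fv.RecallDay("demo", 1, (fv.RecallItem("bev_coffee", 300.0, occasions=2),
                             fv.RecallItem("wg_bread", 70.0, occasions=2))),
    fv.RecallDay("demo", 2, (fv.RecallItem("bev_coffee", 150.0, occasions=1),)),
    fv.RecallDay("demo", 3, ()),  # a fasting day still counts as completed
]
freqs = fv.recall_daily_frequencies(days, identity_map(schema), schema)
print(f"coffee: 3 occasions over 3 days -> {freqs['bev_coffee']:.2f} intakes/day")
print(f"wholegrain bread: 2 occasions over 3 days -> {freqs['wg_bread']:.3f}/day")

nutrients = fv.recall_nutrients(days, fv.FoodCompositionTable.default().table)
print(f"\nmean daily energy over the 3 days: {nutrients['energy_kcal']:.0f} kcal")

# the inclusion rule of the validation analysis: at least four completed days
dataset = fv.generate_cohort(100, seed=2)
kept, attrition = fv.inclusion_filter(dataset.participants, min_days=4)
print(f"\nattrition: {attrition.as_dict()} -> {len(kept)} analysable")
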