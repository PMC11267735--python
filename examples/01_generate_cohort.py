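"""Generate a synthetic validation study and look at its ground truth.

A validation study pairs a frequency questionnaire (administered twice) with
six repeated 24-hour recall days per participant.  The generator retains the
latent habitual diet of every participant, so downstream statistics can be
judged against a known truth.
"""
import ffqval as fv

dataset = fv.generate_cohort(n=244, seed=1)

print(f"participants: {len(dataset.participants)}")
print(dataset.participants.head(3))
days = dataset.participants["completed_recall_days"]
print(f"\ncompleted >=4 recall days: {(days >= 4).sum()} "
      f"(these form the validation group)")
print(f"completed all 6 days:     {(days == 6).sum()}")

cat = "bev_coffee"
truth = dataset.truth_freq[cat]
print(f"\ntrue habitual {cat}: median {truth.median():.2f} intakes/day, "
      f"never-consumers {(truth == 0).mean():.0%}")
print("The questionnaire and the recalls both observe this truth through "
      "their own error models; everything downstream estimates how well.")

# dataset.write_csvs("study_dir/") exports the five CSVs plus a data dictionary
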