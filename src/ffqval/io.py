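"""Reading a written study back into memory."""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ConfigurationError
from .schema import FFQSchema, FrequencyMapping
from .synth import ErrorModel, GeneratorConfig, StudyDataset


def read_study_csvs(
    directory,
    schema: FFQSchema | None = None,
    mapping: FrequencyMapping | None = None,
) -> StudyDataset:
    """Load the CSVs written by :meth:`StudyDataset.write_csvs`.

    The error model and generator config are not recoverable from the CSVs;
    the returned dataset carries defaults there (the data are what matter
    for analysis).
    """
    d = Path(directory)
    schema = schema or FFQSchema.default()
    mapping = mapping or FrequencyMapping.default()

    def read(name, index_col=None):
        path = d / name
        if not path.exists():
            raise ConfigurationError(f"study directory missing {name}")
        df = pd.read_csv(path)
        if index_col:
            df = df.set_index(index_col)
        return df

    participants = read("participants.csv", "participant_id")
    truth_freq = read("truth_frequencies.csv", "participant_id")
    truth_portion = read("truth_portions.csv", "participant_id")
    ffq_baseline = read("ffq_baseline.csv", "participant_id")
    ffq_repeat = read("ffq_repeat.csv", "participant_id")
    recalls = read("recalls.csv")

    from .nutrients import FoodCompositionTable, estimate_nutrients

    truth_energy = estimate_nutrients(
        truth_freq, truth_portion, FoodCompositionTable.default()
    )["energy_kcal"]
    return StudyDataset(
        participants=participants,
        ffq_baseline=ffq_baseline,
        ffq_repeat=ffq_repeat,
        recalls=recalls,
        truth_freq=truth_freq,
        truth_portion=truth_portion,
        truth_energy=truth_energy,
        seed=-1,
        schema=schema,
        mapping=mapping,
        error_model=ErrorModel(),
        config=GeneratorConfig(),
    )
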