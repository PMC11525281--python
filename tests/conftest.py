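import numpy as np
import pandas as pd
import pytest

from formantkit import FormantTable, SyntheticConfig, concat_tables, generate_population


@pytest.fixture
def printed_token_wide(tmp_path):
    """Wide CSV with the two example tokens (one has a missing F3)."""
    path = tmp_path / "tokens.csv"
    pd.DataFrame(
        {
            "vowel": ["had", "cot"],
            "f1": [564, 931],
            "f2": [2442, 1348],
            "f3": [None, 2698],
            "f4": [4038, 4540],
        }
    ).to_csv(path, index=False)
    return path


@pytest.fixture
def two_speaker_doubled():
    """Two speakers, the second with all frequencies exactly doubled."""
    base = [500.0, 1500.0, 2500.0, 3500.0]
    parts = []
    for vowel, mult in [("a", 1.0), ("e", 1.1), ("o", 0.95)]:
        for sp, scale in [("s1", 1.0), ("s2", 2.0)]:
            parts.append(
                FormantTable.from_formants(
                    [f * scale * mult for f in base],
                    token=f"{sp}_{vowel}",
                    speaker=sp,
                    vowel=vowel,
                )
            )
    return concat_tables(parts)


@pytest.fixture(scope="session")
def recovery_population():
    """30 cylindrical-ish speakers x 8 vowels x 4 formants, tau ~ 0.10."""
    return generate_population(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def two_group_populations():
    """Two populations with disjoint VTL ranges (9-11 cm vs 16-18 cm)."""
    child, _ = generate_population(
        SyntheticConfig(n_speakers=20, vtl_range_cm=(9, 11), group="child",
                        speaker_prefix="c", seed=11)
    )
    man, _ = generate_population(
        SyntheticConfig(n_speakers=20, vtl_range_cm=(16, 18), group="man",
                        speaker_prefix="m", seed=12)
    )
    return concat_tables([child, man])
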