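import pandas as pd
import pytest
from hypothesis import settings

from smorfkit.denovo import PeptideRecord, split_modifications
from smorfkit.simulate import FixtureConfig, generate_bundle

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def records_from_table(df: pd.DataFrame) -> list[PeptideRecord]:
    """Convert a generated de novo table into PeptideRecords."""
    out = []
    for _, row in df.iterrows():
        seq, mods = split_modifications(str(row["Peptide"]))
        out.append(
            PeptideRecord(
                sequence=seq,
                alc=float(row["ALC (%)"]),
                neg10lgp=float(row["-10lgP"]),
                modifications=mods,
            )
        )
    return out


@pytest.fixture(scope="session")
def bundle():
    """Default fixture bundle: planted SEPs, noisy peptides, all class codes."""
    return generate_bundle(FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def zero_noise_bundle():
    """Fixture with no decoy peptides (clean truth-recovery conditions)."""
    return generate_bundle(FixtureConfig(seed=7, peptide_noise=0.0))
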