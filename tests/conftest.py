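import numpy as np
import pytest
from hypothesis import settings

from targetprops import synthetic_data as synth
from targetprops.ingest import ProteinRecord

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def separable_table():
    """Two well-separated classes: strong informative features, light noise."""
    return synth.gen_feature_table(
        synth.SyntheticTableConfig(
            n_pos=100,
            n_unl=100,
            features=[
                synth.FeatureSpec("sig_a", 0.95),
                synth.FeatureSpec("sig_b", 0.95),
                synth.FeatureSpec("sig_c", 0.9),
            ],
            n_noise_features=5,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def moderate_table():
    """Moderate effect sizes with noise: a realistic classification task."""
    return synth.gen_feature_table(
        synth.SyntheticTableConfig(
            n_pos=100,
            n_unl=100,
            features=[synth.FeatureSpec(f"sig_{k}", 0.75) for k in range(3)],
            n_noise_features=7,
            seed=7,
        )
    )


def random_protein_record(rng: np.random.Generator, index: int) -> ProteinRecord:
    length = int(rng.integers(30, 80))
    alphabet = list("ACDEFGHIKLMNPQRSTVWYBJZX")
    sequence = "".join(rng.choice(alphabet, size=length))
    n_secondary = int(rng.integers(0, 3))
    partners = {f"PART{int(rng.integers(0, 50)):03d}"
                for _ in range(int(rng.integers(0, 4)))}
    keywords = set(
        rng.choice(["KW-0297", "KW-1071", "KW-0418", "KW-0031", "KW-9999"],
                   size=int(rng.integers(0, 3)), replace=False)
    )
    return ProteinRecord(
        representative_accession=f"P{index:05d}",
        secondary_accessions=[f"Q{index:05d}{k}" for k in range(n_secondary)],
        name=f"PROT{index}_HUMAN",
        sequence=sequence,
        has_signal_peptide=bool(rng.integers(0, 2)),
        n_glyc_sites=int(rng.integers(0, 5)),
        o_glyc_sites=int(rng.integers(0, 3)),
        phospho_ser=int(rng.integers(0, 6)),
        phospho_thr=int(rng.integers(0, 4)),
        phospho_tyr=int(rng.integers(0, 3)),
        tm_helices=int(rng.integers(0, 8)),
        binary_ppi_partners=partners,
        keywords=keywords,
    )


@pytest.fixture
def random_records():
    rng = np.random.default_rng(42)
    return [random_protein_record(rng, i) for i in range(10)]
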