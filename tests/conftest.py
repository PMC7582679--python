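import numpy as np
import pytest

from targetfish.compounds import CompoundRecord, FingerprintConfig, fingerprint, standardize
from targetfish.simulate import FixtureSpec, generate_decoy_pool, generate_fixture


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    """Desk-scale fixture: 20 compounds, 12 targets (3 planted, 2 confusers)."""
    return FixtureSpec(
        seed=7,
        n_compounds=20,
        n_targets=12,
        n_planted_targets=3,
        n_confuser_targets=2,
        ligands_per_target=5,
        decoy_pool_size=60,
    )


@pytest.fixture(scope="session")
def small_fixture_dir(small_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    paths = generate_fixture(small_spec, out)
    return out, paths


@pytest.fixture(scope="session")
def circular_fp():
    """SMILES -> circular fingerprint (2048 bits), standardizing first."""
    cfg = FingerprintConfig()

    def fp(smiles: str) -> np.ndarray:
        rec = standardize(CompoundRecord("q", smiles, ""))
        return fingerprint(rec, cfg).circular_fp

    return fp


@pytest.fixture(scope="session")
def decoy_pool_fps(circular_fp):
    """Fingerprints of a 150-molecule decoy pool (family-clustered)."""
    pool = generate_decoy_pool(FixtureSpec(seed=11, decoy_pool_size=150))
    return np.stack([circular_fp(s) for s in pool])
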