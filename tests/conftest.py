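import numpy as np
import pandas as pd
import pytest

from neoedit import (
    AlleleFrequencyTable,
    MotifPredictor,
    SimulationConfig,
    aggregate_variant_allele,
    call_silent,
    windows_frame,
)
from neoedit.simulate import make_panel, make_proteome, make_variants


@pytest.fixture(scope="session")
def sim_config():
    """Small study conditions shared across tests; seed fixed once."""
    return SimulationConfig(
        seed=1234,
        n_alleles_per_locus=4,
        n_proteins=2,
        protein_length=(60, 120),
        n_variants=40,
        n_patients=150,
        background_size=20_000,
    )


@pytest.fixture(scope="session")
def panel(sim_config):
    alleles, freqs = make_panel(sim_config)
    return alleles, freqs


@pytest.fixture(scope="session")
def predictor(sim_config, panel):
    alleles, _ = panel
    return MotifPredictor(alleles, background_size=sim_config.background_size)


@pytest.fixture(scope="session")
def freqs(panel):
    return panel[1]


@pytest.fixture(scope="session")
def small_study(sim_config, predictor, freqs):
    """Proteome, variants, windows, summary grid and presentation map."""
    rng = np.random.default_rng(sim_config.seed + 1)
    proteome = make_proteome(sim_config, rng)
    variants = make_variants(proteome, sim_config.n_variants, rng)
    windows = windows_frame(proteome, variants)
    records = predictor.predict(sorted(windows["mutant"].unique()))
    summaries = aggregate_variant_allele(windows, records)
    pmap = call_silent(summaries, freqs)
    return {
        "proteome": proteome,
        "variants": variants,
        "windows": windows,
        "records": records,
        "summaries": summaries,
        "pmap": pmap,
    }


@pytest.fixture()
def uniform_freqs():
    """Hand-built frequency table with easy closed forms."""
    return AlleleFrequencyTable(
        pd.DataFrame(
            {
                "allele": ["A*01:01", "A*02:01", "B*01:01", "B*02:01", "C*01:01"],
                "locus": ["A", "A", "B", "B", "C"],
                "frequency": [0.5, 0.1, 0.1, 0.2, 0.3],
            }
        )
    )
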