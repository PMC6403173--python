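import numpy as np
import pytest

from proteoclust.model import Organism, ProteinRecord, ProteomeSet
from proteoclust.simulate import (CORRUPTION_MODES, SimulationConfig,
                                  generate_pan_proteome)

ZERO_RATES = {m: 0.0 for m in CORRUPTION_MODES}


def make_record(seq_id="s1", organism_id="org1", replicon_id="chr",
                replicon_type="chromosome", start=1, end=None, strand="+",
                annotation="protein", sequence="MKVLITGAGG"):
    if end is None:
        end = start + 3 * len(sequence) - 1
    return ProteinRecord(seq_id=seq_id, organism_id=organism_id,
                         replicon_id=replicon_id, replicon_type=replicon_type,
                         start=start, end=end, strand=strand,
                         annotation=annotation, sequence=sequence)


def make_proteome(records):
    orgs = {r.organism_id: Organism(organism_id=r.organism_id, name=r.organism_id)
            for r in records}
    return ProteomeSet(organisms=orgs, records={r.seq_id: r for r in records})


def random_protein(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


@pytest.fixture(scope="session")
def clean_sim():
    """Corruption-free synthetic pan-proteome: 20 organisms x 10 families."""
    cfg = SimulationConfig(n_organisms=20, n_families=10,
                           corruption_rates=dict(ZERO_RATES), rng_seed=11)
    return generate_pan_proteome(cfg)


@pytest.fixture(scope="session")
def small_clean_sim():
    """Smaller corruption-free set for faster end-to-end checks."""
    cfg = SimulationConfig(n_organisms=6, n_families=4,
                           family_length_range=(120, 250),
                           corruption_rates=dict(ZERO_RATES), rng_seed=5)
    return generate_pan_proteome(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
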