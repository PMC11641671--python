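import numpy as np
import pandas as pd
import pytest

from lipidstats import quantmatrix as qm
from lipidstats import synthetic_data as sd


@pytest.fixture(scope="session")
def default_sim():
    """One full draw of the study-design default dataset."""
    return sd.generate(sd.default_study_config(seed=1))


@pytest.fixture(scope="session")
def hippo_molpct(default_sim):
    return qm.to_molpct(qm.apply_lod(default_sim.matrices["hippocampus"]))


@pytest.fixture(scope="session")
def plasma_molpct(default_sim):
    return qm.to_molpct(qm.apply_lod(default_sim.matrices["plasma"]))


@pytest.fixture
def toy_tables(tmp_path):
    """A 3-species x 2-sample quant table plus matching metadata."""
    quant = tmp_path / "quant.csv"
    quant.write_text(
        "species,s1,s2\n"
        "LPE 18:1,1.0,2.0\n"
        "PC 34:1,3.0,4.0\n"
        "TAG 52:2,5.0,6.0\n"
    )
    meta = tmp_path / "meta.csv"
    meta.write_text(
        "sample_id,animal_id,tissue,arm\n"
        "s1,a1,plasma,CONTROL\n"
        "s2,a2,plasma,CORT\n"
    )
    return quant, meta


def make_matrix(values, species_names, arms, lod=0.0, tissue="plasma"):
    """Build a QuantMatrix from a plain array (samples x species)."""
    from lipidstats.nomenclature import parse_species
    from lipidstats.quantmatrix import ARMS, QuantMatrix, SampleMeta

    values = np.asarray(values, dtype=float)
    sample_ids = [f"s{i}" for i in range(values.shape[0])]
    samples = [
        SampleMeta(sid, f"a{i}", tissue, ARMS[arm])
        for i, (sid, arm) in enumerate(zip(sample_ids, arms))
    ]
    amounts = pd.DataFrame(
        values, index=pd.Index(sample_ids, name="sample_id"), columns=species_names
    )
    return QuantMatrix(
        amounts=amounts,
        samples=samples,
        species=[parse_species(n) for n in species_names],
        lod=lod,
    )
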