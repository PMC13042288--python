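import numpy as np
import pytest

import malines as m


@pytest.fixture(scope="session")
def default_experiment():
    """One default-scale synthetic experiment shared across tests."""
    return m.generate_experiment(m.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_pipeline(default_experiment):
    exp = default_experiment
    return m.run_pipeline(
        exp.records,
        exp.sv_records,
        exp.te_calls,
        exp.line_meta,
        gene_track=exp.gene_track,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_variant_record(rng, panel, contig="2L", position=None):
    """A single random but valid VariantRecord over the given panel."""
    bases = "ACGT"
    ref = bases[rng.integers(4)]
    alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
    position = position or int(rng.integers(1, 1_000_000))
    annotations = {
        "MQ": round(float(rng.uniform(30, 60)), 3),
        "QD": round(float(rng.uniform(0, 35)), 3),
        "FS": round(float(rng.uniform(0, 100)), 3),
        "SOR": round(float(rng.uniform(0, 6)), 3),
        "MQRankSum": round(float(rng.uniform(-12, 12)), 3),
        "ReadPosRankSum": round(float(rng.uniform(-8, 8)), 3),
    }
    # randomly drop some annotations to exercise missing handling
    for key in list(annotations):
        if rng.random() < 0.1:
            del annotations[key]
    calls = {}
    for line in panel:
        g = rng.random()
        depth = int(rng.integers(10, 250))
        if g < 0.75:
            calls[line] = m.LineCall(m.Genotype.HOM_REF, 0, depth)
        elif g < 0.85:
            calls[line] = m.LineCall(
                m.Genotype.HET, int(rng.integers(0, depth + 1)), depth
            )
        elif g < 0.95:
            calls[line] = m.LineCall(m.Genotype.HOM_ALT, depth, depth)
        else:
            calls[line] = m.LineCall(m.Genotype.MISSING, 0, 0)
    return m.VariantRecord(
        contig=contig,
        position=position,
        ref_allele=ref,
        alt_allele=alt,
        site_annotations=annotations,
        per_line_calls=calls,
    )
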