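import numpy as np
import pandas as pd
import pytest

import mirsea as ms


@pytest.fixture(scope="session")
def layout():
    return ms.make_default_layout()


@pytest.fixture(scope="session")
def toy_ranked():
    """A 10-miRNA ranked list with distinct descending scores."""
    names = [f"m{i}" for i in range(1, 11)]
    return ms.RankedList(names=names, scores=np.arange(10.0, 0.0, -1.0))


@pytest.fixture(scope="session")
def planted_experiment(layout):
    """One simulated panel run with a planted up-regulated 5-member set."""
    planted = ms.PlantedSet(
        "planted-up",
        ("hsa-mir-182", "hsa-mir-214", "hsa-mir-100", "hsa-mir-9", "hsa-mir-21"),
        "up",
    )
    cfg = ms.SimulationConfig(
        n_samples_per_condition=3,
        n_de_mirnas=0,
        de_effect_size=2.0,
        planted_sets=(planted,),
        seed=11,
    )
    return ms.simulate_experiment(layout, cfg)


@pytest.fixture(scope="session")
def planted_cq(planted_experiment):
    return ms.interplate_calibrate(ms.call_cq_table(planted_experiment.curves))


@pytest.fixture(scope="session")
def planted_matrix(planted_experiment, planted_cq):
    return ms.normalize_delta_cq(planted_cq, planted_experiment.conditions)


@pytest.fixture()
def cq_records():
    """Hand-built Cq records: 2 plates, calibrators offset by 1.0 cycle."""
    rows = []
    for sample, plate, off in [("s1", "p1", 0.0), ("s2", "p2", 1.0)]:
        for i, cal in enumerate(["ipc1", "ipc2", "ipc3"]):
            rows.append((sample, plate, cal, "interplate_calibrator", 20.0 + off))
        for ref in ["ref1", "ref2"]:
            rows.append((sample, plate, ref, "reference_gene", 19.0 + off))
        for spike in ["sp1", "sp2"]:
            rows.append((sample, plate, spike, "spike_in", 21.0 + off))
        rows.append((sample, plate, "hsa-mir-1", "mirna_assay", 25.0 + off))
        rows.append((sample, plate, "hsa-mir-2", "mirna_assay", 24.0 + off))
    return pd.DataFrame(rows, columns=["sample_id", "plate_id", "assay_name", "well_class", "cq"])
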