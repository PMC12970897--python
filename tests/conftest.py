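import numpy as np
import pandas as pd
import pytest

from pvsignal import GeneratorConfig, SignalSpec, generate

EGPA = "Eosinophilic granulomatosis with polyangiitis"


def small_config(**overrides) -> GeneratorConfig:
    """Compact study-like config: one strong planted pair, modest vocab."""
    cfg = GeneratorConfig(
        n_reports=overrides.pop("n_reports", 20_000),
        drugs={
            "montelukast": 0.02,
            "zafirlukast": 0.005,
            "fluticasone": 0.03,
            "amoxicillin": 0.05,
        },
        events={EGPA: 0.0008, "Headache": 0.05, "Nausea": 0.06},
        signals=[
            SignalSpec("montelukast", EGPA, target_rr=50.0, tto_scale=391.08, tto_shape=0.76)
        ],
        seed=overrides.pop("seed", 0),
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture(scope="session")
def planted_dataset():
    """One deduplicated synthetic database with a strong montelukast-EGPA pair."""
    from pvsignal import deduplicate

    ds, truth = generate(small_config(seed=11))
    ds, _ = deduplicate(ds)
    return ds, truth


def write_faers_fixture(tmpdir, demo_rows, drug_rows, reac_rows, ther_rows=None,
                        indi_rows=None, outc_rows=None):
    """Write minimal $-delimited FAERS-style tables from row dicts."""
    import csv
    from pathlib import Path

    tmpdir = Path(tmpdir)

    def dump(name, rows, columns):
        with open(tmpdir / name, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=columns, delimiter="$")
            w.writeheader()
            w.writerows(rows)

    dump("DEMO.txt", demo_rows, list(demo_rows[0].keys()))
    dump("DRUG.txt", drug_rows, list(drug_rows[0].keys()))
    dump("REAC.txt", reac_rows, list(reac_rows[0].keys()))
    if ther_rows:
        dump("THER.txt", ther_rows, list(ther_rows[0].keys()))
    if indi_rows:
        dump("INDI.txt", indi_rows, list(indi_rows[0].keys()))
    if outc_rows:
        dump("OUTC.txt", outc_rows, list(outc_rows[0].keys()))
    return tmpdir
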