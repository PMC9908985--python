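import json
from pathlib import Path

import pytest

from foldassign import synthetic
from foldassign.pipeline import RunConfig, run
from foldassign.quality import Thresholds, calibrate_thresholds, qc_verdict


@pytest.fixture(scope="session")
def compact_bundle():
    return synthetic.make_bundle(3, 18, 8.5, protein_id="bundle")


@pytest.fixture(scope="session")
def helix20():
    return synthetic.make_ideal_helix(20)


@pytest.fixture(scope="session")
def sheet():
    return synthetic.make_sheet(4, 10)


@pytest.fixture(scope="session")
def decoy60():
    return synthetic.make_decoy(60, seed=1)


@pytest.fixture(scope="session")
def calibrated_thresholds():
    """Globularity cuts calibrated on the synthetic reference battery."""
    reports = [qc_verdict(m) for m in synthetic.make_reference_battery(0)]
    return calibrate_thresholds(reports)


@pytest.fixture(scope="session")
def e2e_inputs(tmp_path_factory):
    """One complete synthetic input set shared by pipeline-level tests."""
    root = tmp_path_factory.mktemp("e2e")
    truth = synthetic.make_end_to_end_inputs(root, seed=7)
    thresholds = Thresholds(**json.loads((root / "thresholds.json").read_text()))
    return {"root": Path(root), "truth": truth, "thresholds": thresholds}


def e2e_config(inputs: dict, out_dir: Path, **overrides) -> RunConfig:
    root = inputs["root"]
    defaults = dict(
        models_dir=str(root / "models"),
        hits_path=str(root / "hits.tsv"),
        out_dir=str(out_dir),
        predictions_path=str(root / "predictions.tsv"),
        library_manifest=str(root / "library.tsv"),
        pdb_unclassified_manifest=str(root / "pdb_unclassified.tsv"),
        thresholds=inputs["thresholds"],
        seed=7,
    )
    defaults.update(overrides)
    return RunConfig(**defaults)


@pytest.fixture(scope="session")
def e2e_run(e2e_inputs, tmp_path_factory):
    """One full pipeline run over the shared synthetic inputs."""
    out = tmp_path_factory.mktemp("e2e_out")
    summary = run(e2e_config(e2e_inputs, out))
    return {"summary": summary, "out": Path(out), "inputs": e2e_inputs}
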