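import pandas as pd
import pytest

from tcrphys import SimulationConfig, generate_repertoire, make_fixtures


@pytest.fixture(scope="session")
def small_sim():
    """A small (150 cells/condition) simulated repertoire with its ledger."""
    config = SimulationConfig(seed=42, n_cells=150, n_samples_per_condition=2)
    rep, ledger = generate_repertoire(config)
    return rep, ledger


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """On-disk fixture files (10x CSV, AIRR TSV, metadata, ground truth)."""
    out = tmp_path_factory.mktemp("fixtures")
    rep, ledger = make_fixtures(out, seed=1234)
    return out, rep, ledger


def toy_records(rows):
    """Build a records DataFrame from (barcode, chain, v, j, nt, aa, umis,
    sample, condition, subset) tuples."""
    cols = [
        "barcode", "chain", "v_gene", "j_gene", "cdr3_nt", "cdr3_aa",
        "umis", "sample_id", "condition", "subset",
    ]
    df = pd.DataFrame(rows, columns=cols)
    df["productive"] = True
    return df
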