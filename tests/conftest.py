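import numpy as np
import pandas as pd
import pytest

from evpipe.localization_io import LOC_COLUMNS, AcquisitionMetadata, LocalizationTable


def make_table(rows, fov_extent_nm=None):
    """Localization table from (frame, x, y, channel) tuples."""
    df = pd.DataFrame(rows, columns=["frame", "x", "y", "channel"])
    df["photons"] = np.nan
    df.insert(0, "id", np.arange(len(df), dtype=np.int64))
    if len(df):
        df["frame"] = df["frame"].astype(np.int64)
        df["channel"] = df["channel"].astype(np.int64)
    else:
        df = pd.DataFrame(
            {c: pd.Series(dtype=float if c in ("x", "y", "photons") else "int64")
             for c in LOC_COLUMNS}
        )
    return LocalizationTable(df=df[LOC_COLUMNS],
                             metadata=AcquisitionMetadata(fov_extent_nm=fov_extent_nm))


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture(scope="session")
def default_sim():
    """One moderately sized labelled imaging simulation shared across tests."""
    from evpipe.cli_pipeline import load_config, process_localizations
    from evpipe.synthetic_data import ImagingSimConfig, simulate_imaging

    cfg = load_config()
    table, truth = simulate_imaging(ImagingSimConfig(n_ev=300, n_aggregate=60, seed=11))
    res = process_localizations(table, cfg)
    return {"cfg": cfg, "table": table, "truth": truth, **res}
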