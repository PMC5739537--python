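"""The packaged 33-complex retrospective benchmark table.

One row per antibody-antigen co-crystal complex (PDB id): antigen residue
counts (whole chain / surface / curated epitope), the number of variant
designs needed to cover all docking models when designing against the
antigen crystal structure vs. a homology model, the quality of the closest
native-like docking model (CAPRI f_nat), homology-model quality (TM-score),
the number of docking decoys, and localization success flags under both
epitope definitions (curated list vs. 5 A binding interface) for both
antigen structure sources.  Shipped as a plain CSV regression fixture for
the summary statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_FLAG_COLUMNS = [
    "success_iedb_crystal", "success_interface_crystal",
    "success_iedb_model", "success_interface_model",
]


def packaged_retrospective() -> pd.DataFrame:
    """Load the packaged 33-row benchmark table.

    Success flags are parsed from T/F into booleans; PDB ids are the index
    order of the original table.
    """
    ref = resources.files("episcope.data").joinpath("retrospective_cases.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    for col in _FLAG_COLUMNS:
        df[col] = df[col].map({"T": True, "F": False})
        if df[col].isna().any():
            raise ValueError(f"bad success flag in column {col}")
    if len(df) != 33:
        raise ValueError(f"expected 33 rows, found {len(df)}")
    return df
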