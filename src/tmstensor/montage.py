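"""61-channel EEG montage handling.

The analysis only needs a 2D scalp layout (label, x, y) to build spatially
smooth component topographies, so the montage is a schematic 10-10-style
disc projection rather than digitised electrode positions: rows of the
extended international system placed on a unit-radius head outline.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

# Rows of the extended 10-20 ("10-10") system, front to back, 61 channels
# in total once earlobe/mastoid sites are excluded.
_ROWS: list[list[str]] = [
    ["Fp1", "Fpz", "Fp2"],
    ["AF7", "AF3", "AFz", "AF4", "AF8"],
    ["F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"],
    ["FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8"],
    ["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"],
    ["TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8"],
    ["P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8"],
    ["PO7", "PO3", "POz", "PO4", "PO8"],
    ["O1", "Oz", "O2"],
]


def generate_1010_montage() -> pd.DataFrame:
    """Build the schematic 61-channel layout.

    Returns a DataFrame with columns ``label``, ``x``, ``y`` in head radii;
    +y is anterior, +x is the subject's right.
    """
    rows = []
    n_rows = len(_ROWS)
    ys = np.linspace(0.95, -0.95, n_rows)
    for labels, y in zip(_ROWS, ys):
        n = len(labels)
        # lateral extent shrinks toward the front/back poles and for the
        # short (5- and 3-electrode) rows
        half_width = 0.92 * np.sqrt(max(1.0 - y * y, 0.0)) * (n - 1) / 8.0
        xs = np.linspace(-half_width, half_width, n) if n > 1 else np.array([0.0])
        for label, x in zip(labels, xs):
            rows.append((label, round(float(x), 4), round(float(y), 4)))
    return pd.DataFrame(rows, columns=["label", "x", "y"])


def load_montage(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited montage file with columns label/x/y."""
    df = pd.read_csv(path, sep="\t", dtype={"label": str})
    missing = {"label", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"montage file missing columns: {sorted(missing)}")
    if df["label"].duplicated().any():
        dupes = df.loc[df["label"].duplicated(), "label"].tolist()
        raise ValueError(f"duplicate channel labels in montage: {dupes}")
    return df[["label", "x", "y"]]


def default_montage() -> pd.DataFrame:
    """The packaged 61-channel layout."""
    ref = importlib.resources.files("tmstensor") / "data" / "montage61.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_montage(path)


def subset_montage(montage: pd.DataFrame, n_channels: int) -> pd.DataFrame:
    """Evenly thinned montage for reduced-size simulations.

    Always retains the full set when ``n_channels`` equals the montage size.
    """
    if not 1 <= n_channels <= len(montage):
        raise ValueError(
            f"n_channels={n_channels} outside 1..{len(montage)}"
        )
    idx = np.unique(np.round(np.linspace(0, len(montage) - 1, n_channels)).astype(int))
    return montage.iloc[idx].reset_index(drop=True)
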