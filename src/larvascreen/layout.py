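"""96-well plate layouts for the larval-size modifier screen.

The screen format is fixed: 8 rows (A-H) x 12 columns. Column 1 holds the
negative control (mutant homozygotes on 0.1% v/v DMSO vehicle), columns 2-11
hold the 80 test compounds (homozygotes, compound + 0.1% DMSO), wells A12-F12
hold positive control group 1 (heterozygotes + 0.1% DMSO) and G12-H12 hold
positive control group 2 (homozygotes without DMSO).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

N_ROWS = 8
N_COLS = 12
ROW_LABELS = "ABCDEFGH"


class Role(str, Enum):
    """Role of a well on a screening plate."""

    NEG = "NEG"
    TEST = "TEST"
    POS1 = "POS1"
    POS2 = "POS2"


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> plate address such as 'A1' (A1 at top-left)."""
    if not (0 <= row < N_ROWS and 0 <= col < N_COLS):
        raise ValueError(f"well ({row},{col}) outside the 8x12 grid")
    return f"{ROW_LABELS[row]}{col + 1}"


@dataclass
class PlateLayout:
    """Role, compound identity, dose, and vehicle level for all 96 wells.

    ``table`` has one row per well with columns:
    row, col, well, role, compound_id, substance, dose_uM, dmso_pct, genotype.
    """

    plate_id: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"row", "col", "well", "role", "compound_id", "substance",
                    "dose_uM", "dmso_pct", "genotype"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"layout table missing columns: {sorted(missing)}")
        if len(self.table) != N_ROWS * N_COLS:
            raise ValueError("a plate layout must describe exactly 96 wells")
        keys = set(zip(self.table["row"], self.table["col"]))
        if len(keys) != N_ROWS * N_COLS:
            raise ValueError("duplicate or missing well addresses in layout")

    def wells(self, role: Role | str | None = None) -> pd.DataFrame:
        """Rows of the layout table, optionally restricted to one role."""
        if role is None:
            return self.table
        role = Role(role)
        return self.table[self.table["role"] == role.value]

    @property
    def n_test_wells(self) -> int:
        return int((self.table["role"] == Role.TEST.value).sum())

    def to_json(self, path) -> None:
        records = self.table.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump({"plate_id": self.plate_id, "wells": records}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PlateLayout":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(payload["plate_id"], pd.DataFrame(payload["wells"]))


def default_screen_layout(
    plate_id: str,
    compounds: list[tuple[str, str]] | None = None,
    dose_uM: float = 10.0,
    dmso_pct: float = 0.1,
) -> PlateLayout:
    """Build the standard screening layout for one plate.

    Parameters
    ----------
    compounds
        Up to 80 ``(compound_id, substance)`` pairs filled into columns 2-11
        in row-major order. Unused test wells keep an empty compound id.
    dose_uM
        Library compound concentration in the test wells.
    dmso_pct
        Vehicle concentration (% v/v) in NEG, TEST and POS1 wells.
    """
    compounds = list(compounds or [])
    if len(compounds) > 80:
        raise ValueError("at most 80 test compounds fit on one plate")
    rows = []
    k = 0
    for r in range(N_ROWS):
        for c in range(N_COLS):
            entry = {
                "row": r, "col": c, "well": well_name(r, c),
                "compound_id": "", "substance": "", "dose_uM": 0.0,
            }
            if c == 0:
                entry.update(role=Role.NEG.value, dmso_pct=dmso_pct, genotype="hom")
            elif c < 11:
                cid, sub = compounds[k] if k < len(compounds) else ("", "")
                k += 1
                entry.update(role=Role.TEST.value, compound_id=cid, substance=sub,
                             dose_uM=dose_uM if cid else 0.0,
                             dmso_pct=dmso_pct, genotype="hom")
            elif r < 6:  # A12-F12
                entry.update(role=Role.POS1.value, dmso_pct=dmso_pct, genotype="het")
            else:  # G12, H12
                entry.update(role=Role.POS2.value, dmso_pct=0.0, genotype="hom")
            rows.append(entry)
    return PlateLayout(plate_id, pd.DataFrame(rows))
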