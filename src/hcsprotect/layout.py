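"""384-well plate layouts for an arrayed miRNA-mimic screen.

A screening plate carries four well roles:

* ``dark_control`` — untransfected wells shielded from the light stress
  (first two columns); they verify that the stress was effective.
* ``light_control`` — untransfected, light-exposed wells (last two
  columns); their percent-dying distribution is the reference for the
  per-plate Z score.
* ``transfection_control`` — wells transfected with a fluorophore-labelled
  non-targeting mimic, used to estimate transfection efficiency.
* ``sample`` — wells transfected with one library miRNA mimic each.

The default geometry is a 16 x 24 plate with 320 sample wells (columns
3-22).  Each biological replicate reuses the same miRNA-to-well map, so a
library of N miRNAs occupies ``ceil(N / 320)`` plates per replicate.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLE_DARK = "dark_control"
ROLE_LIGHT = "light_control"
ROLE_TRANSFECTION = "transfection_control"
ROLE_SAMPLE = "sample"
ROLE_EMPTY = "empty"
ROLES = (ROLE_DARK, ROLE_LIGHT, ROLE_TRANSFECTION, ROLE_SAMPLE, ROLE_EMPTY)

ROW_LETTERS = string.ascii_uppercase


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> 'A01'-style well name."""
    return f"{ROW_LETTERS[row]}{col + 1:02d}"


def parse_well(name: str) -> tuple[int, int]:
    """'A01'-style name -> 0-based (row, col)."""
    return ROW_LETTERS.index(name[0]), int(name[1:]) - 1


@dataclass(frozen=True)
class LayoutSpec:
    """Geometry of one screening plate.

    ``dark_cols`` / ``light_cols`` are 0-based column indices; defaults put
    dark controls in the first two and light controls in the last two
    columns.  ``n_transfection`` wells are carved out of the top of the
    last light-control column.
    """

    n_rows: int = 16
    n_cols: int = 24
    dark_cols: tuple[int, ...] = (0, 1)
    light_cols: tuple[int, ...] = (22, 23)
    n_transfection: int = 8

    @property
    def sample_cols(self) -> tuple[int, ...]:
        ctrl = set(self.dark_cols) | set(self.light_cols)
        return tuple(c for c in range(self.n_cols) if c not in ctrl)

    @property
    def sample_capacity(self) -> int:
        return self.n_rows * len(self.sample_cols)

    def validate(self) -> None:
        if not self.light_cols:
            raise ValueError("layout has no light-control columns; "
                             "Z scoring against light controls is impossible")
        if set(self.dark_cols) & set(self.light_cols):
            raise ValueError("dark and light control columns overlap")
        if self.n_transfection > self.n_rows * len(self.light_cols) - 2:
            raise ValueError("transfection controls would leave fewer than "
                             "two light-control wells")


@dataclass(frozen=True)
class PlateLayout:
    """Role and miRNA assignment of every well on one plate."""

    plate_id: str
    replicate_index: int
    n_rows: int = 16
    n_cols: int = 24
    role_map: dict[str, str] = field(default_factory=dict)
    mirna_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for well, role in self.role_map.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} at {well}")
        for well in self.mirna_map:
            if self.role_map.get(well) != ROLE_SAMPLE:
                raise ValueError(f"miRNA assigned to non-sample well {well}")
        samples = self.wells_with_role(ROLE_SAMPLE)
        missing = set(samples) - set(self.mirna_map)
        if missing:
            raise ValueError(f"sample wells without a miRNA: {sorted(missing)}")

    def wells_with_role(self, role: str) -> list[str]:
        return sorted(w for w, r in self.role_map.items() if r == role)

    @property
    def n_light_controls(self) -> int:
        return len(self.wells_with_role(ROLE_LIGHT))


def generate_layout(
    n_mirnas: int,
    replicate_count: int,
    seed: int,
    *,
    mirna_ids: list[str] | None = None,
    spec: LayoutSpec = LayoutSpec(),
    shuffle: bool = True,
) -> list[PlateLayout]:
    """Lay a miRNA library out on replicated 384-well plates.

    Returns ``ceil(n_mirnas / capacity) * replicate_count`` plates.  The
    assignment of miRNAs to (plate, well) positions is drawn once from
    ``seed`` and reused across replicates, so every miRNA occupies the
    same position on each replicate plate and appears exactly once per
    replicate.
    """
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    if replicate_count < 1:
        raise ValueError("replicate_count must be >= 1")
    spec.validate()
    if mirna_ids is None:
        mirna_ids = [f"syn-miR-{i + 1:04d}" for i in range(n_mirnas)]
    elif len(mirna_ids) != n_mirnas:
        raise ValueError("mirna_ids length disagrees with n_mirnas")
    if len(set(mirna_ids)) != n_mirnas:
        raise ValueError("duplicate miRNA identifiers")

    rng = np.random.default_rng(seed)
    order = np.array(mirna_ids, dtype=object)
    if shuffle:
        order = rng.permutation(order)

    n_plates = math.ceil(n_mirnas / spec.sample_capacity)

    # Transfection controls: top rows of the last light-control column.
    tc_col = spec.light_cols[-1]
    tc_wells = {well_name(r, tc_col) for r in range(spec.n_transfection)}

    base_roles: dict[str, str] = {}
    sample_positions: list[str] = []
    for col in range(spec.n_cols):
        for row in range(spec.n_rows):
            w = well_name(row, col)
            if col in spec.dark_cols:
                base_roles[w] = ROLE_DARK
            elif col in spec.light_cols:
                base_roles[w] = ROLE_TRANSFECTION if w in tc_wells else ROLE_LIGHT
            else:
                sample_positions.append(w)
    # Column-major fill order of sample wells, stable across replicates.

    plates: list[PlateLayout] = []
    for rep in range(1, replicate_count + 1):
        for p in range(n_plates):
            chunk = order[p * spec.sample_capacity:(p + 1) * spec.sample_capacity]
            roles = dict(base_roles)
            mirnas: dict[str, str] = {}
            for w, mid in zip(sample_positions, chunk):
                roles[w] = ROLE_SAMPLE
                mirnas[w] = str(mid)
            for w in sample_positions[len(chunk):]:
                roles[w] = ROLE_EMPTY
            plates.append(PlateLayout(
                plate_id=f"P{p + 1:02d}_R{rep}",
                replicate_index=rep,
                n_rows=spec.n_rows,
                n_cols=spec.n_cols,
                role_map=roles,
                mirna_map=mirnas,
            ))
    return plates


def layouts_to_frame(layouts: list[PlateLayout]) -> pd.DataFrame:
    """Flatten layouts to a plate-map table (one row per non-empty well)."""
    rows = []
    for lay in layouts:
        for well in sorted(lay.role_map):
            role = lay.role_map[well]
            if role == ROLE_EMPTY:
                continue
            rows.append({
                "plate_id": lay.plate_id,
                "well": well,
                "role": role,
                "mirna_id": lay.mirna_map.get(well, ""),
                "replicate": lay.replicate_index,
            })
    return pd.DataFrame(rows, columns=["plate_id", "well", "role", "mirna_id", "replicate"])


def frame_to_layouts(frame: pd.DataFrame) -> list[PlateLayout]:
    """Rebuild PlateLayout objects from a plate-map table."""
    layouts = []
    for plate_id, grp in frame.groupby("plate_id", sort=True):
        roles = dict(zip(grp["well"], grp["role"]))
        mirnas = {w: m for w, m, r in zip(grp["well"], grp["mirna_id"], grp["role"])
                  if r == ROLE_SAMPLE and isinstance(m, str) and m}
        rep = int(grp["replicate"].iloc[0])
        layouts.append(PlateLayout(plate_id=str(plate_id), replicate_index=rep,
                                   role_map=roles, mirna_map=mirnas))
    return layouts


def read_platemap(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"plate_id": str, "well": str, "role": str,
                                     "mirna_id": str}, keep_default_na=False)
    required = {"plate_id", "well", "role", "mirna_id", "replicate"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"plate map missing columns: {sorted(missing)}")
    return frame


def write_platemap(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)
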