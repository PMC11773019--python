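"""Per-plate quality control and Z scoring against light controls.

The screen's normalisation is strictly per plate: a sample well's
percent dying x is converted to Z = (x − μ) / σ where μ and σ are the
mean and sample standard deviation of the *same plate's* light-control
wells.  Negative Z means fewer dying cells than the stressed controls,
i.e. protection.

QC asks whether the light stress worked on that plate: light controls
must show more death than dark controls, quantified by a standardised
separation statistic (difference of means over pooled SD by default, a
Z'-factor optionally) with a configurable floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .layout import ROLE_DARK, ROLE_LIGHT, ROLE_SAMPLE


@dataclass(frozen=True)
class QCParams:
    separation_floor: float = 2.0
    statistic: str = "separation"  # or "zprime"
    min_controls: int = 2


@dataclass(frozen=True)
class PlateQC:
    """Light-control reference statistics and stress-efficacy verdict."""

    plate_id: str
    mu_light: float
    sigma_light: float
    mu_dark: float
    n_light_controls: int
    n_dark_controls: int
    separation_stat: float
    passed: bool
    reason: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def _valid(frame: pd.DataFrame) -> pd.DataFrame:
    if "valid" in frame.columns:
        return frame[frame["valid"].astype(bool)]
    return frame


def qc_plate(well_table: pd.DataFrame,
             params: QCParams = QCParams()) -> PlateQC:
    """Compute light-control reference stats and the QC verdict for one plate.

    The input must contain exactly one plate.  μ and σ (ddof=1) are taken
    over valid light-control wells; the verdict requires μ_light > μ_dark
    and the separation statistic to clear its floor.
    """
    plates = well_table["plate_id"].unique()
    if len(plates) != 1:
        raise ValueError(f"qc_plate expects one plate, got {list(plates)}")
    plate_id = str(plates[0])

    frame = _valid(well_table)
    light = frame.loc[frame["role"] == ROLE_LIGHT, "percent_dying"].to_numpy(float)
    dark = frame.loc[frame["role"] == ROLE_DARK, "percent_dying"].to_numpy(float)
    if len(light) < params.min_controls or len(dark) < params.min_controls:
        raise ValueError(
            f"plate {plate_id}: need >= {params.min_controls} valid light and "
            f"dark controls, got {len(light)} light / {len(dark)} dark")

    mu_l, mu_d = float(light.mean()), float(dark.mean())
    sigma_l = float(light.std(ddof=1))
    sigma_d = float(dark.std(ddof=1))

    if sigma_l == 0.0:
        return PlateQC(plate_id=plate_id, mu_light=mu_l, sigma_light=0.0,
                       mu_dark=mu_d, n_light_controls=len(light),
                       n_dark_controls=len(dark), separation_stat=float("nan"),
                       passed=False,
                       reason="sigma_light = 0: Z score undefined")

    if params.statistic == "separation":
        pooled = np.sqrt(((len(light) - 1) * sigma_l**2
                          + (len(dark) - 1) * sigma_d**2)
                         / (len(light) + len(dark) - 2))
        stat = (mu_l - mu_d) / pooled if pooled > 0 else np.inf
    elif params.statistic == "zprime":
        stat = 1.0 - 3.0 * (sigma_l + sigma_d) / abs(mu_l - mu_d) \
            if mu_l != mu_d else -np.inf
    else:
        raise ValueError(f"unknown QC statistic {params.statistic!r}")

    passed = bool(mu_l > mu_d and stat >= params.separation_floor)
    reason = "" if passed else (
        "light controls not above dark controls" if mu_l <= mu_d
        else f"separation {stat:.2f} below floor {params.separation_floor}")
    return PlateQC(plate_id=plate_id, mu_light=mu_l, sigma_light=sigma_l,
                   mu_dark=mu_d, n_light_controls=len(light),
                   n_dark_controls=len(dark), separation_stat=float(stat),
                   passed=passed, reason=reason)


def zscore_wells(well_table: pd.DataFrame, qc: PlateQC,
                 *, allow_failed_qc: bool = False) -> pd.DataFrame:
    """Z-score every valid sample well of one plate against its light controls.

    Returns a frame with columns plate_id, well, mirna_id, replicate,
    x (percent dying), normalized (x / μ_light) and z.  Control wells
    receive no Z; wells from another plate are rejected.
    """
    plates = set(well_table["plate_id"].astype(str).unique())
    if plates != {qc.plate_id}:
        raise ValueError(f"well table plates {sorted(plates)} do not match "
                         f"QC plate {qc.plate_id!r}")
    if qc.sigma_light == 0.0 or not np.isfinite(qc.sigma_light):
        raise ValueError(f"plate {qc.plate_id}: sigma_light is not positive; "
                         "Z score undefined")
    if not qc.passed and not allow_failed_qc:
        raise ValueError(f"plate {qc.plate_id} failed QC ({qc.reason}); "
                         "pass allow_failed_qc=True to override")

    frame = _valid(well_table)
    samples = frame[frame["role"] == ROLE_SAMPLE]
    x = samples["percent_dying"].to_numpy(float)
    out = pd.DataFrame({
        "plate_id": samples["plate_id"].to_numpy(),
        "well": samples["well"].to_numpy(),
        "mirna_id": samples["mirna_id"].to_numpy(),
        "replicate": samples["replicate"].to_numpy(),
        "x": x,
        "normalized": x / qc.mu_light,
        "z": (x - qc.mu_light) / qc.sigma_light,
    })
    return out.reset_index(drop=True)


def qc_and_zscore(well_table: pd.DataFrame,
                  params: QCParams = QCParams(),
                  *, allow_failed_qc: bool = False
                  ) -> tuple[list[PlateQC], pd.DataFrame]:
    """Run QC and Z scoring plate by plate over a multi-plate well table."""
    qcs: list[PlateQC] = []
    ztables = []
    for plate_id, grp in well_table.groupby("plate_id", sort=True):
        qc = qc_plate(grp, params)
        qcs.append(qc)
        if qc.passed or allow_failed_qc:
            if qc.sigma_light > 0:
                ztables.append(zscore_wells(grp, qc,
                                            allow_failed_qc=allow_failed_qc))
    zframe = pd.concat(ztables, ignore_index=True) if ztables else pd.DataFrame(
        columns=["plate_id", "well", "mirna_id", "replicate", "x",
                 "normalized", "z"])
    return qcs, zframe


def write_qc_report(qcs: list[PlateQC], path) -> None:
    with open(path, "w") as fh:
        json.dump([qc.to_dict() for qc in qcs], fh, indent=2, sort_keys=True)
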