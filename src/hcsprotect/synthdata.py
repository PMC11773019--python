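"""Seeded synthetic screen inputs with known ground truth.

The generator emulates the study conditions of a light-stress viability
screen: untransfected control wells sit at a dark baseline (~5% dying) or
a light baseline (~40% dying), and each library miRNA multiplies the
light-induced dying probability by a per-miRNA effect (1.0 neutral,
< 1 protective, > 1 deleterious).  Plate-level batch offsets (small
additive shifts of the dying fraction shared by every well on a plate)
are on by default; they are exactly what per-plate normalisation against
light controls is meant to remove.

Two generation routes exist: ``simulate_well_table`` produces well-level
percent-dying tables directly (fast mode), and :mod:`hcsprotect.render`
produces per-well microscopy images whose planted nuclei carry
healthy/dying labels (image mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import (ROLE_DARK, ROLE_EMPTY, ROLE_SAMPLE, PlateLayout)

DEFAULT_BASELINE_DARK = 0.05
DEFAULT_BASELINE_LIGHT = 0.40
DEFAULT_NOISE_SD = 0.05
DEFAULT_BATCH_OFFSET_SD = 0.02


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic screen run.

    ``effect_map`` multiplies the light dying probability per miRNA;
    ``per_nucleus_labels`` is filled by the image renderer (image id ->
    list of True-for-dying flags).
    """

    effect_map: dict[str, float]
    baseline_dying_dark: float = DEFAULT_BASELINE_DARK
    baseline_dying_light: float = DEFAULT_BASELINE_LIGHT
    seed: int = 0
    per_nucleus_labels: dict[str, list[bool]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_dying_dark <= 1.0:
            raise ValueError("baseline_dying_dark outside [0, 1]")
        if not 0.0 <= self.baseline_dying_light <= 1.0:
            raise ValueError("baseline_dying_light outside [0, 1]")
        if self.baseline_dying_light <= self.baseline_dying_dark:
            raise ValueError("light baseline must exceed dark baseline "
                             "(the stress must be effective)")
        for mid, eff in self.effect_map.items():
            if eff < 0:
                raise ValueError(f"negative effect for {mid}")

    def dying_probability(self, mirna_id: str | None, lit: bool) -> float:
        """Planted dying probability for a well."""
        if not lit:
            return self.baseline_dying_dark
        eff = 1.0 if mirna_id is None else self.effect_map.get(mirna_id, 1.0)
        return float(np.clip(self.baseline_dying_light * eff, 0.0, 1.0))


def make_ground_truth(
    mirna_ids: list[str],
    seed: int,
    *,
    n_protective: int = 0,
    protective_effect: float = 0.5,
    n_deleterious: int = 0,
    deleterious_effect: float = 1.5,
    baseline_dark: float = DEFAULT_BASELINE_DARK,
    baseline_light: float = DEFAULT_BASELINE_LIGHT,
) -> GroundTruth:
    """Plant protective/deleterious effects in an otherwise neutral library."""
    if n_protective + n_deleterious > len(mirna_ids):
        raise ValueError("more planted effects than miRNAs")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(mirna_ids), size=n_protective + n_deleterious,
                        replace=False)
    effects = {mid: 1.0 for mid in mirna_ids}
    for idx in chosen[:n_protective]:
        effects[mirna_ids[idx]] = protective_effect
    for idx in chosen[n_protective:]:
        effects[mirna_ids[idx]] = deleterious_effect
    return GroundTruth(effect_map=effects, baseline_dying_dark=baseline_dark,
                       baseline_dying_light=baseline_light, seed=seed)


def planted_ids(truth: GroundTruth, kind: str) -> list[str]:
    """miRNAs with a planted effect; kind is 'protective' or 'deleterious'."""
    if kind == "protective":
        return sorted(m for m, e in truth.effect_map.items() if e < 1.0)
    if kind == "deleterious":
        return sorted(m for m, e in truth.effect_map.items() if e > 1.0)
    raise ValueError(kind)


def simulate_well_table(
    layouts: list[PlateLayout],
    truth: GroundTruth,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    *,
    batch_offset_sd: float = DEFAULT_BATCH_OFFSET_SD,
) -> pd.DataFrame:
    """Fast-mode generator: well-level percent-dying, bypassing imaging.

    Each well's dying fraction is its planted probability plus the plate's
    batch offset plus Gaussian well noise, clipped to [0, 1] and reported
    as a percentage.  Dark-control wells are the only unlit wells.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if batch_offset_sd < 0:
        raise ValueError("batch_offset_sd must be non-negative")
    for lay in layouts:
        missing = set(lay.mirna_map.values()) - set(truth.effect_map)
        if missing:
            raise ValueError(f"ground truth lacks effects for {sorted(missing)[:5]}")

    rng = np.random.default_rng(seed)
    rows = []
    for lay in layouts:
        offset = rng.normal(0.0, batch_offset_sd) if batch_offset_sd > 0 else 0.0
        for well in sorted(lay.role_map):
            role = lay.role_map[well]
            if role == ROLE_EMPTY:
                continue
            mid = lay.mirna_map.get(well)
            p = truth.dying_probability(mid, lit=(role != ROLE_DARK))
            p = float(np.clip(p + offset, 0.0, 1.0))
            frac = p if noise_sd == 0 else float(np.clip(rng.normal(p, noise_sd), 0.0, 1.0))
            rows.append({
                "plate_id": lay.plate_id,
                "well": well,
                "role": role,
                "mirna_id": mid or "",
                "replicate": lay.replicate_index,
                "n_nuclei": np.nan,
                "n_dying": np.nan,
                "percent_dying": 100.0 * frac,
                "valid": True,
            })
    return pd.DataFrame(rows)


def simulate_secondary_assay(
    effects: dict[str, float],
    baseline_dark: float = DEFAULT_BASELINE_DARK,
    baseline_light: float = DEFAULT_BASELINE_LIGHT,
    cells_per_well: int = 60_000,
    replicates: int = 3,
    seed: int = 0,
    *,
    duplicates: int = 2,
    biological_sd: float = 0.02,
) -> pd.DataFrame:
    """Simulate the dye-exclusion (trypan-blue) validation assay.

    For each miRNA mimic and its matched negative (non-targeting) mimic,
    wells are seeded with ``cells_per_well`` cells, run in ``duplicates``
    technical duplicates per condition and ``replicates`` biological
    replicates.  Dead counts are binomial draws around a per-well dying
    probability jittered by additive Gaussian noise (``biological_sd``,
    on the fraction scale).  The additive — homoskedastic — noise form
    keeps the downstream fixed-effects ANOVA exactly calibrated under
    the null, which is what a null-calibration check of the test
    requires.  Protective effects act on the light condition only.
    """
    if not 0.0 <= baseline_dark <= 1.0 or not 0.0 <= baseline_light <= 1.0:
        raise ValueError("baselines must lie in [0, 1]")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if duplicates < 1:
        raise ValueError("duplicates must be >= 1")
    if cells_per_well < 1:
        raise ValueError("cells_per_well must be >= 1")

    rng = np.random.default_rng(seed)
    rows = []
    for mid, effect in effects.items():
        for treatment, eff in (("mimic", effect), ("negative_mimic", 1.0)):
            for condition in ("light", "dark"):
                base = baseline_light if condition == "light" else baseline_dark
                p0 = base * eff if condition == "light" else base
                for rep in range(1, replicates + 1):
                    for dup in range(1, duplicates + 1):
                        p = float(np.clip(p0 + rng.normal(0.0, biological_sd),
                                          1e-6, 1.0 - 1e-6))
                        dead = int(rng.binomial(cells_per_well, p))
                        rows.append({
                            "mirna_id": mid,
                            "condition": condition,
                            "treatment": treatment,
                            "replicate": rep,
                            "duplicate": dup,
                            "live": cells_per_well - dead,
                            "dead": dead,
                        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic stand-in for the published per-miRNA average-Z reference table.
# ---------------------------------------------------------------------------

SHORTLIST_MIRNAS = (
    "hsa-miR-150-3p",
    "hsa-miR-346",
    "hsa-miR-371a-5p",
    "hsa-miR-429",
    "hsa-miR-514b-5p",
    "hsa-miR-5010-5p",
)

REFERENCE_LIBRARY_SIZE = 1268
_TOP_HIT = "hsa-miR-429"


def synthetic_reference_screen_table(seed: int = 0) -> tuple[
        list[pd.DataFrame], set[str]]:
    """SYNTHETIC stand-in for the published screen's scored library.

    The real per-miRNA average-Z supplementary table is not redistributed
    here; this generator fabricates replicate-level Z tables that encode
    only the published summary facts — 1,268 scored miRNAs, a protective
    tail below Z = −2.1 whose annotated, low-variability members are the
    six shortlisted miRNAs with miR-429 scoring lowest, and a deleterious
    tail above Z = +2.1 — and fills the remaining library with neutral
    synthetic entries.  Everything else about the table is invented.

    Returns three replicate Z-score frames (columns mirna_id, z,
    normalized) and the annotation-membership id set.
    """
    rng = np.random.default_rng(seed)
    mu_light, sigma_light = 40.0, 5.0

    ids: list[str] = []
    mean_z: dict[str, float] = {}
    spread: dict[str, float] = {}
    annotated: set[str] = set()

    # Six shortlisted hits: deep protective Z, tight replicates, annotated;
    # miR-429 planted lowest.
    shortlist_means = {_TOP_HIT: -3.5}
    others = [m for m in SHORTLIST_MIRNAS if m != _TOP_HIT]
    for m, z in zip(others, np.linspace(-3.1, -2.4, len(others))):
        shortlist_means[m] = float(z)
    for m in SHORTLIST_MIRNAS:
        ids.append(m)
        mean_z[m] = shortlist_means[m]
        spread[m] = 0.05
        annotated.add(m)

    # Annotated protective entries with erratic replicates: pass the Z and
    # annotation filters but lose the variability ranking.
    for i in range(6):
        m = f"hsa-miR-syn-var-{i + 1:02d}"
        ids.append(m)
        mean_z[m] = float(rng.uniform(-3.3, -2.3))
        spread[m] = 1.2
        annotated.add(m)

    # Protective entries absent from the annotation database.
    for i in range(10):
        m = f"hsa-miR-syn-novel-{i + 1:02d}"
        ids.append(m)
        mean_z[m] = float(rng.uniform(-3.0, -2.3))
        spread[m] = 0.2

    # Deleterious tail (Z > 2.1), reported without further filtering.
    for i in range(15):
        m = f"hsa-miR-syn-del-{i + 1:02d}"
        ids.append(m)
        mean_z[m] = float(rng.uniform(2.3, 4.0))
        spread[m] = 0.3
        annotated.add(m)

    # Neutral bulk, kept far enough inside the cutoffs that replicate
    # noise cannot create spurious tail members.
    n_neutral = REFERENCE_LIBRARY_SIZE - len(ids)
    for i in range(n_neutral):
        m = f"hsa-miR-syn-{i + 1:04d}"
        ids.append(m)
        mean_z[m] = float(np.clip(rng.normal(0.0, 0.8), -1.6, 1.6))
        spread[m] = 0.3
        if rng.random() < 0.5:
            annotated.add(m)

    # Replicate deviations are standardised (sample mean 0, sample SD 1)
    # before scaling, so each entry's realised mean Z and replicate SD equal
    # the planted values exactly and the encoded summary facts (miR-429
    # lowest, shortlist CV ordering) hold by construction, not by chance.
    frames = []
    reps = {}
    for m in ids:
        d = rng.standard_normal(3)
        d = (d - d.mean()) / d.std(ddof=1)
        reps[m] = mean_z[m] + spread[m] * d
    for r in range(3):
        z = np.array([reps[m][r] for m in ids])
        x = mu_light + sigma_light * z  # implied percent dying
        frames.append(pd.DataFrame({
            "mirna_id": ids,
            "z": z,
            "normalized": x / mu_light,
        }))
    return frames, annotated
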