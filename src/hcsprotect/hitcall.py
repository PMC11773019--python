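"""Replicate aggregation, filtering, and ranked hit lists.

Hit calling proceeds in auditable stages: per-miRNA replicate Z scores
are averaged; miRNAs with mean Z below the protective cutoff (−2.1 by
default) form the protective set; the set is intersected with a curated
annotation database (MirGeneDB-style membership list); survivors are
ranked by their coefficient of variation across replicates and the
top-n least variable become the shortlist.  The deleterious tail
(mean Z above +2.1) is reported without further filtering.

The CV is computed over the per-replicate light-normalised dying
fractions (x / μ_light), which are positive and scale-free; the
alternative (CV of |Z|) is available via ``cv_basis='abs_z'``.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

_SPECIES_PREFIX = re.compile(r"^[a-z]{3,4}-(?=(mir|let)\b)", re.IGNORECASE)


def canonical_mirna(mirna_id: str) -> str:
    """Case-fold and strip the species prefix: 'hsa-miR-429' -> 'mir-429'."""
    name = mirna_id.strip().lower()
    return _SPECIES_PREFIX.sub("", name)


@dataclass
class MiRNAScore:
    """Per-miRNA screen summary: the unit of hit calling."""

    mirna_id: str
    z_replicates: tuple[float, ...]
    mean_z: float
    cv: float
    n_replicates: int
    in_annotation_set: bool | None = None
    rank: int | None = None


@dataclass(frozen=True)
class HitCallingConfig:
    z_cutoff_protective: float = -2.1
    z_cutoff_deleterious: float = 2.1
    cv_policy: str = "rank_and_keep_top_n"  # or "cv_threshold"
    top_n: int = 6
    cv_threshold: float = 0.5
    annotation_required: bool = True
    min_replicates: int = 3

    def __post_init__(self) -> None:
        if not self.z_cutoff_protective < 0 < self.z_cutoff_deleterious:
            raise ValueError("need protective cutoff < 0 < deleterious cutoff")


@dataclass
class HitList:
    protective: list[str]
    deleterious: list[str]
    shortlist: list[str]
    provenance: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def aggregate_replicates(ztables: list[pd.DataFrame],
                         *, cv_basis: str = "normalized") -> list[MiRNAScore]:
    """Combine one Z table per biological replicate into per-miRNA scores.

    Each table needs columns ``mirna_id`` and ``z``; for the default CV
    basis it also needs ``normalized`` (x / μ_light).  A miRNA duplicated
    within one replicate is an error (it would silently average two
    wells); miRNAs missing from some replicates are kept but carry their
    observed replicate count for downstream filtering.
    """
    if not ztables:
        raise ValueError("no replicate tables given")
    if cv_basis not in ("normalized", "abs_z"):
        raise ValueError(f"unknown cv_basis {cv_basis!r}")

    pieces = []
    for rep_idx, table in enumerate(ztables, start=1):
        counts = table["mirna_id"].value_counts()
        dups = counts[counts > 1]
        if len(dups):
            mid = dups.index[0]
            ctx = table.loc[table["mirna_id"] == mid]
            where = ", ".join(f"{p}/{w}" for p, w in
                              zip(ctx.get("plate_id", ["?"] * len(ctx)),
                                  ctx.get("well", ["?"] * len(ctx))))
            raise ValueError(f"miRNA {mid!r} appears {dups.iloc[0]} times in "
                             f"replicate {rep_idx} ({where})")
        piece = pd.DataFrame({
            "mirna_id": table["mirna_id"].astype(str),
            "z": table["z"].astype(float),
        })
        piece["basis"] = (table["normalized"].astype(float).to_numpy()
                          if cv_basis == "normalized"
                          else np.abs(piece["z"].to_numpy()))
        pieces.append(piece)
    stacked = pd.concat(pieces, ignore_index=True)

    grouped = stacked.groupby("mirna_id", sort=True)
    agg = grouped.agg(mean_z=("z", "mean"), n=("z", "size"),
                      basis_mean=("basis", "mean"),
                      basis_sd=("basis", lambda v: v.std(ddof=1)
                                if len(v) > 1 else 0.0))
    z_lists = grouped["z"].agg(tuple)

    scores = []
    for mid, row in agg.iterrows():
        mean = float(row["basis_mean"])
        cv = float(row["basis_sd"]) / abs(mean) if mean != 0 else float("inf")
        scores.append(MiRNAScore(
            mirna_id=str(mid),
            z_replicates=z_lists[mid],
            mean_z=float(row["mean_z"]),
            cv=cv,
            n_replicates=int(row["n"]),
        ))
    return scores


def _sort_key(score: MiRNAScore):
    # mean Z ascending; ties broken by lower CV, then lexicographic id.
    return (score.mean_z, score.cv, score.mirna_id)


def rank_and_filter(scores: list[MiRNAScore], annotation_set,
                    config: HitCallingConfig = HitCallingConfig()) -> HitList:
    """Apply the cutoff → annotation → variability filter chain.

    ``annotation_set`` is an iterable of curated miRNA ids; matching is
    exact on canonical names (case-folded, species prefix stripped).
    Ranks (1..n, mean Z ascending) are assigned in place over the scored
    set.  Returns the protective set, the deleterious tail, and the
    post-CV shortlist, with stage-by-stage counts in ``provenance``.
    """
    annotation = {canonical_mirna(m) for m in annotation_set}
    if config.annotation_required and not annotation:
        raise ValueError("annotation filtering requested with an empty set")

    incomplete = [s.mirna_id for s in scores
                  if s.n_replicates < config.min_replicates]
    scored = [s for s in scores if s.n_replicates >= config.min_replicates]

    scored.sort(key=_sort_key)
    for i, s in enumerate(scored, start=1):
        s.rank = i
        s.in_annotation_set = canonical_mirna(s.mirna_id) in annotation

    protective = [s for s in scored if s.mean_z < config.z_cutoff_protective]
    deleterious = [s for s in scored if s.mean_z > config.z_cutoff_deleterious]

    if config.annotation_required:
        annotated = [s for s in protective if s.in_annotation_set]
    else:
        annotated = list(protective)

    by_cv = sorted(annotated, key=lambda s: (s.cv, s.mirna_id))
    if config.cv_policy == "rank_and_keep_top_n":
        if config.top_n > len(by_cv):
            warnings.warn(f"top_n={config.top_n} exceeds the {len(by_cv)} "
                          "surviving miRNAs; returning all survivors",
                          stacklevel=2)
        shortlist = by_cv[:config.top_n]
    elif config.cv_policy == "cv_threshold":
        shortlist = [s for s in by_cv if s.cv <= config.cv_threshold]
    else:
        raise ValueError(f"unknown cv_policy {config.cv_policy!r}")
    # Present the shortlist in screen order (strongest protection first).
    shortlist = sorted(shortlist, key=_sort_key)

    provenance = {
        "config": asdict(config),
        "n_input": len(scores),
        "n_incomplete_replicates": len(incomplete),
        "incomplete_ids": sorted(incomplete),
        "n_scored": len(scored),
        "n_protective_cutoff": len(protective),
        "n_after_annotation": len(annotated),
        "n_shortlist": len(shortlist),
        "n_deleterious": len(deleterious),
        "excluded_by_annotation": sorted(
            s.mirna_id for s in protective if s not in annotated),
        "excluded_by_cv": sorted(
            s.mirna_id for s in annotated if s not in shortlist),
    }
    return HitList(
        protective=[s.mirna_id for s in sorted(protective, key=_sort_key)],
        deleterious=[s.mirna_id for s in
                     sorted(deleterious, key=_sort_key, reverse=True)],
        shortlist=[s.mirna_id for s in shortlist],
        provenance=provenance,
    )


def scores_to_frame(scores: list[MiRNAScore]) -> pd.DataFrame:
    n_rep = max((s.n_replicates for s in scores), default=0)
    rows = []
    for s in scores:
        row = {"mirna_id": s.mirna_id}
        for i in range(n_rep):
            row[f"z_rep{i + 1}"] = (s.z_replicates[i]
                                    if i < len(s.z_replicates) else np.nan)
        row.update({"mean_z": s.mean_z, "cv": s.cv,
                    "n_replicates": s.n_replicates,
                    "annotated": s.in_annotation_set, "rank": s.rank})
        rows.append(row)
    return pd.DataFrame(rows)


def read_annotation_list(path) -> set[str]:
    """Read a one-id-per-line annotation membership list."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()
                and not line.startswith("#")}
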