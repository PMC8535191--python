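"""Occurrence records: cleaning by discard rules and spatial thinning.

Cleaning applies three discard rules in a fixed order, recording the first
matching reason per record: (i) outside the known range polygon, (ii) not
expert-verified, (iii) coordinate uncertainty above a maximum (default 1 km,
the working grid resolution — coarser records could land in the wrong cell).

Thinning removes clustered records until every retained pair is at least a
minimum distance apart (default 1.5 km).  The algorithm is the one popularised
by the spThin R package: repeatedly drop a uniformly random record among those
with the most neighbours closer than the threshold; run many replicates and
keep one with the largest retained count.  It is a heuristic for maximum
independent set on the conflict graph; an exhaustive oracle is provided for
small instances so the heuristic's optimality rate can be measured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .grids import haversine_m

__all__ = [
    "OccurrenceSet",
    "clean_records",
    "thin",
    "brute_force_thin_oracle",
    "pairwise_distances",
    "read_occurrences_csv",
    "write_occurrences_csv",
]

COLUMNS = ["id", "x", "y", "uncertainty_m", "verified", "source", "discard_reason"]


@dataclass
class OccurrenceSet:
    """Ordered occurrence records plus a provenance log.

    ``records`` is a DataFrame with columns id, x, y, uncertainty_m, verified,
    source, discard_reason (None while a record is retained).
    """

    records: pd.DataFrame
    lonlat: bool = False
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in COLUMNS:
            if col not in self.records.columns:
                if col == "discard_reason":
                    self.records["discard_reason"] = None
                elif col == "source":
                    self.records["source"] = ""
                elif col == "uncertainty_m":
                    self.records["uncertainty_m"] = np.nan
                elif col == "verified":
                    self.records["verified"] = True
                else:
                    raise ValueError(f"occurrence table lacks required column {col!r}")
        if self.records["id"].duplicated().any():
            raise ValueError("occurrence ids must be unique")
        u = self.records["uncertainty_m"]
        if (u.dropna() < 0).any():
            raise ValueError("uncertainty_m must be >= 0")

    @property
    def active(self) -> pd.DataFrame:
        """Records not discarded."""
        return self.records[self.records["discard_reason"].isna()]

    def __len__(self) -> int:
        return len(self.active)

    def coords(self) -> np.ndarray:
        """(n, 2) x/y of active records."""
        return self.active[["x", "y"]].to_numpy(dtype=float)


def pairwise_distances(coords: np.ndarray, lonlat: bool = False) -> np.ndarray:
    """Full symmetric distance matrix in meters (Euclidean or great-circle)."""
    coords = np.asarray(coords, dtype=float)
    if lonlat:
        x, y = coords[:, 0], coords[:, 1]
        return haversine_m(x[:, None], y[:, None], x[None, :], y[None, :])
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def clean_records(
    raw: OccurrenceSet,
    range_polygon: BaseGeometry,
    max_uncertainty_m: float = 1000.0,
) -> OccurrenceSet:
    """Apply the three discard rules in order; survivors are unmodified.

    Records with missing coordinates are a hard error, not a discard: they
    cannot be evaluated against any rule.
    """
    df = raw.records.copy()
    if df.empty:
        raise ValueError("empty occurrence set")
    if df[["x", "y"]].isna().any().any():
        bad = df.loc[df[["x", "y"]].isna().any(axis=1), "id"].tolist()
        raise ValueError(f"records with missing coordinates: {bad}")

    reason = df["discard_reason"].copy()
    undecided = reason.isna()

    inside = np.array([range_polygon.covers(Point(x, y))
                       for x, y in df[["x", "y"]].to_numpy(dtype=float)])
    rule_i = undecided & ~inside
    reason[rule_i] = "out_of_range"
    undecided &= ~rule_i

    rule_ii = undecided & ~df["verified"].astype(bool)
    reason[rule_ii] = "unverified"
    undecided &= ~rule_ii

    # strict ">": a record exactly at the maximum uncertainty is kept
    rule_iii = undecided & (df["uncertainty_m"] > max_uncertainty_m)
    reason[rule_iii] = "inaccurate"

    df["discard_reason"] = reason
    log = dict(raw.log)
    log["clean"] = {
        "out_of_range": int(rule_i.sum()),
        "unverified": int(rule_ii.sum()),
        "inaccurate": int(rule_iii.sum()),
        "kept": int(reason.isna().sum()),
        "max_uncertainty_m": max_uncertainty_m,
    }
    return OccurrenceSet(records=df, lonlat=raw.lonlat, log=log)


def _thin_once(dist: np.ndarray, thin_dist_m: float, rng: np.random.Generator) -> np.ndarray:
    """One thinning replicate; returns indices retained (into dist)."""
    n = dist.shape[0]
    conflict = (dist < thin_dist_m) & ~np.eye(n, dtype=bool)
    alive = np.ones(n, dtype=bool)
    counts = conflict.sum(axis=1).astype(int)
    while True:
        if not counts[alive].max(initial=0) > 0:
            break
        mx = counts[alive].max()
        candidates = np.flatnonzero(alive & (counts == mx))
        drop = int(rng.choice(candidates))
        alive[drop] = False
        counts[conflict[drop]] -= 1
        counts[drop] = 0
    return np.flatnonzero(alive)


def thin(
    occ: OccurrenceSet,
    thin_dist_m: float = 1500.0,
    reps: int = 100,
    seed: int = 0,
) -> OccurrenceSet:
    """Spatially thin active records to pairwise distances >= ``thin_dist_m``.

    Runs ``reps`` independent replicates of the greedy removal and returns the
    first replicate attaining the largest retained count (deterministic given
    the seed, which is logged).
    """
    active = occ.active
    if len(active) == 0:
        raise ValueError("no active records to thin")
    coords = active[["x", "y"]].to_numpy(dtype=float)
    dist = pairwise_distances(coords, lonlat=occ.lonlat)
    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    for _ in range(reps):
        kept = _thin_once(dist, thin_dist_m, rng)
        if best is None or kept.size > best.size:
            best = kept
    assert best is not None
    sub = dist[np.ix_(best, best)]
    off = sub[~np.eye(len(best), dtype=bool)]
    assert off.size == 0 or off.min() >= thin_dist_m, "thinning violated the distance constraint"

    df = occ.records.copy()
    kept_ids = set(active.iloc[best]["id"])
    mask_active = df["discard_reason"].isna()
    df.loc[mask_active & ~df["id"].isin(kept_ids), "discard_reason"] = "thinned"
    log = dict(occ.log)
    log["thin"] = {
        "thin_dist_m": thin_dist_m,
        "reps": reps,
        "seed": seed,
        "input": int(len(active)),
        "retained": int(best.size),
    }
    return OccurrenceSet(records=df, lonlat=occ.lonlat, log=log)


def brute_force_thin_oracle(occ_or_coords, thin_dist_m: float, lonlat: bool = False) -> int:
    """Exact maximum number of retainable records (max independent set).

    Exhaustive over the conflict graph; refuses more than 20 records.
    """
    if isinstance(occ_or_coords, OccurrenceSet):
        coords = occ_or_coords.coords()
        lonlat = occ_or_coords.lonlat
    else:
        coords = np.asarray(occ_or_coords, dtype=float)
    n = len(coords)
    if n > 20:
        raise ValueError("oracle limited to <= 20 records")
    if n == 0:
        return 0
    dist = pairwise_distances(coords, lonlat=lonlat)
    conflict_bits = [0] * n
    for i in range(n):
        for j in range(n):
            if i != j and dist[i, j] < thin_dist_m:
                conflict_bits[i] |= 1 << j
    best = 0
    for subset in range(1 << n):
        size = subset.bit_count()
        if size <= best:
            continue
        ok = True
        s = subset
        while s:
            i = (s & -s).bit_length() - 1
            if conflict_bits[i] & subset:
                ok = False
                break
            s &= s - 1
        if ok:
            best = size
    return best


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_occurrences_csv(path: str | Path, lonlat: bool = False) -> OccurrenceSet:
    df = pd.read_csv(path)
    if "discard_reason" in df.columns:
        df["discard_reason"] = df["discard_reason"].where(df["discard_reason"].notna(), None)
    return OccurrenceSet(records=df, lonlat=lonlat)


def write_occurrences_csv(occ: OccurrenceSet, path: str | Path,
                          log_sidecar: bool = True) -> Path:
    path = Path(path)
    occ.records.to_csv(path, index=False, columns=COLUMNS)
    if log_sidecar and occ.log:
        path.with_suffix(".log.json").write_text(json.dumps(occ.log, indent=2))
    return path
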