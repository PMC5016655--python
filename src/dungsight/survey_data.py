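"""Survey data model: pellet events, transects, vegetation quadrats.

The observation unit is the *pellet event* — a group of at least ten dung
pellets of consistent age and size found on a strip transect, recorded with
its perpendicular distance from the transect center line.  Territorial
clusters of feces (middens) are flagged and excluded from density analysis,
because their placement reflects territory marking rather than resource use.

The sampling unit is the *transect*: a paired wadi/plain strip of fixed
geometry, belonging to a wadi system (the random-effect grouping), with a
vector of habitat covariates aggregated from vegetation quadrats placed
along its center line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPECIES = ("oryx", "gazelle")

#: Default distance-interval cutpoints in meters (three equal bins to 4 m).
DEFAULT_CUTPOINTS = (0.0, 4.0 / 3.0, 8.0 / 3.0, 4.0)

EVENT_COLUMNS = ["transect_id", "species", "distance_m", "n_pellets", "is_midden"]
TRANSECT_COLUMNS = [
    "transect_id", "pair_id", "wadi_system", "habitat", "length_m",
    "half_width_m", "north_south", "east_west", "predator_scats",
]
QUADRAT_COLUMNS = [
    "transect_id", "quadrat_idx", "rock_pct", "litter_pct", "herb_pct",
    "shrub_pct", "tree_pct", "herb_height_cm", "shrub_height_cm",
    "tree_height_cm", "richness", "nonwoody_wet_g", "nonwoody_dry_g", "woody_g",
]

#: Registered transect-level predictors of pellet-group density.
PREDICTORS = [
    "habitat_type",        # wadi/plain indicator (plain = 1)
    "wadi_location",       # wadi-system index treated as a located gradient
    "north_south",
    "east_west",
    "rock_cover",
    "litter_cover",
    "nonwoody_biomass",
    "woody_biomass",
    "herb_cover",
    "herb_height",
    "shrub_cover",
    "shrub_height",
    "tree_cover",
    "tree_height",
    "plant_water",
    "richness",
    "predation",
]


class SchemaError(ValueError):
    """A required column is missing or a value fails schema validation."""


class ValidationError(ValueError):
    """Rows violate a survey-design invariant (e.g. distance beyond strip)."""


@dataclass
class SurveyDataset:
    """Validated survey tables plus derived per-transect covariates."""

    events: pd.DataFrame
    transects: pd.DataFrame
    quadrats: pd.DataFrame
    covariates: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    cutpoints: tuple = DEFAULT_CUTPOINTS

    @property
    def n_transects(self) -> int:
        return len(self.transects)

    @property
    def n_pairs(self) -> int:
        return self.transects["pair_id"].nunique()

    @property
    def n_wadi_systems(self) -> int:
        return self.transects["wadi_system"].nunique()

    def write(self, events_path, transects_path, quadrats_path) -> None:
        self.events.to_csv(events_path, index=False)
        self.transects.to_csv(transects_path, index=False)
        self.quadrats.to_csv(quadrats_path, index=False)


def _require_columns(df: pd.DataFrame, required, name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def load_survey(events_path, transects_path, quadrats_path, *,
                cutpoints=DEFAULT_CUTPOINTS,
                richness_mode: str = "pooled",
                expected_quadrats: int = 11) -> SurveyDataset:
    """Read the three survey CSVs, validate them and aggregate covariates.

    Parameters
    ----------
    events_path, transects_path, quadrats_path
        CSV files with the event, transect and quadrat schemas.
    cutpoints
        Distance-interval cutpoints in meters, starting at 0 and ending at
        the strip half-width.
    richness_mode
        ``"pooled"`` (distinct species over the transect's quadrats, using
        the ``species_list`` column when present) or ``"mean"`` (mean of the
        per-quadrat richness counts).
    expected_quadrats
        Number of quadrats per transect in the design; a shortfall is
        logged as a warning but tolerated.

    Raises
    ------
    SchemaError
        A required column is absent.
    ValidationError
        Referential integrity or a unit bound is violated.
    """
    events = pd.read_csv(events_path)
    transects = pd.read_csv(transects_path)
    quadrats = pd.read_csv(quadrats_path)

    _require_columns(events, EVENT_COLUMNS, "events")
    _require_columns(transects, TRANSECT_COLUMNS, "transects")
    _require_columns(quadrats, QUADRAT_COLUMNS, "quadrats")

    bad_species = set(events["species"]) - set(SPECIES)
    if bad_species:
        raise ValidationError(f"unknown species label(s): {sorted(bad_species)}")
    bad_habitat = set(transects["habitat"]) - {"wadi", "plain"}
    if bad_habitat:
        raise ValidationError(f"unknown habitat label(s): {sorted(bad_habitat)}")

    if (transects["length_m"] <= 0).any() or (transects["half_width_m"] <= 0).any():
        raise ValidationError("transect dimensions must be positive")

    known = set(transects["transect_id"])
    orphans = events.loc[~events["transect_id"].isin(known), "transect_id"].unique()
    if len(orphans):
        raise ValidationError(f"events reference unknown transect(s): {sorted(orphans)}")
    orphans = quadrats.loc[~quadrats["transect_id"].isin(known), "transect_id"].unique()
    if len(orphans):
        raise ValidationError(f"quadrats reference unknown transect(s): {sorted(orphans)}")

    hw = transects.set_index("transect_id")["half_width_m"]
    ev_hw = events["transect_id"].map(hw)
    bad = events.index[(events["distance_m"] < 0) | (events["distance_m"] > ev_hw)]
    if len(bad):
        raise ValidationError(
            f"event distance outside [0, half-width] at rows {list(bad)}")
    if (events["n_pellets"] < 10).any():
        bad = events.index[events["n_pellets"] < 10]
        raise ValidationError(
            f"pellet events require >= 10 pellets; offending rows {list(bad)}")

    cover_cols = ["rock_pct", "litter_pct", "herb_pct", "shrub_pct", "tree_pct"]
    for c in cover_cols:
        if ((quadrats[c] < 0) | (quadrats[c] > 100)).any():
            raise ValidationError(f"quadrat cover {c} outside [0, 100]")
    if (quadrats["nonwoody_dry_g"] > quadrats["nonwoody_wet_g"] + 1e-9).any():
        raise ValidationError("dry mass exceeds wet mass in quadrats")

    counts = quadrats.groupby("transect_id").size()
    short = counts[counts != expected_quadrats]
    for tid, n in short.items():
        logger.warning("transect %s has %d quadrats (expected %d)",
                       tid, n, expected_quadrats)

    w = float(transects["half_width_m"].iloc[0])
    cp = tuple(float(c) for c in cutpoints)
    if cp[0] != 0 or any(b <= a for a, b in zip(cp, cp[1:])) or abs(cp[-1] - w) > 1e-9:
        raise ValidationError(
            f"cutpoints {cp} must rise from 0 to the half-width {w}")

    ds = SurveyDataset(events=events, transects=transects, quadrats=quadrats,
                       cutpoints=cp)
    ds.covariates = aggregate_quadrats(quadrats, transects,
                                       richness_mode=richness_mode)
    return ds


def filter_middens(events: pd.DataFrame):
    """Drop midden-flagged events; return (retained, bookkeeping).

    Bookkeeping is a DataFrame indexed by species with columns
    ``recorded``, ``middens``, ``retained`` plus a ``combined`` row, so the
    per-species accounting (recorded − middens = retained) is auditable.
    """
    flag = events["is_midden"].astype(bool)
    retained = events.loc[~flag].reset_index(drop=True)
    rows = {}
    for sp in SPECIES:
        mask = events["species"] == sp
        rec = int(mask.sum())
        mid = int((mask & flag).sum())
        rows[sp] = {"recorded": rec, "middens": mid, "retained": rec - mid}
    rows["combined"] = {k: sum(rows[sp][k] for sp in SPECIES)
                        for k in ("recorded", "middens", "retained")}
    bookkeeping = pd.DataFrame(rows).T
    return retained, bookkeeping


def bin_distances(retained: pd.DataFrame, transects: pd.DataFrame,
                  cutpoints=DEFAULT_CUTPOINTS) -> pd.DataFrame:
    """Bin retained events into distance intervals per transect × species.

    Intervals are half-open ``[lo, hi)`` with the outermost interval closed
    at the strip half-width, so a distance exactly on an interior cutpoint
    falls in the farther interval and the total count is conserved.

    Returns a DataFrame with one row per transect × species and columns
    ``bin_1 .. bin_K``; transect/species combinations without events get
    all-zero rows.
    """
    cp = np.asarray(cutpoints, float)
    if cp[0] != 0 or np.any(np.diff(cp) <= 0):
        raise ValueError(f"cutpoints must strictly increase from 0; got {cutpoints}")
    w = cp[-1]
    d = retained["distance_m"].to_numpy(float)
    if len(d) and (d.min() < 0 or d.max() > w):
        raise ValidationError("distance outside [0, half-width] in binning")
    k = np.searchsorted(cp[1:-1], d, side="right")  # [lo, hi), last closed at w
    nbins = len(cp) - 1
    idx = pd.MultiIndex.from_product(
        [transects["transect_id"], list(SPECIES)], names=["transect_id", "species"])
    out = pd.DataFrame(0, index=idx,
                       columns=[f"bin_{i + 1}" for i in range(nbins)])
    if len(d):
        grouped = pd.DataFrame({
            "transect_id": retained["transect_id"],
            "species": retained["species"],
            "k": k,
        }).groupby(["transect_id", "species", "k"]).size()
        for (tid, sp, b), n in grouped.items():
            out.loc[(tid, sp), f"bin_{b + 1}"] = n
    return out.reset_index()


def _water_content(wet: np.ndarray, dry: np.ndarray) -> float:
    """Percent plant water content from wet/dry subquadrat masses."""
    wet_t, dry_t = float(np.sum(wet)), float(np.sum(dry))
    if wet_t <= 0:
        return 0.0
    if dry_t == 0:
        logger.warning("all-zero dry mass with nonzero wet mass: water content 100%%")
    return 100.0 * (wet_t - dry_t) / wet_t


def aggregate_quadrats(quadrats: pd.DataFrame, transects: pd.DataFrame,
                       richness_mode: str = "pooled") -> pd.DataFrame:
    """Roll quadrat records up to one covariate vector per transect.

    Cover and height predictors are means over the transect's quadrats;
    biomass predictors are mean subquadrat masses; plant water content is
    derived from the pooled wet/dry nonwoody masses.  Richness is either the
    pooled count of distinct species over the transect (default, using the
    ``species_list`` column when present) or the mean per-quadrat count.
    The result also carries the transect-level predictors (habitat
    indicator, gradients, predator scats) so it is the complete design
    matrix source for density models.
    """
    if richness_mode not in ("pooled", "mean"):
        raise ValueError(f"richness_mode must be 'pooled' or 'mean', got {richness_mode!r}")
    rows = []
    tmeta = transects.set_index("transect_id")
    wadi_codes = {ws: i for i, ws in enumerate(
        pd.unique(transects["wadi_system"]))}
    for tid, grp in quadrats.groupby("transect_id", sort=False):
        if richness_mode == "pooled" and "species_list" in grp.columns and grp["species_list"].notna().any():
            pooled = set()
            for s in grp["species_list"].dropna():
                pooled.update(x for x in str(s).split(";") if x)
            richness = float(len(pooled))
        elif richness_mode == "pooled":
            # without species identities the per-quadrat max is the best
            # lower bound on the pooled distinct count
            richness = float(grp["richness"].max())
        else:
            richness = float(grp["richness"].mean())
        meta = tmeta.loc[tid]
        rows.append({
            "transect_id": tid,
            "habitat_type": 1.0 if meta["habitat"] == "plain" else 0.0,
            "wadi_location": float(wadi_codes[meta["wadi_system"]]),
            "north_south": float(meta["north_south"]),
            "east_west": float(meta["east_west"]),
            "rock_cover": grp["rock_pct"].mean(),
            "litter_cover": grp["litter_pct"].mean(),
            "herb_cover": grp["herb_pct"].mean(),
            "shrub_cover": grp["shrub_pct"].mean(),
            "tree_cover": grp["tree_pct"].mean(),
            "herb_height": grp["herb_height_cm"].mean(),
            "shrub_height": grp["shrub_height_cm"].mean(),
            "tree_height": grp["tree_height_cm"].mean(),
            "nonwoody_biomass": grp["nonwoody_wet_g"].mean(),
            "woody_biomass": grp["woody_g"].mean(),
            "plant_water": _water_content(grp["nonwoody_wet_g"].to_numpy(),
                                          grp["nonwoody_dry_g"].to_numpy()),
            "richness": richness,
            "predation": float(meta["predator_scats"]),
        })
    return pd.DataFrame(rows)
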