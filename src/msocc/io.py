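"""Survey-table formats, filtering rules and design-matrix construction.

The on-disk interchange format is a pair of CSVs:

- a long detection table with one row per performed (station, replicate,
  species): ``station_id, centre_id, replicate, species_id, detected,
  method, time_of_day``
- a station sidecar with coordinates and per-station covariates:
  ``station_id, centre_id, x, y, <covariate columns>``

Categorical design matrices use alphabetical baselines (am, net,
agricultural, primary), so reported contrasts are offsets from those levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import (
    DetectionHistory,
    Landscape,
    ReplicateDesign,
    StationCovariates,
)

__all__ = [
    "SurveyTable",
    "survey_table_from_arrays",
    "read_survey_table",
    "write_survey_table",
    "filter_species",
    "cap_replicates",
    "occupancy_design_matrix",
]

METHODS = ("net", "point")
TIMES = ("am", "pm")

DETECTION_COLUMNS = [
    "station_id",
    "centre_id",
    "replicate",
    "species_id",
    "detected",
    "method",
    "time_of_day",
]


@dataclass
class SurveyTable:
    """Validated long-format survey data plus its station sidecar."""

    detections: pd.DataFrame
    stations: pd.DataFrame

    @property
    def species_ids(self) -> np.ndarray:
        return np.sort(self.detections["species_id"].unique())

    @property
    def station_ids(self) -> np.ndarray:
        return np.sort(self.stations["station_id"].unique())

    def replicate_counts(self) -> pd.Series:
        """Performed replicates per station."""
        return (
            self.detections.groupby("station_id")["replicate"]
            .nunique()
            .reindex(self.station_ids, fill_value=0)
        )

    def to_arrays(self):
        """Rebuild dense arrays: (DetectionHistory, landscape, species_ids).

        Species and stations are ordered by sorted id; replicate slots are
        compacted in ascending replicate index.
        """
        sp_ids = self.species_ids
        st_ids = self.station_ids
        sp_ix = {s: i for i, s in enumerate(sp_ids)}
        st_ix = {s: j for j, s in enumerate(st_ids)}
        det = self.detections
        rep_rank = (
            det.groupby("station_id")["replicate"]
            .transform(lambda r: r.rank(method="dense").astype(int) - 1)
        )
        n_rep = self.replicate_counts().to_numpy()
        k_max = int(n_rep.max())
        n_sp, n_st = len(sp_ids), len(st_ids)
        y = np.full((n_sp, n_st, k_max), -1, dtype=np.int8)
        method = np.zeros((n_st, k_max), dtype=np.int8)
        time = np.zeros((n_st, k_max), dtype=np.int8)
        jj = det["station_id"].map(st_ix).to_numpy()
        ii = det["species_id"].map(sp_ix).to_numpy()
        kk = rep_rank.to_numpy()
        y[ii, jj, kk] = det["detected"].to_numpy()
        method[jj, kk] = (det["method"] == "point").to_numpy()
        time[jj, kk] = (det["time_of_day"] == "pm").to_numpy()
        design = ReplicateDesign(n_replicates=n_rep, method=method, time=time)
        history = DetectionHistory(y=y, design=design)
        st = self.stations.set_index("station_id").loc[st_ids]
        landscape = Landscape(
            centre_coords=np.empty((0, 2)),
            station_coords=st[["x", "y"]].to_numpy(float),
            centre_of_station=st["centre_id"].to_numpy(int),
        )
        return history, landscape, sp_ids


def _validate(detections: pd.DataFrame, stations: pd.DataFrame) -> None:
    problems = []
    missing_cols = [c for c in DETECTION_COLUMNS if c not in detections.columns]
    if missing_cols:
        problems.append(f"missing detection columns: {missing_cols}")
    else:
        dup = detections.duplicated(["station_id", "replicate", "species_id"])
        if dup.any():
            rows = detections.index[dup].tolist()[:10]
            problems.append(
                f"duplicate (station, replicate, species) rows at index {rows}"
            )
        bad_m = set(detections["method"].unique()) - set(METHODS)
        if bad_m:
            problems.append(f"unknown method levels: {sorted(bad_m)}")
        bad_t = set(detections["time_of_day"].unique()) - set(TIMES)
        if bad_t:
            problems.append(f"unknown time_of_day levels: {sorted(bad_t)}")
        if not detections["detected"].isin([0, 1]).all():
            problems.append("detected must be 0/1")
        unknown_st = set(detections["station_id"]) - set(stations["station_id"])
        if unknown_st:
            problems.append(
                f"stations missing from sidecar: {sorted(unknown_st)[:10]}"
            )
    if problems:
        raise ValueError("invalid survey table: " + "; ".join(problems))


def survey_table_from_arrays(
    history: DetectionHistory,
    landscape: Landscape,
    covariates: StationCovariates | None = None,
) -> SurveyTable:
    """Flatten simulated arrays into the long-format interchange tables."""
    n_sp, n_st, _ = history.y.shape
    d = history.design
    mask = d.mask()
    jj, kk = np.nonzero(mask)
    rows = {
        "station_id": np.tile(jj, n_sp),
        "centre_id": np.tile(landscape.centre_of_station[jj], n_sp),
        "replicate": np.tile(kk + 1, n_sp),
        "species_id": np.repeat(np.arange(n_sp), jj.size),
        "detected": history.y[:, jj, kk].ravel().astype(np.int64),
        "method": np.tile(np.asarray(METHODS)[d.method[jj, kk]], n_sp),
        "time_of_day": np.tile(np.asarray(TIMES)[d.time[jj, kk]], n_sp),
    }
    det = pd.DataFrame(rows)
    st = pd.DataFrame(
        {
            "station_id": np.arange(n_st),
            "centre_id": landscape.centre_of_station,
            "x": landscape.station_coords[:, 0],
            "y": landscape.station_coords[:, 1],
        }
    )
    if covariates is not None:
        for i, name in enumerate(covariates.continuous_names):
            st[name] = covariates.continuous[:, i]
        st["land_class"] = covariates.land_class
        st["forest_type"] = covariates.forest_type
        for r, radius in enumerate(("defo_1km", "defo_2km", "defo_5km")):
            st[radius] = covariates.deforestation[:, r]
    return SurveyTable(detections=det, stations=st)


def write_survey_table(table: SurveyTable, detections_path, stations_path) -> None:
    table.detections.to_csv(detections_path, index=False)
    table.stations.to_csv(stations_path, index=False)


def read_survey_table(detections_path, stations_path) -> SurveyTable:
    """Read and validate the two-CSV survey format."""
    det = pd.read_csv(detections_path)
    st = pd.read_csv(stations_path)
    _validate(det, st)
    return SurveyTable(detections=det, stations=st)


def filter_species(table: SurveyTable, min_stations: int = 10):
    """Drop species detected at ``min_stations`` or fewer distinct stations.

    The retention rule is strict: a species is kept only if it was detected
    at strictly more than ``min_stations`` stations. Returns the filtered
    table and a report DataFrame of dropped species with their counts.
    """
    if min_stations < 0:
        raise ValueError("min_stations must be >= 0")
    det = table.detections
    n_st = (
        det[det["detected"] == 1].groupby("species_id")["station_id"].nunique()
    )
    n_st = n_st.reindex(det["species_id"].unique(), fill_value=0)
    keep = n_st[n_st > min_stations].index
    report = (
        n_st[n_st <= min_stations]
        .rename("stations_detected")
        .reset_index()
        .rename(columns={"index": "species_id"})
    )
    filtered = det[det["species_id"].isin(keep)].reset_index(drop=True)
    return SurveyTable(detections=filtered, stations=table.stations), report


def cap_replicates(table: SurveyTable, cap: int = 12) -> SurveyTable:
    """Truncate each station's replicate list to its first ``cap`` replicates
    (earliest-first retention by replicate index)."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    det = table.detections
    rank = det.groupby("station_id")["replicate"].rank(method="dense")
    return SurveyTable(
        detections=det[rank <= cap].reset_index(drop=True),
        stations=table.stations,
    )


def occupancy_design_matrix(
    stations: pd.DataFrame, terms: list[str] | None
) -> tuple[np.ndarray, list[str]]:
    """Build an occupancy design matrix from station covariate columns.

    ``terms`` is a list of column names; categorical columns are expanded to
    indicator contrasts with the alphabetically first level as baseline.
    ``terms=None`` or ``[]`` gives the intercept-only design. Returns the
    matrix (with leading intercept) and column names.
    """
    st = stations.sort_values("station_id")
    cols = [np.ones(len(st))]
    names = ["intercept"]
    for term in terms or []:
        col = st[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.unique())
            for lev in levels[1:]:
                cols.append((col == lev).to_numpy(float))
                names.append(f"{term}[{lev}]")
        else:
            v = col.to_numpy(float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in covariate {term!r}")
            cols.append(v)
            names.append(term)
    return np.column_stack(cols), names
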