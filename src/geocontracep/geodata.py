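"""Geographic primitives, survey-record I/O, and nearest-facility linkage.

Records follow the analytic-sample convention: every woman entering the
pipeline is already "in need" of contraception (sexually active, fecund, not
pregnant, wanting to avoid pregnancy) — the denominator restriction happens
upstream of this package.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius

#: Allowed levels for every categorical covariate, in display order.
CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": ("15-19", "20-24", "25-34", "35-49"),
    "education": ("never", "primary", "secondary+"),
    "marital": ("not_married", "married_union", "divorced_widowed"),
    "religion": ("christian", "muslim", "other"),
    "wealth": ("low", "middle", "high"),
    "parity": ("0-1", "2-3", "4+"),
    "media": ("no", "yes"),
    "ever_pregnant": ("no", "yes"),
    "partner_discussion": ("no", "yes"),
    "partner_feeling": ("disapprove", "dont_care", "ok"),
    "fertility_intention": ("have_another", "no_preference"),
    "residence": ("urban", "rural"),
}

METHODS = ("injectable", "implant", "pill", "other")

DISTANCE_CATEGORIES = ("le2km", "2to6km", "gt6km")


class GeoValidationError(ValueError):
    """Raised when coordinates or record fields violate their constraints."""


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 longitude/latitude pair in decimal degrees."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lon) and math.isfinite(self.lat)):
            raise GeoValidationError(f"non-finite coordinate {self}")
        if not -180.0 <= self.lon <= 180.0:
            raise GeoValidationError(f"longitude {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise GeoValidationError(f"latitude {self.lat} outside [-90, 90]")


@dataclass
class SDPRecord:
    """A service delivery point (health facility offering family planning)."""

    sdp_id: str
    location: GeoPoint
    sector: str = "public"  # public | private
    offers_fp: bool = True

    def __post_init__(self) -> None:
        if self.sector not in ("public", "private"):
            raise GeoValidationError(f"sector {self.sector!r} not public/private")


@dataclass
class WomanRecord:
    """One sampled woman in need of contraception.

    ``weight`` is the design (inverse inclusion probability) sampling weight;
    ``uses_modern`` is the binary modern-contraception outcome and ``method``
    the method used (``none`` iff not using).
    """

    woman_id: str
    ea_id: str
    household_location: GeoPoint
    weight: float
    age_group: str
    education: str
    marital: str
    religion: str
    wealth: str
    parity: str
    media: str
    ever_pregnant: str
    partner_discussion: str
    partner_feeling: str
    fertility_intention: str
    residence: str
    region: str
    zone: str
    uses_modern: bool
    method: str = "none"
    sdp_distance_km: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (math.isfinite(self.weight) and self.weight > 0):
            raise GeoValidationError(f"weight must be positive, got {self.weight}")
        for name, levels in CATEGORY_LEVELS.items():
            value = getattr(self, name)
            if value not in levels:
                raise GeoValidationError(
                    f"field {name!r}: value {value!r} not in {levels}"
                )
        if self.method not in METHODS + ("none",):
            raise GeoValidationError(f"method {self.method!r} unknown")
        if (self.method != "none") != bool(self.uses_modern):
            raise GeoValidationError(
                f"method {self.method!r} inconsistent with uses_modern={self.uses_modern}"
            )
        if self.sdp_distance_km is not None and not (
            math.isfinite(self.sdp_distance_km) and self.sdp_distance_km >= 0
        ):
            raise GeoValidationError(
                f"sdp_distance_km must be nonnegative, got {self.sdp_distance_km}"
            )


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in km on the mean-radius sphere.

    Symmetric, zero iff the points coincide, and within ~0.5% of the
    ellipsoidal geodesic at country scale.
    """
    lon1, lat1, lon2, lat2 = map(
        math.radians, (a.lon, a.lat, b.lon, b.lat)
    )
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2.0) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(
        dlon / 2.0
    ) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def pairwise_haversine_km(points: Sequence[GeoPoint]):
    """Symmetric matrix of great-circle distances (km), vectorised."""
    import numpy as np

    lon = np.radians([p.lon for p in points])
    lat = np.radians([p.lat for p in points])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def cross_haversine_km(points_a: Sequence[GeoPoint], points_b: Sequence[GeoPoint]):
    """Rectangular matrix of great-circle distances (km) between two sets."""
    import numpy as np

    lon_a = np.radians([p.lon for p in points_a])
    lat_a = np.radians([p.lat for p in points_a])
    lon_b = np.radians([p.lon for p in points_b])
    lat_b = np.radians([p.lat for p in points_b])
    dlat = lat_a[:, None] - lat_b[None, :]
    dlon = lon_a[:, None] - lon_b[None, :]
    h = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat_a)[:, None] * np.cos(lat_b)[None, :] * np.sin(dlon / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def nearest_sdp_distance(
    woman: WomanRecord, sdps: Sequence[SDPRecord]
) -> float:
    """Distance (km) from the woman's household to her nearest facility.

    Ties are broken by the smallest ``sdp_id`` so linkage is deterministic.
    """
    if not sdps:
        raise GeoValidationError("SDP list is empty")
    best = min(
        sdps,
        key=lambda s: (haversine_km(woman.household_location, s.location), s.sdp_id),
    )
    return haversine_km(woman.household_location, best.location)


def link_nearest_sdp(
    women: Sequence[WomanRecord], sdps: Sequence[SDPRecord]
) -> list[WomanRecord]:
    """Fill ``sdp_distance_km`` on every record (vectorised; returns new list)."""
    import numpy as np

    if not sdps:
        raise GeoValidationError("SDP list is empty")
    d = cross_haversine_km(
        [w.household_location for w in women], [s.location for s in sdps]
    )
    dmin = d.min(axis=1)
    return [replace(w, sdp_distance_km=float(di)) for w, di in zip(women, dmin)]


def categorize_distance(d_km: float) -> str:
    """Map a nonnegative distance to the {le2km, 2to6km, gt6km} partition.

    Categories are closed on the right: 2.0 km -> le2km, 6.0 km -> 2to6km.
    """
    if not (math.isfinite(d_km) and d_km >= 0):
        raise GeoValidationError(f"distance must be nonnegative, got {d_km}")
    if d_km <= 2.0:
        return "le2km"
    if d_km <= 6.0:
        return "2to6km"
    return "gt6km"


# ---------------------------------------------------------------------------
# CSV I/O

_WOMAN_COLUMNS = [
    "woman_id", "ea_id", "lon", "lat", "weight",
    *CATEGORY_LEVELS.keys(),
    "region", "zone", "uses_modern", "method", "sdp_distance_km",
]

_SDP_COLUMNS = ["sdp_id", "lon", "lat", "sector", "offers_fp"]


def _record_to_row(w: WomanRecord) -> dict[str, str]:
    row = {
        "woman_id": w.woman_id,
        "ea_id": w.ea_id,
        "lon": repr(w.household_location.lon),
        "lat": repr(w.household_location.lat),
        "weight": repr(w.weight),
        "region": w.region,
        "zone": w.zone,
        "uses_modern": "1" if w.uses_modern else "0",
        "method": w.method,
        "sdp_distance_km": "" if w.sdp_distance_km is None else repr(w.sdp_distance_km),
    }
    for name in CATEGORY_LEVELS:
        row[name] = getattr(w, name)
    return row


def write_records(records: Iterable[WomanRecord], path: str | Path) -> None:
    """Write woman records as RFC-4180 CSV with full-precision floats."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_WOMAN_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for w in records:
            writer.writerow(_record_to_row(w))


def read_records(path: str | Path) -> list[WomanRecord]:
    """Read woman records from CSV, rejecting malformed rows with their number."""
    records: list[WomanRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise GeoValidationError(f"{path}: empty file, header required")
        missing = set(_WOMAN_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise GeoValidationError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                dist = row["sdp_distance_km"]
                records.append(
                    WomanRecord(
                        woman_id=row["woman_id"],
                        ea_id=row["ea_id"],
                        household_location=GeoPoint(
                            float(row["lon"]), float(row["lat"])
                        ),
                        weight=float(row["weight"]),
                        **{k: row[k] for k in CATEGORY_LEVELS},
                        region=row["region"],
                        zone=row["zone"],
                        uses_modern=row["uses_modern"] == "1",
                        method=row["method"],
                        sdp_distance_km=None if dist == "" else float(dist),
                    )
                )
            except (GeoValidationError, ValueError, KeyError) as exc:
                raise GeoValidationError(f"{path} row {i}: {exc}") from exc
    return records


def write_sdps(sdps: Iterable[SDPRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_SDP_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for s in sdps:
            writer.writerow(
                {
                    "sdp_id": s.sdp_id,
                    "lon": repr(s.location.lon),
                    "lat": repr(s.location.lat),
                    "sector": s.sector,
                    "offers_fp": "1" if s.offers_fp else "0",
                }
            )


def read_sdps(path: str | Path) -> list[SDPRecord]:
    sdps: list[SDPRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise GeoValidationError(f"{path}: empty file, header required")
        missing = set(_SDP_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise GeoValidationError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                sdps.append(
                    SDPRecord(
                        sdp_id=row["sdp_id"],
                        location=GeoPoint(float(row["lon"]), float(row["lat"])),
                        sector=row["sector"],
                        offers_fp=row["offers_fp"] == "1",
                    )
                )
            except (GeoValidationError, ValueError, KeyError) as exc:
                raise GeoValidationError(f"{path} row {i}: {exc}") from exc
    return sdps


def read_polygons(path: str | Path) -> dict[str, BaseGeometry]:
    """Read admin polygons from a GeoJSON FeatureCollection.

    The feature property ``name`` is the join key; geometries must be
    Polygon or MultiPolygon.
    """
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise GeoValidationError(f"{path}: expected a FeatureCollection")
    out: dict[str, BaseGeometry] = {}
    for feat in gj["features"]:
        name = feat.get("properties", {}).get("name")
        if name is None:
            raise GeoValidationError(f"{path}: feature missing 'name' property")
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise GeoValidationError(
                f"{path}: feature {name!r} has type {geom.geom_type}"
            )
        out[name] = geom
    return out
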