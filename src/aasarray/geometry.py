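"""Station geometry: placing a linear array on the sphere and
great-circle (haversine) distances between stations.

Earth is treated as a sphere of radius 6,378,137 m (the WGS-84
equatorial radius, the default of the common geographic-distance
tools); the radius is configurable in every function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_M = 6_378_137.0


@dataclass(frozen=True)
class StationGeometry:
    """One hydrophone station: id, instrument model tag, position."""

    station_id: str
    instrument: str  # "LS" or "ST"
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude out of range: {self.lat}")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude out of range: {self.lon}")


def destination_point(
    lat: float, lon: float, bearing_deg: float, distance_m: float, radius_m: float = EARTH_RADIUS_M
) -> tuple[float, float]:
    """Great-circle destination from (lat, lon) along an initial bearing."""
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    theta = np.radians(bearing_deg)
    delta = distance_m / radius_m
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    lon2 = (np.degrees(lam2) + 540.0) % 360.0 - 180.0
    return float(np.degrees(phi2)), float(lon2)


def make_geometry(config) -> list[StationGeometry]:
    """Place ``config.n_stations`` stations ``config.spacing_m`` apart
    along ``config.bearing_deg`` from the array origin.

    Deterministic given the configuration; station ids alternate the
    two instrument tags (LS at even positions, ST at odd).
    """
    stations = []
    for k, sid in enumerate(config.station_ids):
        lat, lon = destination_point(
            config.origin_lat, config.origin_lon, config.bearing_deg, k * config.spacing_m
        )
        stations.append(StationGeometry(sid, sid[:2], lat, lon))
    return stations


def haversine_m(
    lat1, lon1, lat2, lon2, radius_m: float = EARTH_RADIUS_M
):
    """Haversine great-circle distance in meters (vectorized)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    if np.any(np.abs(np.degrees(lat1)) > 90) or np.any(np.abs(np.degrees(lat2)) > 90):
        raise ValueError("latitude out of range")
    dphi = lat2 - lat1
    dlam = lon2 - lon1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * radius_m * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def haversine_matrix(geometry, radius_m: float = EARTH_RADIUS_M) -> np.ndarray:
    """Symmetric station-by-station great-circle distance matrix (m)."""
    lat = np.array([g.lat for g in geometry])
    lon = np.array([g.lon for g in geometry])
    d = haversine_m(lat[:, None], lon[:, None], lat[None, :], lon[None, :], radius_m)
    d = np.asarray(d, dtype=float)
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)
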