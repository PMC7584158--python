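"""Geohash clustering and great-circle distance.

A geohash interleaves longitude and latitude bits (longitude first) and
renders them in a base-32 alphabet; at precision 8 (40 bits: 20 per axis)
the equatorial cell measures about 38.2 m east-west by 19.1 m north-south,
which is the clustering resolution used for the engineered location
features ``cl_latitude``/``cl_longitude``.
"""

from __future__ import annotations

import math

__all__ = [
    "geohash_encode",
    "geohash_decode",
    "geohash_cluster",
    "geohash_cell_extent_m",
    "haversine_dist",
    "EARTH_RADIUS_M",
]

_BASE32 = "0123456789bcdefghjkmnpqrstuvwxyz"

#: IUGG mean Earth radius, metres.
EARTH_RADIUS_M = 6_371_008.8


def _check_coords(lat: float, lon: float) -> None:
    if not (-90.0 <= lat <= 90.0):
        raise ValueError(f"latitude {lat} outside [-90, 90]")
    if not (-180.0 <= lon <= 180.0):
        raise ValueError(f"longitude {lon} outside [-180, 180]")


def geohash_encode(lat: float, lon: float, precision: int = 8) -> str:
    """Encode a WGS-84 point as a base-32 geohash of ``precision`` chars."""
    _check_coords(lat, lon)
    lat_lo, lat_hi = -90.0, 90.0
    lon_lo, lon_hi = -180.0, 180.0
    bits = []
    even = True  # longitude bit first
    while len(bits) < precision * 5:
        if even:
            mid = (lon_lo + lon_hi) / 2
            if lon >= mid:
                bits.append(1)
                lon_lo = mid
            else:
                bits.append(0)
                lon_hi = mid
        else:
            mid = (lat_lo + lat_hi) / 2
            if lat >= mid:
                bits.append(1)
                lat_lo = mid
            else:
                bits.append(0)
                lat_hi = mid
        even = not even
    chars = []
    for i in range(0, len(bits), 5):
        idx = 0
        for b in bits[i : i + 5]:
            idx = (idx << 1) | b
        chars.append(_BASE32[idx])
    return "".join(chars)


def geohash_decode(code: str) -> tuple[float, float]:
    """Decode a geohash to the centre (lat, lon) of its cell."""
    lat_lo, lat_hi = -90.0, 90.0
    lon_lo, lon_hi = -180.0, 180.0
    even = True
    for ch in code:
        try:
            idx = _BASE32.index(ch)
        except ValueError:
            raise ValueError(f"invalid geohash character {ch!r}") from None
        for shift in range(4, -1, -1):
            bit = (idx >> shift) & 1
            if even:
                mid = (lon_lo + lon_hi) / 2
                if bit:
                    lon_lo = mid
                else:
                    lon_hi = mid
            else:
                mid = (lat_lo + lat_hi) / 2
                if bit:
                    lat_lo = mid
                else:
                    lat_hi = mid
            even = not even
    return (lat_lo + lat_hi) / 2, (lon_lo + lon_hi) / 2


def geohash_cluster(lat: float, lon: float, precision: int = 8) -> tuple[float, float]:
    """Snap a point to the centre of its geohash cell.

    Returns the clustered ``(cl_latitude, cl_longitude)`` pair: all points
    within the same precision-``precision`` cell map to identical values.
    """
    return geohash_decode(geohash_encode(lat, lon, precision))


def geohash_cell_extent_m(precision: int = 8, lat: float = 0.0) -> tuple[float, float]:
    """Cell size (east-west, north-south) in metres at latitude ``lat``.

    Precision-8 cells span 360/2**20 degrees of longitude and 180/2**20
    degrees of latitude.
    """
    nbits = precision * 5
    lon_bits = nbits - nbits // 2
    lat_bits = nbits // 2
    lon_deg = 360.0 / (1 << lon_bits)
    lat_deg = 180.0 / (1 << lat_bits)
    m_per_deg = EARTH_RADIUS_M * math.pi / 180.0
    return lon_deg * m_per_deg * math.cos(math.radians(lat)), lat_deg * m_per_deg


def haversine_dist(prev: tuple[float, float], cur: tuple[float, float]) -> float:
    """Great-circle distance in metres between two (lat, lon) points."""
    lat1, lon1 = prev
    lat2, lon2 = cur
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(h)))
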