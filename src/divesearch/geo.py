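"""Geodetic helpers: UTM projection and solar elevation.

Tracks are worked on in planar meters. Lon/lat fixes are projected with a
WGS84 transverse-Mercator (UTM) projection; the inverse is used to recover
geographic coordinates for interpolated fixes (needed by the solar night
filter). Solar elevation follows the NOAA general solar-position
approximation, which is accurate to ~0.2 degrees — ample for a civil-twilight
(-6 degree) cut.
"""

from __future__ import annotations

import numpy as np

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)
_EP2 = _E2 / (1.0 - _E2)
_K0 = 0.9996
_FALSE_EASTING = 500000.0


def utm_zone_lon0(zone: int) -> float:
    """Central meridian (degrees) of a UTM zone (1-60)."""
    if not 1 <= zone <= 60:
        raise ValueError(f"UTM zone must be in 1..60, got {zone}")
    return -183.0 + 6.0 * zone


def _meridian_arc(phi: np.ndarray) -> np.ndarray:
    e2, e4, e6 = _E2, _E2**2, _E2**3
    return _A * (
        (1 - e2 / 4 - 3 * e4 / 64 - 5 * e6 / 256) * phi
        - (3 * e2 / 8 + 3 * e4 / 32 + 45 * e6 / 1024) * np.sin(2 * phi)
        + (15 * e4 / 256 + 45 * e6 / 1024) * np.sin(4 * phi)
        - (35 * e6 / 3072) * np.sin(6 * phi)
    )


def project(lon, lat, zone: int = 30):
    """Forward UTM projection (northern hemisphere), degrees -> meters.

    Returns (x, y) arrays. Accuracy is sub-millimeter within the zone and
    degrades gracefully a few degrees outside it.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    phi = np.radians(lat)
    lam = np.radians(lon - utm_zone_lon0(zone))

    sinp, cosp, tanp = np.sin(phi), np.cos(phi), np.tan(phi)
    n = _A / np.sqrt(1 - _E2 * sinp**2)
    t = tanp**2
    c = _EP2 * cosp**2
    a_ = lam * cosp
    m = _meridian_arc(phi)

    x = _K0 * n * (
        a_
        + (1 - t + c) * a_**3 / 6
        + (5 - 18 * t + t**2 + 72 * c - 58 * _EP2) * a_**5 / 120
    ) + _FALSE_EASTING
    y = _K0 * (
        m
        + n * tanp * (
            a_**2 / 2
            + (5 - t + 9 * c + 4 * c**2) * a_**4 / 24
            + (61 - 58 * t + t**2 + 600 * c - 330 * _EP2) * a_**6 / 720
        )
    )
    return x, y


def unproject(x, y, zone: int = 30):
    """Inverse UTM projection, meters -> (lon, lat) degrees."""
    x = np.asarray(x, dtype=float) - _FALSE_EASTING
    y = np.asarray(y, dtype=float)

    m = y / _K0
    mu = m / (_A * (1 - _E2 / 4 - 3 * _E2**2 / 64 - 5 * _E2**3 / 256))
    e1 = (1 - np.sqrt(1 - _E2)) / (1 + np.sqrt(1 - _E2))
    # footpoint latitude
    phi1 = mu + (
        (3 * e1 / 2 - 27 * e1**3 / 32) * np.sin(2 * mu)
        + (21 * e1**2 / 16 - 55 * e1**4 / 32) * np.sin(4 * mu)
        + (151 * e1**3 / 96) * np.sin(6 * mu)
        + (1097 * e1**4 / 512) * np.sin(8 * mu)
    )

    sinp, cosp, tanp = np.sin(phi1), np.cos(phi1), np.tan(phi1)
    c1 = _EP2 * cosp**2
    t1 = tanp**2
    n1 = _A / np.sqrt(1 - _E2 * sinp**2)
    r1 = _A * (1 - _E2) / (1 - _E2 * sinp**2) ** 1.5
    d = x / (n1 * _K0)

    phi = phi1 - (n1 * tanp / r1) * (
        d**2 / 2
        - (5 + 3 * t1 + 10 * c1 - 4 * c1**2 - 9 * _EP2) * d**4 / 24
        + (61 + 90 * t1 + 298 * c1 + 45 * t1**2 - 252 * _EP2 - 3 * c1**2) * d**6 / 720
    )
    lam = (
        d
        - (1 + 2 * t1 + c1) * d**3 / 6
        + (5 - 2 * c1 + 28 * t1 - 3 * c1**2 + 8 * _EP2 + 24 * t1**2) * d**5 / 120
    ) / cosp

    lat = np.degrees(phi)
    lon = utm_zone_lon0(zone) + np.degrees(lam)
    return lon, lat


def solar_elevation(t_unix, lon, lat):
    """Solar elevation angle (degrees) at UTC unix time(s) and position(s).

    NOAA general solar-position formulas (fractional-year Fourier fits for
    the equation of time and declination).
    """
    t = np.asarray(t_unix, dtype=float)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)

    days = t / 86400.0  # days since 1970-01-01 UTC
    # day of year and fractional hour, ignoring leap seconds
    year_day = np.floor(days) % 365.25
    frac_hour = (days - np.floor(days)) * 24.0
    gamma = 2 * np.pi / 365.0 * (year_day + (frac_hour - 12.0) / 24.0)

    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )

    time_offset = eqtime + 4.0 * lon  # minutes
    tst = frac_hour * 60.0 + time_offset
    ha = np.radians(tst / 4.0 - 180.0)

    phi = np.radians(lat)
    cos_zenith = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(ha)
    cos_zenith = np.clip(cos_zenith, -1.0, 1.0)
    return 90.0 - np.degrees(np.arccos(cos_zenith))


def bearing(dx, dy):
    """Planar bearing in radians, mathematical convention (CCW from +x)."""
    return np.arctan2(dy, dx)
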