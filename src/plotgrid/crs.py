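"""Minimal projected-CRS handling for plot layers.

Plots are meter/foot-scale rectangles, so only projected CRSs with a linear
unit of meters or feet are supported; geographic (degree) CRSs are rejected.
A CRS is given either as a WKT string or as an ``EPSG:nnnn`` code from a
small built-in table (WGS84/NAD83 UTM zones and Web Mercator).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_FOOT = 0.3048  # international foot, exact

_UTM_WGS84 = (
    'PROJCS["WGS 84 / UTM zone {zone}{hemi}",GEOGCS["WGS 84",'
    'DATUM["WGS_1984",SPHEROID["WGS 84",6378137,298.257223563]],'
    'PRIMEM["Greenwich",0],UNIT["degree",0.0174532925199433]],'
    'PROJECTION["Transverse_Mercator"],'
    'PARAMETER["latitude_of_origin",0],'
    'PARAMETER["central_meridian",{lon}],'
    'PARAMETER["scale_factor",0.9996],'
    'PARAMETER["false_easting",500000],'
    'PARAMETER["false_northing",{fn}],'
    'UNIT["metre",1],AUTHORITY["EPSG","{code}"]]'
)

_UTM_NAD83 = (
    'PROJCS["NAD83 / UTM zone {zone}N",GEOGCS["NAD83",'
    'DATUM["North_American_Datum_1983",SPHEROID["GRS 1980",6378137,298.257222101]],'
    'PRIMEM["Greenwich",0],UNIT["degree",0.0174532925199433]],'
    'PROJECTION["Transverse_Mercator"],'
    'PARAMETER["latitude_of_origin",0],'
    'PARAMETER["central_meridian",{lon}],'
    'PARAMETER["scale_factor",0.9996],'
    'PARAMETER["false_easting",500000],'
    'PARAMETER["false_northing",0],'
    'UNIT["metre",1],AUTHORITY["EPSG","{code}"]]'
)

_WEB_MERCATOR = (
    'PROJCS["WGS 84 / Pseudo-Mercator",GEOGCS["WGS 84",'
    'DATUM["WGS_1984",SPHEROID["WGS 84",6378137,298.257223563]],'
    'PRIMEM["Greenwich",0],UNIT["degree",0.0174532925199433]],'
    'PROJECTION["Mercator_1SP"],PARAMETER["central_meridian",0],'
    'PARAMETER["scale_factor",1],PARAMETER["false_easting",0],'
    'PARAMETER["false_northing",0],UNIT["metre",1],'
    'AUTHORITY["EPSG","3857"]]'
)


class CRSError(ValueError):
    """Raised for unparseable, geographic, or unsupported-unit CRSs."""


@dataclass(frozen=True)
class CRS:
    """A projected CRS: its WKT and the size of its linear unit in meters."""

    wkt: str
    unit_to_meters: float

    @property
    def linear_unit(self) -> str:
        return "foot" if abs(self.unit_to_meters - _FOOT) < 1e-9 else "meter"


def _epsg_wkt(code: int) -> str:
    if 32601 <= code <= 32660:  # WGS84 UTM north
        zone = code - 32600
        return _UTM_WGS84.format(zone=zone, hemi="N", lon=zone * 6 - 183, fn=0, code=code)
    if 32701 <= code <= 32760:  # WGS84 UTM south
        zone = code - 32700
        return _UTM_WGS84.format(
            zone=zone, hemi="S", lon=zone * 6 - 183, fn=10000000, code=code
        )
    if 26901 <= code <= 26923:  # NAD83 UTM north
        zone = code - 26900
        return _UTM_NAD83.format(zone=zone, lon=zone * 6 - 183, code=code)
    if code == 3857:
        return _WEB_MERCATOR
    raise CRSError(
        f"EPSG:{code} is not in the built-in table; pass the CRS as WKT instead"
    )


def _wkt_linear_unit(wkt: str) -> float:
    """Factor (meters per unit) of the projected CRS's linear UNIT.

    The projection unit is the last UNIT[...] entry of a PROJCS (the first
    belongs to the geographic base and is in degrees/radians).
    """
    units = re.findall(r'UNIT\s*\[\s*"([^"]*)"\s*,\s*([0-9.eE+-]+)', wkt)
    if not units:
        raise CRSError("WKT has no UNIT entry")
    name, factor = units[-1]
    factor = float(factor)
    if abs(factor - 1.0) < 1e-9 or abs(factor - _FOOT) < 1e-6:
        return 1.0 if abs(factor - 1.0) < 1e-9 else _FOOT
    raise CRSError(
        f"unsupported CRS linear unit {name!r} ({factor} m); "
        "only meter- and foot-based projected CRSs are supported"
    )


def parse_crs(text: str) -> CRS:
    """Parse an ``EPSG:nnnn`` code or a WKT string into a :class:`CRS`."""
    text = text.strip()
    if not text:
        raise CRSError("empty CRS identifier")
    m = re.fullmatch(r"(?i)EPSG\s*:\s*(\d+)", text)
    if m:
        wkt = _epsg_wkt(int(m.group(1)))
    elif text.upper().startswith(("PROJCS", "GEOGCS", "PROJCRS", "GEOGCRS")):
        wkt = text
    else:
        raise CRSError(f"cannot interpret CRS identifier {text!r}")
    head = wkt.lstrip().upper()
    if head.startswith(("GEOGCS", "GEOGCRS")):
        raise CRSError(
            "geographic (degree-unit) CRSs are not supported; "
            "use a projected CRS so plots have meter/foot coordinates"
        )
    return CRS(wkt=wkt, unit_to_meters=_wkt_linear_unit(wkt))
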