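"""Sunrise/sunset providers for day-roost assignment.

Two interchangeable sources of sun times:

* :class:`TableSunProvider` — user-supplied per-date sunrise/sunset table.
* :class:`SolarSunProvider` — the standard NOAA solar-position approximation
  from latitude/longitude, returning local clock times via a fixed UTC
  offset.  Defaults to Salmonier Nature Park, Newfoundland (47.3 N, 53.3 W)
  on Newfoundland Daylight Time (UTC-2:30), the study system's summer zone.

All timestamps in the package are naive local times in one configured zone;
the providers return naive :class:`datetime.datetime` values on the same
clock.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Mapping, Protocol, Tuple

__all__ = ["SunProvider", "TableSunProvider", "SolarSunProvider"]


class SunProvider(Protocol):
    def sunset(self, date: dt.date) -> dt.datetime: ...

    def sunrise(self, date: dt.date) -> dt.datetime: ...


class TableSunProvider:
    """Sun times looked up from a per-date table.

    Parameters
    ----------
    table:
        Mapping ``date -> (sunrise, sunset)`` of naive local datetimes
        (or time-of-day values, which are attached to the date).
    """

    def __init__(self, table: Mapping[dt.date, Tuple[object, object]]):
        self._table: dict[dt.date, tuple[dt.datetime, dt.datetime]] = {}
        for date, (rise, set_) in table.items():
            self._table[date] = (_as_datetime(date, rise), _as_datetime(date, set_))

    def sunrise(self, date: dt.date) -> dt.datetime:
        try:
            return self._table[date][0]
        except KeyError:
            raise KeyError(f"no sunrise entry for {date}") from None

    def sunset(self, date: dt.date) -> dt.datetime:
        try:
            return self._table[date][1]
        except KeyError:
            raise KeyError(f"no sunset entry for {date}") from None


def _as_datetime(date: dt.date, value: object) -> dt.datetime:
    if isinstance(value, dt.datetime):
        return value
    if isinstance(value, dt.time):
        return dt.datetime.combine(date, value)
    raise TypeError(f"expected datetime or time, got {type(value)!r}")


class SolarSunProvider:
    """NOAA solar-position approximation for sunrise and sunset.

    Uses the fractional-year / equation-of-time / declination expansion from
    the NOAA solar calculator with the standard refraction-corrected zenith
    of 90.833 degrees.  Accurate to a couple of minutes at mid latitudes,
    which is ample for a "last detection before sunset" rule whose inputs
    are minutes-to-hours away from the boundary.

    Parameters
    ----------
    latitude, longitude:
        Decimal degrees; east/north positive.  Default Salmonier Nature
        Park (47.3, -53.3).
    utc_offset_hours:
        Fixed local-clock offset from UTC.  Default -2.5 (Newfoundland
        Daylight Time, in force throughout the maternity season).
    """

    def __init__(
        self,
        latitude: float = 47.3,
        longitude: float = -53.3,
        utc_offset_hours: float = -2.5,
    ):
        if not -90.0 <= latitude <= 90.0:
            raise ValueError("latitude out of range")
        self.latitude = latitude
        self.longitude = longitude
        self.utc_offset_hours = utc_offset_hours

    def _event_minutes(self, date: dt.date, rising: bool) -> float:
        doy = date.timetuple().tm_yday
        # fractional year, radians (noon approximation suffices)
        gamma = 2.0 * math.pi / 365.0 * (doy - 1 + 0.5)
        eqtime = 229.18 * (
            0.000075
            + 0.001868 * math.cos(gamma)
            - 0.032077 * math.sin(gamma)
            - 0.014615 * math.cos(2 * gamma)
            - 0.040849 * math.sin(2 * gamma)
        )
        decl = (
            0.006918
            - 0.399912 * math.cos(gamma)
            + 0.070257 * math.sin(gamma)
            - 0.006758 * math.cos(2 * gamma)
            + 0.000907 * math.sin(2 * gamma)
            - 0.002697 * math.cos(3 * gamma)
            + 0.00148 * math.sin(3 * gamma)
        )
        lat = math.radians(self.latitude)
        zenith = math.radians(90.833)
        cos_ha = (math.cos(zenith) - math.sin(lat) * math.sin(decl)) / (
            math.cos(lat) * math.cos(decl)
        )
        if cos_ha > 1.0 or cos_ha < -1.0:
            raise ValueError(
                f"sun does not rise/set at latitude {self.latitude} on {date}"
            )
        ha = math.degrees(math.acos(cos_ha))
        if not rising:
            ha = -ha
        utc_minutes = 720.0 - 4.0 * (self.longitude + ha) - eqtime
        return utc_minutes + self.utc_offset_hours * 60.0

    def _event(self, date: dt.date, rising: bool) -> dt.datetime:
        minutes = self._event_minutes(date, rising)
        base = dt.datetime.combine(date, dt.time(0, 0))
        return base + dt.timedelta(minutes=minutes)

    def sunrise(self, date: dt.date) -> dt.datetime:
        return self._event(date, rising=True)

    def sunset(self, date: dt.date) -> dt.datetime:
        return self._event(date, rising=False)
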