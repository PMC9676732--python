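"""Five-year age-band conventions shared by all tables.

Bands are the 18 GLOBOCAN-style groups 0-4, 5-9, ..., 80-84, 85+.  Labels are
canonicalized to ``"lo-hi"`` with ``"85+"`` open-ended; en/em dashes and spaces
in source files are tolerated.  Deaths at 85+ can never produce orphans (the
reproductive span ends at 49, so mothers older than 67 at death have no minor
children), hence the open band's width never matters.
"""

from __future__ import annotations

import re

from .errors import ValidationError

#: Inclusive lower bounds of the 18 canonical bands.
BAND_STARTS = list(range(0, 90, 5))

#: Canonical band labels, "0-4" ... "80-84", "85+".
BAND_LABELS = [f"{lo}-{lo + 4}" for lo in BAND_STARTS[:-1]] + ["85+"]

#: Female reproductive span (inclusive); fertility is zero outside it.
FERTILE_MIN = 15
FERTILE_MAX = 49

#: Oldest maternal age at death that can leave a minor child
#: (49 at last possible birth + child just under 18).
MAX_ORPHANING_AGE = 67

_DASHES = re.compile(r"[‐‑‒–—―]")


def canonical_band(label: str) -> str:
    """Canonicalize an age-band label to ``"lo-hi"`` or ``"85+"``.

    Raises :class:`ValidationError` for labels that are not 5-year bands
    starting at a multiple of five (or the open 85+ band).
    """
    s = _DASHES.sub("-", str(label)).strip().replace(" ", "")
    if s in ("85+", "85plus", "85-"):
        return "85+"
    m = re.fullmatch(r"(\d+)-(\d+)", s)
    if not m:
        raise ValidationError(f"unrecognized age-band label: {label!r}")
    lo, hi = int(m.group(1)), int(m.group(2))
    if lo % 5 != 0 or hi != lo + 4:
        raise ValidationError(f"not a canonical 5-year band: {label!r}")
    if lo >= 85:
        return "85+"
    return f"{lo}-{hi}"


def band_bounds(label: str) -> tuple[int, int | None]:
    """Return (lo, hi) of a canonical band; hi is None for the open 85+ band."""
    c = canonical_band(label)
    if c == "85+":
        return 85, None
    lo, hi = c.split("-")
    return int(lo), int(hi)


def band_of_age(age: int) -> str:
    """Canonical band label containing a single age."""
    if age < 0:
        raise ValidationError(f"negative age: {age}")
    return "85+" if age >= 85 else f"{5 * (age // 5)}-{5 * (age // 5) + 4}"


def band_ages(label: str) -> list[int]:
    """The five single ages of a band (85+ is represented as 85..89)."""
    lo, hi = band_bounds(label)
    return list(range(lo, (hi if hi is not None else lo + 4) + 1))


def parse_period(label: str) -> tuple[int, int]:
    """Parse a 5-year calendar-period label like ``"2010-2014"`` to (start, end).

    Periods follow the UN WPP mid-year convention (1 July of the start year to
    30 June of the year after the end year); the label lookup is by calendar
    year: year ``y`` belongs to the period with ``start <= y <= end``.
    """
    s = _DASHES.sub("-", str(label)).strip().replace(" ", "")
    m = re.fullmatch(r"(\d{4})-(\d{4})", s)
    if not m:
        raise ValidationError(f"unrecognized period label: {label!r}")
    start, end = int(m.group(1)), int(m.group(2))
    if end - start != 4:
        raise ValidationError(f"not a 5-year period: {label!r}")
    return start, end


def period_label(start: int) -> str:
    return f"{start}-{start + 4}"
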