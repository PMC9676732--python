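"""Cancer-site vocabulary and site -> reporting-group map.

The death table uses 35 exhaustive, mutually exclusive topographic site labels
(a GLOBOCAN-style breakdown of all malignancies, ICD-10 C00-97, in women).
For reporting they collapse onto 14 groups.  Both live in an editable YAML
configuration shipped with the package (``data/site_groups.yaml``); a custom
map may be supplied, but it must cover the full vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ValidationError

#: The 14 reporting groups.
GROUPS: tuple[str, ...] = (
    "Breast",
    "Cervical",
    "Upper gastrointestinal",
    "Hematological",
    "Other female-specific",
    "Lower gastrointestinal",
    "Respiratory",
    "Brain and nervous system",
    "Head and Neck",
    "Genitourinary",
    "Skin cancer",
    "Kaposi Sarcoma",
    "Thyroid",
    "Other",
)

#: A few tolerated aliases for site labels seen in exports.
SITE_ALIASES: dict[str, str] = {
    "cervix": "Cervix uteri",
    "cervix uteri": "Cervix uteri",
    "cervical": "Cervix uteri",
    "lung": "Trachea, bronchus and lung",
    "trachea, bronchus and lung": "Trachea, bronchus and lung",
    "breast": "Breast",
    "ovary": "Ovary",
    "corpus uteri": "Corpus uteri",
    "leukemia": "Leukaemia",
    "esophagus": "Oesophagus",
    "kaposi's sarcoma": "Kaposi sarcoma",
    "brain, nervous system": "Brain, central nervous system",
}


def _load_default_map() -> dict[str, str]:
    with resources.files("cancer_orphans.data").joinpath("site_groups.yaml").open() as fh:
        return yaml.safe_load(fh)


_DEFAULT_MAP = _load_default_map()

#: The 35-site vocabulary (keys of the shipped map, order preserved).
SITES: tuple[str, ...] = tuple(_DEFAULT_MAP)


def normalize_site(label: str, vocabulary: tuple[str, ...] = SITES) -> str:
    """Return the canonical site label, resolving known aliases.

    Raises :class:`ValidationError` naming the label if it is unknown.
    """
    s = str(label).strip()
    if s in vocabulary:
        return s
    alias = SITE_ALIASES.get(s.lower())
    if alias is not None and alias in vocabulary:
        return alias
    raise ValidationError(f"unknown cancer site label: {label!r}")


@dataclass(frozen=True)
class SiteGroupMap:
    """Total mapping site label -> one of the 14 reporting groups."""

    mapping: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_MAP))

    def __post_init__(self) -> None:
        missing = [s for s in SITES if s not in self.mapping]
        if missing:
            raise ValidationError(f"site-group map is not total; missing sites: {missing}")
        bad = sorted(set(self.mapping.values()) - set(GROUPS))
        if bad:
            raise ValidationError(f"unknown reporting groups in map: {bad}")

    def group_of(self, site: str) -> str:
        return self.mapping[normalize_site(site, tuple(self.mapping))]

    @property
    def groups(self) -> tuple[str, ...]:
        return GROUPS


def load_site_groups(path: str | Path | None = None) -> SiteGroupMap:
    """Load a site -> group map from YAML, or the packaged default."""
    if path is None:
        return SiteGroupMap()
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise ValidationError(f"site-group file {path} is not a mapping")
    return SiteGroupMap({str(k): str(v) for k, v in mapping.items()})
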