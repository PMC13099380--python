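"""Region atlases: ordered region lists with anatomical class and hemisphere.

The atlas fixes the row/column order of every association matrix downstream,
so region order is part of the analysis contract, not a display choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

REGION_CLASSES = ("cortical", "subcortical", "amygdala_subnucleus")
HEMISPHERES = ("left", "right", "midline")

DEFAULT_ATLAS_RESOURCE = "atlas_amygdala105.yaml"


@dataclass(frozen=True)
class Region:
    name: str
    region_class: str
    hemisphere: str

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(
                f"unknown region class {self.region_class!r} for {self.name!r}; "
                f"expected one of {REGION_CLASSES}"
            )
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"unknown hemisphere {self.hemisphere!r} for {self.name!r}; "
                f"expected one of {HEMISPHERES}"
            )


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered collection of named brain regions.

    The order of ``regions`` defines matrix row/column order for every
    covariance network built from this atlas.
    """

    regions: tuple[Region, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate region names in atlas: {sorted(dupes)}")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"region {name!r} not in atlas") from None

    def of_class(self, region_class: str) -> list[str]:
        if region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {region_class!r}")
        return [r.name for r in self.regions if r.region_class == region_class]

    @property
    def subnuclei(self) -> list[str]:
        return self.of_class("amygdala_subnucleus")

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in REGION_CLASSES}
        for r in self.regions:
            counts[r.region_class] += 1
        return counts

    def to_records(self) -> list[dict]:
        return [
            {"name": r.name, "class": r.region_class, "hemisphere": r.hemisphere}
            for r in self.regions
        ]


def _atlas_from_records(records: Iterable[dict]) -> RegionAtlas:
    regions = []
    for rec in records:
        try:
            regions.append(
                Region(
                    name=str(rec["name"]),
                    region_class=str(rec["class"]),
                    hemisphere=str(rec["hemisphere"]),
                )
            )
        except KeyError as exc:
            raise ValueError(f"atlas record {rec!r} missing field {exc}") from None
    return RegionAtlas(regions=tuple(regions))


def load_region_atlas(path: str | Path) -> RegionAtlas:
    """Load a region atlas from a YAML or JSON file.

    The file holds a list of ``{name, class, hemisphere}`` records, either
    at top level or under a ``regions`` key. Duplicate names and unknown
    classes are hard errors.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        payload = json.loads(text)
    else:
        payload = yaml.safe_load(text)
    if isinstance(payload, dict):
        payload = payload.get("regions", payload)
    if not isinstance(payload, list):
        raise ValueError(f"atlas file {path} does not contain a region list")
    return _atlas_from_records(payload)


def write_region_atlas(atlas: RegionAtlas, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump({"regions": atlas.to_records()}, fh, sort_keys=False)


def default_atlas() -> RegionAtlas:
    """The packaged 105-region atlas: 63 cortical, 24 subcortical, 18 subnuclei."""
    ref = resources.files("scovnet.data").joinpath(DEFAULT_ATLAS_RESOURCE)
    payload = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _atlas_from_records(payload["regions"])


def make_atlas(records: Sequence[dict]) -> RegionAtlas:
    """Build an atlas directly from records (used for small test atlases)."""
    return _atlas_from_records(records)
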