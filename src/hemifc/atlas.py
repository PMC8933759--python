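"""Lateralized ROI catalogue.

An atlas is an ordered list of ROIs, each carrying a hemisphere label
(``L``, ``R`` or ``M`` for midline) and, for lateral ROIs, an optional
homotopic partner (the mirror-image ROI in the opposite hemisphere).
All hemispheric statistics downstream operate on the lateral subset.

The bundled default atlas is a 105-ROI reconstruction of a standard
cortical + subcortical parcellation: 50 left, 50 right and 5 midline
regions, with homotopic pairing a perfect matching on the lateral ROIs.
Any user table with the same schema is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import (
    AtlasValidationError,
    DuplicateRoiIdError,
    PartnerMappingError,
    UnknownHemisphereError,
)

VALID_HEMISPHERES = frozenset({"L", "R", "M"})

#: Strings interpreted as "no partner" in atlas tables.
_NO_PARTNER = {"", ".", "na", "NA", "none", "None"}


@dataclass(frozen=True)
class Roi:
    """One atlas parcel."""

    roi_id: str
    name: str
    hemisphere: str
    homotopic_partner: Optional[str] = None


@dataclass(frozen=True)
class RoiAtlas:
    """Validated, ordered collection of :class:`Roi`.

    Construction runs full validation; an invalid ROI list raises one of
    the :class:`~hemifc.errors.AtlasValidationError` subclasses naming the
    offending row.
    """

    rois: tuple[Roi, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        index: dict[str, int] = {}
        for row, roi in enumerate(self.rois):
            if roi.roi_id in index:
                raise DuplicateRoiIdError(
                    f"duplicate roi_id {roi.roi_id!r} at row {row}"
                )
            if roi.hemisphere not in VALID_HEMISPHERES:
                raise UnknownHemisphereError(
                    f"unknown hemisphere {roi.hemisphere!r} for ROI "
                    f"{roi.roi_id!r} at row {row}; expected one of L, R, M"
                )
            index[roi.roi_id] = row
        for row, roi in enumerate(self.rois):
            partner = roi.homotopic_partner
            if partner is None:
                continue
            if roi.hemisphere == "M":
                raise PartnerMappingError(
                    f"midline ROI {roi.roi_id!r} at row {row} declares a "
                    f"homotopic partner {partner!r}; midline ROIs have none"
                )
            if partner not in index:
                raise PartnerMappingError(
                    f"ROI {roi.roi_id!r} at row {row} declares partner "
                    f"{partner!r} which is not in the atlas"
                )
            other = self.rois[index[partner]]
            if other.hemisphere == roi.hemisphere:
                raise PartnerMappingError(
                    f"ROI {roi.roi_id!r} at row {row} and its partner "
                    f"{partner!r} are both in hemisphere {roi.hemisphere!r}"
                )
            if other.homotopic_partner != roi.roi_id:
                raise PartnerMappingError(
                    f"asymmetric pairing: {roi.roi_id!r} at row {row} declares "
                    f"partner {partner!r}, but {partner!r} declares "
                    f"{other.homotopic_partner!r}"
                )
        object.__setattr__(self, "_index", index)

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def __contains__(self, roi_id: str) -> bool:
        return roi_id in self._index

    def __getitem__(self, roi_id: str) -> Roi:
        return self.rois[self._index[roi_id]]

    # -- views --------------------------------------------------------------

    @property
    def roi_ids(self) -> list[str]:
        return [r.roi_id for r in self.rois]

    def hemisphere_of(self, roi_id: str) -> str:
        return self[roi_id].hemisphere

    def ids_in_hemisphere(self, hemisphere: str) -> list[str]:
        return [r.roi_id for r in self.rois if r.hemisphere == hemisphere]

    @property
    def n_lateral(self) -> int:
        return sum(1 for r in self.rois if r.hemisphere != "M")

    def lateral_subset(self) -> "RoiAtlas":
        """Atlas restricted to hemispheres L and R, order preserved.

        Idempotent; an atlas of only midline ROIs yields an empty atlas,
        which downstream operations reject.
        """
        return RoiAtlas(tuple(r for r in self.rois if r.hemisphere != "M"))

    def subset(self, roi_ids: Iterable[str]) -> "RoiAtlas":
        """Restrict to ``roi_ids`` (atlas order preserved), dropping partner
        links that would dangle."""
        keep = set(roi_ids)
        missing = keep - set(self._index)
        if missing:
            raise AtlasValidationError(f"unknown roi_ids in subset: {sorted(missing)}")
        rois = []
        for r in self.rois:
            if r.roi_id not in keep:
                continue
            partner = r.homotopic_partner if r.homotopic_partner in keep else None
            rois.append(Roi(r.roi_id, r.name, r.hemisphere, partner))
        return RoiAtlas(tuple(rois))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": [r.roi_id for r in self.rois],
                "name": [r.name for r in self.rois],
                "hemisphere": [r.hemisphere for r in self.rois],
                "homotopic_partner": [
                    r.homotopic_partner if r.homotopic_partner is not None else "."
                    for r in self.rois
                ],
            }
        )


def load_atlas(path: str | Path) -> RoiAtlas:
    """Read and validate an atlas from a tab-separated table.

    The table must have a header row with columns ``roi_id``, ``name``,
    ``hemisphere`` and ``homotopic_partner`` (``.`` or empty = no partner).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"roi_id", "name", "hemisphere", "homotopic_partner"}
    missing = required - set(df.columns)
    if missing:
        raise AtlasValidationError(
            f"atlas file {path} is missing columns: {sorted(missing)}"
        )
    rois = []
    for rec in df.itertuples(index=False):
        partner = rec.homotopic_partner.strip()
        rois.append(
            Roi(
                roi_id=rec.roi_id.strip(),
                name=rec.name,
                hemisphere=rec.hemisphere.strip(),
                homotopic_partner=None if partner in _NO_PARTNER else partner,
            )
        )
    return RoiAtlas(tuple(rois))


def save_atlas(atlas: RoiAtlas, path: str | Path) -> None:
    atlas.to_frame().to_csv(path, sep="\t", index=False)


def default_atlas() -> RoiAtlas:
    """The bundled 105-ROI atlas (50 L + 50 R + 5 midline)."""
    ref = resources.files("hemifc").joinpath("data/default_atlas.tsv")
    with resources.as_file(ref) as path:
        return load_atlas(path)
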