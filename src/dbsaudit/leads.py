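"""Lead geometry: lead specifications and contact-centre computation.

A DBS lead is modelled as a straight line segment: a tip point, a unit
direction pointing from the tip towards the skull entry, and a manufacturer
geometry (number of contacts, contact length, centre-to-centre pitch, and the
distance from the tip to the centre of the most distal contact).  Directional
leads are collapsed to their ring centres — all accuracy metrics in this
package are purely positional, so segment azimuths carry no information here.

Manufacturer constants ship in ``data/lead_library.json`` as approximate
published geometries; they are deliberately an editable data file rather than
code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

#: Tolerance on the direction vector's norm.
DIRECTION_NORM_TOL = 1e-9

_LEAD_FIELDS = {
    "n_contacts": int,
    "contact_length": float,
    "contact_pitch": float,
    "tip_to_first_contact_centre": float,
    "directional": bool,
}


@dataclass(frozen=True)
class LeadSpec:
    """Geometric description of a lead model.

    All lengths in mm; ``contact_pitch`` is centre-to-centre spacing of
    consecutive contacts, ``tip_to_first_contact_centre`` the distance from
    the physical tip to the centre of the most distal contact.
    """

    model_name: str
    n_contacts: int
    contact_length: float
    contact_pitch: float
    tip_to_first_contact_centre: float
    directional: bool = False

    def __post_init__(self) -> None:
        if self.n_contacts < 1:
            raise ValueError("n_contacts must be >= 1")
        if not self.contact_length > 0:
            raise ValueError("contact_length must be > 0")
        if self.contact_pitch < self.contact_length:
            raise ValueError("contact_pitch must be >= contact_length")
        if self.tip_to_first_contact_centre < 0:
            raise ValueError("tip offset must be >= 0")


@dataclass
class ElectrodeModel:
    """An implanted electrode: tip position, direction and lead geometry.

    ``direction`` is the unit vector from the tip towards the entry point, so
    contact k (0-based, distal to proximal) sits at
    ``tip + direction * (tip_to_first_contact_centre + k * pitch)``.

    The left hemisphere is always implantation order 1 and the right order 2
    (the study cohort was implanted left side first in every case).
    """

    tip: np.ndarray
    direction: np.ndarray
    spec: LeadSpec
    hemisphere: str = "left"
    implantation_order: int | None = None

    def __post_init__(self) -> None:
        self.tip = np.asarray(self.tip, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > DIRECTION_NORM_TOL:
            raise ValueError(
                f"direction must be a unit vector (norm {norm!r} deviates by "
                f"more than {DIRECTION_NORM_TOL})"
            )
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        if self.implantation_order is None:
            self.implantation_order = 1 if self.hemisphere == "left" else 2
        expected = 1 if self.hemisphere == "left" else 2
        if self.implantation_order != expected:
            raise ValueError(
                "left hemisphere is implanted first: hemisphere "
                f"{self.hemisphere!r} requires implantation_order {expected}"
            )


def contact_centers(electrode: ElectrodeModel) -> np.ndarray:
    """World coordinates of every contact centre, distal to proximal.

    Returns an ``(n_contacts, 3)`` array in world mm.
    """
    spec = electrode.spec
    offsets = spec.tip_to_first_contact_centre + spec.contact_pitch * np.arange(
        spec.n_contacts
    )
    return electrode.tip[None, :] + offsets[:, None] * electrode.direction[None, :]


def _parse_spec(name: str, raw: dict) -> LeadSpec:
    kwargs = {"model_name": name}
    for field_name, caster in _LEAD_FIELDS.items():
        if field_name not in raw:
            raise ValueError(f"lead {name!r}: missing field {field_name!r}")
        value = raw[field_name]
        if caster is bool:
            if not isinstance(value, bool):
                raise ValueError(f"lead {name!r}: field {field_name!r} must be boolean")
            kwargs[field_name] = value
        else:
            try:
                kwargs[field_name] = caster(value)
            except (TypeError, ValueError):
                raise ValueError(
                    f"lead {name!r}: field {field_name!r} is not numeric: {value!r}"
                ) from None
    # unknown fields (provenance notes etc.) are ignored
    return LeadSpec(**kwargs)


def load_lead_library(path: str | Path | None = None) -> dict[str, LeadSpec]:
    """Load a lead library (model name -> :class:`LeadSpec`) from JSON.

    With no path, the library shipped with the package is used.  Duplicate
    model names and malformed numeric fields raise ``ValueError``.
    """
    if path is None:
        text = (
            resources.files("dbsaudit").joinpath("data/lead_library.json").read_text()
        )
    else:
        text = Path(path).read_text()
    if not text.strip():
        return {}
    raw = json.loads(text, object_pairs_hook=_reject_duplicates)
    meta_keys = {k for k in raw if k.startswith("_")}
    return {
        name: _parse_spec(name, entry)
        for name, entry in raw.items()
        if name not in meta_keys
    }


def _reject_duplicates(pairs):
    seen = {}
    for key, value in pairs:
        if key in seen:
            raise ValueError(f"duplicate model name {key!r} in lead library")
        seen[key] = value
    return seen


def save_lead_library(library: dict[str, LeadSpec], path: str | Path) -> None:
    """Write a lead library back to JSON (inverse of :func:`load_lead_library`)."""
    out = {
        name: {
            "n_contacts": spec.n_contacts,
            "contact_length": spec.contact_length,
            "contact_pitch": spec.contact_pitch,
            "tip_to_first_contact_centre": spec.tip_to_first_contact_centre,
            "directional": spec.directional,
        }
        for name, spec in library.items()
    }
    Path(path).write_text(json.dumps(out, indent=2) + "\n")
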