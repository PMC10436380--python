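"""Color palettes.

The shipped default palette covers the dermoscopy color list: the named
absolute colors (White .. Black, each with RGB and hex encodings) plus the
skin-relative symbolic colors (Non-pigmented, Hypopigmented, Pigmented,
Dark) and the collection-level qualifiers (Uniform, Variable), which carry
no RGB data.  Palette files are CSV with columns ``name,r,g,b,hex``; rows
with empty RGB cells define symbolic colors.

``COLOR_SUBSUMPTION`` records which absolute colors each symbolic category
covers; the query engine's ``subsumes`` match mode walks it.  Hypo-/
pigmented are relative to the individual's skin color, so the mapping is a
pragmatic toolkit reading, not a colorimetric fact.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from .errors import ValidationError
from .model import Color, make_color

#: Collection-level qualifiers listed in the color inventory.
QUALIFIER_COLORS = frozenset({"Uniform", "Variable"})

#: symbolic category -> absolute palette colors it subsumes
COLOR_SUBSUMPTION: dict[str, frozenset[str]] = {
    "Dark": frozenset({"Black", "Brown", "Gray Brown", "Light Brown", "Blue Gray", "Indigo"}),
    "Pigmented": frozenset({"Black", "Brown", "Gray Brown", "Light Brown", "Blue Gray", "Blue White", "Dark"}),
    "Hypopigmented": frozenset({"White", "Bright White", "Non-pigmented"}),
    "Non-pigmented": frozenset({"White", "Bright White"}),
    "White": frozenset({"Bright White"}),
}


def load_palette(path: Optional[Union[str, Path]] = None) -> dict[str, Color]:
    """Load a palette CSV into a name -> :class:`Color` mapping.

    With no ``path`` the shipped default palette is returned.  Names must
    be unique within a palette.
    """
    if path is None:
        text = resources.files("vizonto").joinpath("data/palette.csv").read_text()
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    palette: dict[str, Color] = {}
    for i, row in enumerate(rows, start=2):
        name = (row.get("name") or "").strip()
        if not name:
            raise ValidationError(f"palette line {i}: missing color name")
        if name in palette:
            raise ValidationError(f"palette line {i}: duplicate color name {name!r}")
        r, g, b, hx = (row.get(k, "").strip() for k in ("r", "g", "b", "hex"))
        if not (r or g or b or hx):
            palette[name] = make_color(name, symbolic=True, qualifier=name in QUALIFIER_COLORS)
        else:
            palette[name] = make_color(name, (int(r), int(g), int(b)), hx)
    return palette


def default_palette() -> dict[str, Color]:
    """The shipped dermoscopy palette (cached per call site; cheap to load)."""
    return load_palette(None)
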