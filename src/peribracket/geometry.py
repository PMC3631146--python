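"""Parametric synthetic geometry of a bracket-bearing labial tooth surface.

The computational domain is a thin rectangular saliva film resting on the
labial (vestibular) surface of a lower central incisor.  The tooth surface is
the plane z = 0; the x axis runs mesio-distally, the y axis occluso-gingivally
(occlusal = +y, gingival = -y, left/right from the viewer's labial
perspective).  An orthodontic bracket is modelled as a rectangular prism
protruding from the tooth surface, optionally carrying a round archwire that
runs mesio-distally through the bracket slot.  Solids are represented on a
uniform Cartesian grid by a boolean cell mask (immersed-obstacle
representation); the band extending 2 mm around the bracket base is split
into the four peri-bracket regions BO (occlusal), BG (gingival), BL and BR
(lateral).

All lengths are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

# Region label codes used in ``GeometryModel.region_labels``.
NONE_LABEL = 0
BO = 1  # occlusal side of the band (+y of the bracket)
BG = 2  # gingival side (-y)
BL = 3  # viewer's left lateral side (-x)
BR = 4  # viewer's right lateral side (+x)

REGION_NAMES = {BO: "BO", BG: "BG", BL: "BL", BR: "BR"}
REGION_CODES = {v: k for k, v in REGION_NAMES.items()}

#: inches -> mm for the archwire cross-section
_INCH_MM = 25.4


@dataclass(frozen=True)
class DomainSpec:
    """Extents and resolution of the saliva-filled vestibular domain.

    Defaults give a 10 x 10 x 1.4 mm slab whose volume is 140 mm^3 =
    0.14 ml, the saliva volume of the modelled swallow.
    """

    length_md: float = 10.0  #: mesio-distal extent (x), mm
    length_og: float = 10.0  #: occluso-gingival extent (y), mm
    depth: float = 1.4  #: labio-lingual film thickness (z), mm
    cell_size: float = 0.2  #: uniform cell edge, mm

    def __post_init__(self):
        for name in ("length_md", "length_og", "depth", "cell_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"DomainSpec.{name} must be > 0")
        if min(self.shape) < 4:
            raise ConfigurationError(
                f"grid must be at least 4 cells per axis, got {self.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        """Grid dimensions (nx, ny, nz), extents rounded to whole cells."""
        return (
            int(round(self.length_md / self.cell_size)),
            int(round(self.length_og / self.cell_size)),
            int(round(self.depth / self.cell_size)),
        )

    @property
    def volume(self) -> float:
        """Nominal domain volume in mm^3."""
        return self.length_md * self.length_og * self.depth

    def cell_centers(self, axis: int) -> np.ndarray:
        """Cell-center coordinates along ``axis`` (0=x, 1=y, 2=z), mm."""
        n = self.shape[axis]
        return (np.arange(n) + 0.5) * self.cell_size


@dataclass(frozen=True)
class ApplianceSpec:
    """Bracket prism and optional archwire, placed on the tooth plane.

    The bracket is ``bracket_width`` (mesio-distal) by ``bracket_height``
    (occluso-gingival) at its base and protrudes ``bracket_thickness``
    labially.  The archwire is a cylinder of diameter ``wire_diameter``
    (default 0.014 inch = 0.3556 mm) whose axis runs mesio-distally through
    the bracket slot at height ``wire_height`` above the tooth surface.
    """

    bracket_width: float = 2.4
    bracket_height: float = 3.0
    bracket_thickness: float = 1.0
    wire_diameter: float = 0.014 * _INCH_MM
    wire_present: bool = False
    bracket_center: tuple[float, float] = (5.0, 5.0)
    wire_height: float = 1.2

    def __post_init__(self):
        for name in ("bracket_width", "bracket_height", "bracket_thickness"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"ApplianceSpec.{name} must be > 0")
        if self.wire_present and self.wire_diameter <= 0:
            raise ConfigurationError(
                "ApplianceSpec.wire_diameter must be > 0 when wire_present"
            )

    @property
    def footprint(self) -> tuple[float, float, float, float]:
        """Bracket base rectangle (x0, x1, y0, y1) on the tooth plane, mm."""
        cx, cy = self.bracket_center
        return (
            cx - self.bracket_width / 2,
            cx + self.bracket_width / 2,
            cy - self.bracket_height / 2,
            cy + self.bracket_height / 2,
        )


@dataclass(frozen=True)
class GeometryModel:
    """Discretised domain: specs, solid cell mask and region label map."""

    domain: DomainSpec
    appliance: ApplianceSpec
    solid_mask: np.ndarray = field(repr=False)  # bool, (nx, ny, nz)
    region_labels: np.ndarray = field(repr=False)  # int8, (nx, ny)
    band_width: float = 0.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.domain.shape

    @property
    def cell_size(self) -> float:
        return self.domain.cell_size

    @property
    def cell_area(self) -> float:
        """Tooth-surface area of one cell, mm^2."""
        return self.domain.cell_size**2

    def region_mask(self, code: int) -> np.ndarray:
        """Boolean (nx, ny) mask of one peri-bracket region."""
        return self.region_labels == code

    def region_area(self, code: int) -> float:
        """Area of one region in mm^2 (cell count x cell area)."""
        return float(self.region_mask(code).sum()) * self.cell_area

    def solid_volume(self) -> float:
        """Volume of the solid mask, mm^3."""
        return float(self.solid_mask.sum()) * self.cell_size**3

    @property
    def surface_solid(self) -> np.ndarray:
        """(nx, ny) mask of tooth-surface cells covered by solid."""
        return self.solid_mask[:, :, 0]


def _solid_mask(domain: DomainSpec, appliance: ApplianceSpec) -> np.ndarray:
    """Mark every cell whose center lies in the bracket prism or wire."""
    nx, ny, nz = domain.shape
    x = domain.cell_centers(0)[:, None, None]
    y = domain.cell_centers(1)[None, :, None]
    z = domain.cell_centers(2)[None, None, :]
    x0, x1, y0, y1 = appliance.footprint

    mask = (
        (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
        & (z <= appliance.bracket_thickness)
    )
    mask = np.broadcast_to(mask, (nx, ny, nz)).copy()

    if appliance.wire_present:
        cy = appliance.bracket_center[1]
        r = appliance.wire_diameter / 2
        in_wire = (y - cy) ** 2 + (z - appliance.wire_height) ** 2 <= r**2
        mask |= np.broadcast_to(in_wire, (nx, ny, nz))
    return mask


def build_domain(
    domain: DomainSpec | None = None,
    appliance: ApplianceSpec | None = None,
    band_width: float = 2.0,
) -> GeometryModel:
    """Build the discretised geometry and its peri-bracket partition.

    Parameters
    ----------
    domain, appliance
        Specifications; package defaults are used when omitted.
    band_width
        Width of the peri-bracket metric band, mm (2 mm clinically).

    Raises
    ------
    ConfigurationError
        If the bracket (plus metric band) does not fit inside the domain
        with the required margin, naming the violated side.
    """
    domain = domain or DomainSpec()
    appliance = appliance or ApplianceSpec()

    x0, x1, y0, y1 = appliance.footprint
    margins = {
        "mesial (x=0)": x0,
        "distal (x=L)": domain.length_md - x1,
        "gingival (y=0)": y0,
        "occlusal (y=L)": domain.length_og - y1,
    }
    for side, m in margins.items():
        if m < band_width:
            raise ConfigurationError(
                f"bracket footprint leaves a {m:.3g} mm margin on the "
                f"{side} boundary; >= {band_width:.3g} mm needed for the "
                "peri-bracket band"
            )
    if appliance.wire_present:
        r = appliance.wire_diameter / 2
        if appliance.wire_height + r > domain.depth:
            raise ConfigurationError(
                "archwire protrudes beyond the labial boundary "
                f"(wire top {appliance.wire_height + r:.3g} mm > depth "
                f"{domain.depth:.3g} mm)"
            )

    solid = _solid_mask(domain, appliance)
    model = GeometryModel(
        domain=domain,
        appliance=appliance,
        solid_mask=solid,
        region_labels=np.zeros(domain.shape[:2], dtype=np.int8),
    )
    return partition_peri_bracket(model, band_width)


def partition_peri_bracket(
    model: GeometryModel, band_width: float = 2.0
) -> GeometryModel:
    """Label the 2-mm band around the bracket base with BO/BG/BL/BR.

    A tooth-surface cell belongs to the band when its center lies outside
    the bracket footprint but within ``band_width`` of it along each axis
    (square-cornered offset rectangle).  Each band cell is assigned to the
    side of its nearest bracket edge; corner cells equidistant from a
    horizontal and a vertical edge go to the lateral (BL/BR) region.
    """
    domain, appliance = model.domain, model.appliance
    x0, x1, y0, y1 = appliance.footprint
    if (
        x0 - band_width < 0
        or x1 + band_width > domain.length_md
        or y0 - band_width < 0
        or y1 + band_width > domain.length_og
    ):
        raise ConfigurationError("peri-bracket band exceeds the domain")

    x = domain.cell_centers(0)[:, None]
    y = domain.cell_centers(1)[None, :]
    # signed axis gaps to the footprint (0 inside its x/y span)
    dx = np.maximum(np.maximum(x0 - x, x - x1), 0.0)
    dy = np.maximum(np.maximum(y0 - y, y - y1), 0.0)
    outside = (dx > 0) | (dy > 0)
    in_band = outside & (dx <= band_width) & (dy <= band_width)

    labels = np.zeros(domain.shape[:2], dtype=np.int8)
    # nearest-edge rule: a corner cell at gaps (dx, dy) is dx from the
    # lateral edge line and dy from the horizontal one; smaller wins,
    # ties go lateral
    lateral = in_band & (dx > 0) & ((dy == 0) | (dx <= dy))
    horizontal = in_band & ~lateral
    cx, cy = appliance.bracket_center
    labels[lateral & (x < cx)] = BL
    labels[lateral & (x >= cx)] = BR
    labels[horizontal & (y >= cy)] = BO
    labels[horizontal & (y < cy)] = BG
    return replace(model, region_labels=labels, band_width=band_width)


def toggle_archwire(model: GeometryModel, present: bool) -> GeometryModel:
    """Return the model with the archwire added to or removed from the mask.

    All other fields (domain, bracket, region labels) are unchanged; the
    solid mask is rebuilt so toggling twice restores the original mask.
    """
    if present == model.appliance.wire_present:
        return model
    appliance = replace(model.appliance, wire_present=present)
    if present:
        r = appliance.wire_diameter / 2
        if appliance.wire_height + r > model.domain.depth:
            raise ConfigurationError(
                "archwire protrudes beyond the labial boundary"
            )
    return replace(
        model,
        appliance=appliance,
        solid_mask=_solid_mask(model.domain, appliance),
    )


def mirror_md(model: GeometryModel) -> GeometryModel:
    """Mirror the geometry left-right (about the mid mesio-distal plane)."""
    cx, cy = model.appliance.bracket_center
    appliance = replace(
        model.appliance, bracket_center=(model.domain.length_md - cx, cy)
    )
    return build_domain(model.domain, appliance, band_width=model.band_width)
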