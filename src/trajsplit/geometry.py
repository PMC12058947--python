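"""Display geometry for two-choice cursor-tracking experiments.

The task space consists of three named axis-aligned rectangles: a start
area at the bottom centre of the display and two mirror-symmetric target
areas in the upper left and upper right. All analyses run in a *canonical*
frame with the origin at the start-area centre and y increasing upward;
raw logs may instead use screen coordinates (origin top-left, y down),
which the geometry's ``frame`` tag disambiguates.

Region membership is boundary-inclusive throughout: a cursor sample lying
exactly on a region edge counts as inside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "Rect",
    "DisplayGeometry",
    "GeometryError",
    "load_geometry",
    "save_geometry",
]

_FRAMES = ("canonical", "screen")
_REGIONS = ("start", "target_left", "target_right")


class GeometryError(ValueError):
    """A geometry config violates a structural invariant."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle given by centre and size (pixels)."""

    x_center: float
    y_center: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width < 0 or self.height < 0:
            raise GeometryError("rectangle width/height must be non-negative")

    @property
    def left(self) -> float:
        return self.x_center - self.width / 2.0

    @property
    def right(self) -> float:
        return self.x_center + self.width / 2.0

    @property
    def bottom(self) -> float:
        # Smaller coordinate edge; reads as "bottom" in a y-up frame.
        return self.y_center - self.height / 2.0

    @property
    def top(self) -> float:
        return self.y_center + self.height / 2.0

    def contains(self, x, y):
        """Boundary-inclusive membership test; accepts scalars or arrays."""
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= self.left) & (x <= self.right) & (y >= self.bottom) & (y <= self.top)

    def translated(self, dx: float, dy: float) -> "Rect":
        return Rect(self.x_center + dx, self.y_center + dy, self.width, self.height)

    def mirrored_x(self) -> "Rect":
        """Reflection about the vertical line x = 0."""
        return Rect(-self.x_center, self.y_center, self.width, self.height)

    def overlaps(self, other: "Rect") -> bool:
        return (
            self.left < other.right
            and other.left < self.right
            and self.bottom < other.top
            and other.bottom < self.top
        )


@dataclass(frozen=True)
class DisplayGeometry:
    """Start and target regions plus the coordinate-frame tag.

    Parameters
    ----------
    start, target_left, target_right
        The three task regions in the frame given by ``frame``.
    frame
        ``"canonical"`` (y up) or ``"screen"`` (y down, origin top-left).
    symmetry_tol
        Absolute tolerance (px) for the mirror-symmetry check of the two
        targets about the vertical line through the start centre. The
        default of 0 demands exact symmetry.
    """

    start: Rect
    target_left: Rect
    target_right: Rect
    frame: str = "canonical"
    symmetry_tol: float = 0.0

    def __post_init__(self) -> None:
        if self.frame not in _FRAMES:
            raise GeometryError(f"unknown frame {self.frame!r}; expected one of {_FRAMES}")

    # -- frame handling -------------------------------------------------

    def canonical(self) -> "DisplayGeometry":
        """Return the geometry in the canonical frame.

        The canonical frame has its origin at the start-area centre and y
        increasing upward. A screen-frame geometry is converted with
        ``x' = x - x_start``, ``y' = y_start - y``; a canonical-frame one
        is merely translated so the start centre sits at the origin.
        """
        sx, sy = self.start.x_center, self.start.y_center

        def conv(r: Rect) -> Rect:
            if self.frame == "screen":
                return Rect(r.x_center - sx, sy - r.y_center, r.width, r.height)
            return r.translated(-sx, -sy)

        return DisplayGeometry(
            start=conv(self.start),
            target_left=conv(self.target_left),
            target_right=conv(self.target_right),
            frame="canonical",
            symmetry_tol=self.symmetry_tol,
        )

    def flipped(self) -> "DisplayGeometry":
        """Mirror a canonical geometry about x = 0, swapping the targets."""
        if self.frame != "canonical":
            raise GeometryError("flipped() requires a canonical-frame geometry")
        return DisplayGeometry(
            start=self.start.mirrored_x(),
            target_left=self.target_right.mirrored_x(),
            target_right=self.target_left.mirrored_x(),
            frame="canonical",
            symmetry_tol=self.symmetry_tol,
        )

    def oriented(self, flipped: bool) -> "DisplayGeometry":
        """Canonical geometry matching a trial's flip state.

        After flipping, the correct target always occupies the
        ``target_right`` slot.
        """
        g = self.canonical()
        return g.flipped() if flipped else g

    # -- validation -----------------------------------------------------

    def validate(self) -> "DisplayGeometry":
        """Check all structural invariants; raise :class:`GeometryError`."""
        g = self.canonical()
        tl, tr, st = g.target_left, g.target_right, g.start
        if not (tl.x_center < st.x_center < tr.x_center):
            raise GeometryError("targets not on opposite sides of the start area")
        if not (tl.bottom > st.top and tr.bottom > st.top):
            raise GeometryError("targets do not lie strictly above the start area")
        tol = self.symmetry_tol
        asym = max(
            abs(tl.x_center + tr.x_center),
            abs(tl.y_center - tr.y_center),
            abs(tl.width - tr.width),
            abs(tl.height - tr.height),
        )
        if asym > tol:
            raise GeometryError(
                f"targets not mirror-symmetric about the start centre "
                f"(asymmetry {asym:g} px exceeds tolerance {tol:g} px)"
            )
        for name, region in (("target_left", tl), ("target_right", tr)):
            if st.overlaps(region):
                raise GeometryError(f"start and {name} regions overlap")
        return self

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {name: asdict(getattr(self, name)) for name in _REGIONS}
        d["frame"] = self.frame
        if self.symmetry_tol:
            d["symmetry_tol"] = self.symmetry_tol
        return d


def _rect_from_dict(name: str, d: Any) -> Rect:
    if not isinstance(d, dict):
        raise GeometryError(f"region {name!r} must be a mapping")
    missing = {"x_center", "y_center", "width", "height"} - set(d)
    if missing:
        raise GeometryError(f"region {name!r} missing fields: {sorted(missing)}")
    return Rect(float(d["x_center"]), float(d["y_center"]), float(d["width"]), float(d["height"]))


def load_geometry(path: str | Path) -> DisplayGeometry:
    """Load and validate a display-geometry config (YAML or JSON).

    The schema is ``{start, target_left, target_right}`` with each region
    given as ``{x_center, y_center, width, height}``, plus an optional
    ``frame`` tag (``screen`` or ``canonical``, default canonical) and an
    optional ``symmetry_tol`` in px.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"geometry config not found: {path}")
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise GeometryError("geometry config must be a mapping")
    for name in _REGIONS:
        if name not in data:
            raise GeometryError(f"missing region: {name}")
    geom = DisplayGeometry(
        start=_rect_from_dict("start", data["start"]),
        target_left=_rect_from_dict("target_left", data["target_left"]),
        target_right=_rect_from_dict("target_right", data["target_right"]),
        frame=data.get("frame", "canonical"),
        symmetry_tol=float(data.get("symmetry_tol", 0.0)),
    )
    return geom.validate()


def save_geometry(geometry: DisplayGeometry, path: str | Path) -> None:
    """Write a geometry config as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    d = geometry.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
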