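"""Axis-aligned box data model and annotation I/O.

Internal coordinate convention
------------------------------
Boxes live in a 0-based continuous pixel coordinate system: the image spans
``[0, W] x [0, H]`` and a box is stored in center form ``(cx, cy, w, h)``
with a ``frame`` tag saying whether values are pixels or fractions of the
image size.  Corner form is half-open: ``xmin < xmax``, ``ymin < ymax`` and
``area = (xmax - xmin) * (ymax - ymin)``.

Pascal VOC XML files (as written by common labeling tools) carry 1-based
integer corners; on read they are shifted by -0.5 into the internal frame so
that a VOC box ``(xmin, ymin, xmax, ymax)`` has width ``xmax - xmin`` and
center ``((xmin + xmax)/2 - 0.5, (ymin + ymax)/2 - 0.5)``.  Writing inverts
the shift, so read/write round-trips exactly.

YOLO-style text annotations (one ``class cx cy w h`` line per object, all
values normalized to [0, 1]) are supported as a second dialect, auto-detected
by file extension (``.xml`` vs ``.txt``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, NamedTuple, Sequence
from xml.etree import ElementTree as ET

import numpy as np

logger = logging.getLogger(__name__)

Frame = Literal["pixel", "normalized"]

#: shift between VOC 1-based inclusive integer corners and internal
#: 0-based continuous corners
_VOC_SHIFT = 0.5

DEFAULT_CLASSES = ("fish",)


class ValidationError(ValueError):
    """Raised when a box, annotation or file violates an invariant."""


class Corners(NamedTuple):
    """Half-open corner representation ``[xmin, xmax) x [ymin, ymax)``."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in center form.

    Parameters
    ----------
    cx, cy:
        Center coordinates (pixels, or fractions when ``frame='normalized'``).
    w, h:
        Width and height, strictly positive.
    frame:
        ``'pixel'`` or ``'normalized'``.
    """

    cx: float
    cy: float
    w: float
    h: float
    frame: Frame = "pixel"

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValidationError(f"box must have positive size, got w={self.w}, h={self.h}")
        if self.frame == "normalized":
            for name in ("cx", "cy", "w", "h"):
                v = getattr(self, name)
                if not (0.0 <= v <= 1.0):
                    raise ValidationError(f"normalized box field {name}={v} outside [0, 1]")
        elif self.frame != "pixel":
            raise ValidationError(f"unknown frame {self.frame!r}")

    # -- representations ---------------------------------------------------

    @property
    def corners(self) -> Corners:
        return Corners(
            self.cx - self.w / 2, self.cy - self.h / 2,
            self.cx + self.w / 2, self.cy + self.h / 2,
        )

    @classmethod
    def from_corners(cls, xmin: float, ymin: float, xmax: float, ymax: float,
                     frame: Frame = "pixel") -> "Box":
        if not (xmin < xmax and ymin < ymax):
            raise ValidationError(
                f"degenerate corners ({xmin}, {ymin}, {xmax}, {ymax}): need xmin < xmax, ymin < ymax"
            )
        return cls((xmin + xmax) / 2, (ymin + ymax) / 2, xmax - xmin, ymax - ymin, frame)

    @property
    def area(self) -> float:
        return self.w * self.h

    def to_pixel(self, image_size: tuple[int, int]) -> "Box":
        """Express the box in pixels for an image of size ``(W, H)``."""
        _check_size(image_size)
        if self.frame == "pixel":
            return self
        W, H = image_size
        return Box(self.cx * W, self.cy * H, self.w * W, self.h * H, "pixel")

    def to_normalized(self, image_size: tuple[int, int]) -> "Box":
        _check_size(image_size)
        if self.frame == "normalized":
            return self
        W, H = image_size
        return Box(self.cx / W, self.cy / H, self.w / W, self.h / H, "normalized")

    def clipped(self, image_size: tuple[int, int]) -> "Box":
        """Intersect with the image rectangle; raises if nothing remains."""
        W, H = image_size
        box = self.to_pixel(image_size)
        xmin, ymin, xmax, ymax = box.corners
        xmin, xmax = max(0.0, xmin), min(float(W), xmax)
        ymin, ymax = max(0.0, ymin), min(float(H), ymax)
        if not (xmin < xmax and ymin < ymax):
            raise ValidationError(f"box {self} lies entirely outside image of size {image_size}")
        out = Box.from_corners(xmin, ymin, xmax, ymax, "pixel")
        return out if self.frame == "pixel" else out.to_normalized(image_size)


Representation = Literal["corner-pixel", "center-pixel", "center-normalized"]


def convert_box(box: Box, target: Representation,
                image_size: tuple[int, int]) -> Box | Corners:
    """Value-preserving change of box representation.

    ``center-pixel`` and ``center-normalized`` return a :class:`Box` with the
    corresponding frame; ``corner-pixel`` returns a :class:`Corners` tuple.
    Idempotent when the box already is in the target representation.
    """
    _check_size(image_size)
    if target == "center-pixel":
        return box.to_pixel(image_size)
    if target == "center-normalized":
        return box.to_normalized(image_size)
    if target == "corner-pixel":
        return box.to_pixel(image_size).corners
    raise ValidationError(f"unknown representation {target!r}")


def _check_size(image_size: tuple[int, int]) -> None:
    W, H = image_size
    if not (W > 0 and H > 0):
        raise ValidationError(f"image size must be positive, got {image_size}")


@dataclass(frozen=True)
class Annotation:
    """One labeled object: a box plus class name and difficulty flag."""

    box: Box
    class_name: str = "fish"
    difficult: bool = False

    def __post_init__(self) -> None:
        if not self.class_name:
            raise ValidationError("class_name must be nonempty")


@dataclass
class Detection:
    """A predicted box with confidence score and class index."""

    box: Box
    score: float
    class_index: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score {self.score} outside [0, 1]")
        if self.class_index < 0:
            raise ValidationError("class_index must be nonnegative")


@dataclass
class LabeledImage:
    """Pixel array plus its ground-truth annotations.

    ``pixels`` may be ``None`` for annotation-only records (e.g. a parsed
    XML file whose image has not been loaded); ``image_size`` is then taken
    from the annotation file.
    """

    pixels: np.ndarray | None
    annotations: list[Annotation] = field(default_factory=list)
    source_id: str = ""
    image_size: tuple[int, int] | None = None  # (W, H), used when pixels is None

    def __post_init__(self) -> None:
        if self.pixels is not None:
            if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
                raise ValidationError(f"pixels must be HxWx3, got shape {self.pixels.shape}")
            if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
                raise ValidationError("image must be at least 1x1")
            self.image_size = (self.pixels.shape[1], self.pixels.shape[0])
        elif self.image_size is None:
            raise ValidationError("either pixels or image_size is required")
        _check_size(self.image_size)

    @property
    def size(self) -> tuple[int, int]:
        """(W, H)."""
        assert self.image_size is not None
        return self.image_size


# ---------------------------------------------------------------------------
# Pascal VOC XML dialect
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    """Format a coordinate: integers as ints (labeling-tool style), else repr."""
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def read_voc_xml(path: str | Path, *, classes: Sequence[str] = DEFAULT_CLASSES,
                 allow_unknown: bool = False) -> LabeledImage:
    """Parse a Pascal VOC annotation file into a :class:`LabeledImage`.

    VOC 1-based corners are shifted into the internal 0-based convention;
    boxes poking past the image bounds are clipped with a warning; degenerate
    boxes (``xmax <= xmin`` or ``ymax <= ymin``) raise :class:`ValidationError`.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except (OSError, ET.ParseError) as exc:
        raise IOError(f"cannot read VOC XML {path}: {exc}") from exc
    root = tree.getroot()
    size_el = root.find("size")
    if size_el is None:
        raise ValidationError(f"{path}: missing <size> element")
    W = int(float(size_el.findtext("width", default="0")))
    H = int(float(size_el.findtext("height", default="0")))
    _check_size((W, H))

    annotations: list[Annotation] = []
    for i, obj in enumerate(root.iter("object")):
        name = (obj.findtext("name") or "").strip()
        if not name:
            raise ValidationError(f"{path}: object {i} has empty name")
        if name not in classes and not allow_unknown:
            raise ValidationError(
                f"{path}: object {i} has unknown class {name!r} (known: {list(classes)})"
            )
        bnd = obj.find("bndbox")
        if bnd is None:
            raise ValidationError(f"{path}: object {i} ({name}) lacks <bndbox>")
        vals = {}
        for key in ("xmin", "ymin", "xmax", "ymax"):
            text = bnd.findtext(key)
            if text is None:
                raise ValidationError(f"{path}: object {i} ({name}) lacks <{key}>")
            vals[key] = float(text)
        if vals["xmax"] <= vals["xmin"] or vals["ymax"] <= vals["ymin"]:
            raise ValidationError(
                f"{path}: object {i} ({name}) has degenerate box "
                f"({vals['xmin']}, {vals['ymin']}, {vals['xmax']}, {vals['ymax']})"
            )
        box = Box.from_corners(
            vals["xmin"] - _VOC_SHIFT, vals["ymin"] - _VOC_SHIFT,
            vals["xmax"] - _VOC_SHIFT, vals["ymax"] - _VOC_SHIFT,
        )
        xmin, ymin, xmax, ymax = box.corners
        if xmin < 0 or ymin < 0 or xmax > W or ymax > H:
            logger.warning("%s: object %d (%s) extends past image bounds; clipping", path, i, name)
            box = box.clipped((W, H))
        difficult = (obj.findtext("difficult") or "0").strip() in ("1", "true", "True")
        annotations.append(Annotation(box=box, class_name=name, difficult=difficult))

    return LabeledImage(pixels=None, annotations=annotations,
                        source_id=root.findtext("filename") or path.stem,
                        image_size=(W, H))


def write_voc_xml(labeled: LabeledImage, path: str | Path) -> None:
    """Write annotations as Pascal VOC XML readable by :func:`read_voc_xml`."""
    path = Path(path)
    W, H = labeled.size
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = path.parent.name or "."
    ET.SubElement(root, "filename").text = labeled.source_id or path.stem
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(W)
    ET.SubElement(size, "height").text = str(H)
    ET.SubElement(size, "depth").text = "3"
    for ann in labeled.annotations:
        box = ann.box.to_pixel((W, H))
        xmin, ymin, xmax, ymax = box.corners
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = ann.class_name
        ET.SubElement(obj, "difficult").text = "1" if ann.difficult else "0"
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = _fmt(xmin + _VOC_SHIFT)
        ET.SubElement(bnd, "ymin").text = _fmt(ymin + _VOC_SHIFT)
        ET.SubElement(bnd, "xmax").text = _fmt(xmax + _VOC_SHIFT)
        ET.SubElement(bnd, "ymax").text = _fmt(ymax + _VOC_SHIFT)
    ET.indent(root)
    try:
        ET.ElementTree(root).write(path, encoding="unicode")
    except OSError as exc:
        raise IOError(f"cannot write VOC XML {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# YOLO text dialect
# ---------------------------------------------------------------------------

def read_yolo_txt(path: str | Path, image_size: tuple[int, int], *,
                  classes: Sequence[str] = DEFAULT_CLASSES,
                  allow_unknown: bool = False) -> LabeledImage:
    """Parse ``class cx cy w h`` normalized lines into a :class:`LabeledImage`."""
    path = Path(path)
    _check_size(image_size)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise IOError(f"cannot read YOLO txt {path}: {exc}") from exc
    annotations = []
    for i, line in enumerate(lines):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValidationError(f"{path}:{i + 1}: expected 5 fields, got {len(parts)}")
        idx = int(parts[0])
        if idx >= len(classes) and not allow_unknown:
            raise ValidationError(f"{path}:{i + 1}: class index {idx} out of vocabulary")
        name = classes[idx] if idx < len(classes) else f"class{idx}"
        box = Box(*(float(v) for v in parts[1:]), frame="normalized")
        annotations.append(Annotation(box=box, class_name=name))
    return LabeledImage(pixels=None, annotations=annotations,
                        source_id=path.stem, image_size=image_size)


def write_yolo_txt(labeled: LabeledImage, path: str | Path, *,
                   classes: Sequence[str] = DEFAULT_CLASSES) -> None:
    path = Path(path)
    lines = []
    for ann in labeled.annotations:
        box = ann.box.to_normalized(labeled.size)
        idx = classes.index(ann.class_name) if ann.class_name in classes else 0
        lines.append(f"{idx} {box.cx:.9f} {box.cy:.9f} {box.w:.9f} {box.h:.9f}")
    try:
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    except OSError as exc:
        raise IOError(f"cannot write YOLO txt {path}: {exc}") from exc


def read_annotations(path: str | Path, image_size: tuple[int, int] | None = None,
                     **kwargs) -> LabeledImage:
    """Dispatch on extension: ``.xml`` -> VOC dialect, ``.txt`` -> YOLO dialect."""
    path = Path(path)
    if path.suffix.lower() == ".xml":
        return read_voc_xml(path, **kwargs)
    if path.suffix.lower() == ".txt":
        if image_size is None:
            raise ValidationError("YOLO txt annotations need an explicit image_size")
        return read_yolo_txt(path, image_size, **kwargs)
    raise ValidationError(f"unknown annotation format {path.suffix!r}")
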