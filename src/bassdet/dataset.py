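"""Loading datasets laid out as ``<split>/images/*.png`` + ``<split>/labels/*``.

Annotation files match image stems; VOC XML and YOLO txt dialects are both
accepted (auto-detected by extension).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .boxes import LabeledImage, ValidationError, read_annotations


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file to an HxWx3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def scan_split(root: str | Path, split: str) -> list[tuple[Path, Path]]:
    """Return (image, label) path pairs for one split, sorted by stem."""
    root = Path(root)
    img_dir = root / split / "images"
    lbl_dir = root / split / "labels"
    if not img_dir.is_dir():
        raise IOError(f"missing image directory {img_dir}")
    pairs = []
    for img_path in sorted(img_dir.iterdir()):
        if img_path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        for ext in (".xml", ".txt"):
            lbl_path = lbl_dir / (img_path.stem + ext)
            if lbl_path.exists():
                pairs.append((img_path, lbl_path))
                break
        else:
            raise ValidationError(f"no annotation file for {img_path}")
    return pairs


def load_pair(img_path: str | Path, lbl_path: str | Path, **kwargs) -> LabeledImage:
    """Load one image together with its annotations."""
    pixels = load_image(img_path)
    size = (pixels.shape[1], pixels.shape[0])
    parsed = read_annotations(lbl_path, image_size=size, **kwargs)
    if parsed.size != size:
        raise ValidationError(
            f"annotation size {parsed.size} does not match image size {size} for {img_path}"
        )
    return LabeledImage(pixels=pixels, annotations=parsed.annotations,
                        source_id=Path(img_path).stem)


def load_split(root: str | Path, split: str, **kwargs) -> list[LabeledImage]:
    return [load_pair(i, l, **kwargs) for i, l in scan_split(root, split)]
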