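"""Batched inference: image -> decoded detections -> suppression."""

from __future__ import annotations

import numpy as np

from .augment import resize_image
from .boxes import Detection, LabeledImage
from .model import Detector, decode_predictions
from .postprocess import SuppressionConfig, suppress

__all__ = ["prepare_batch", "detect_images", "draw_detections"]


def prepare_batch(images: list[np.ndarray], input_size: int) -> np.ndarray:
    """Resize HxWx3 uint8 images to the model square and scale to [0, 1]."""
    arrs = []
    for im in images:
        if im.shape[0] != input_size or im.shape[1] != input_size:
            im = resize_image(im, (input_size, input_size))
        arrs.append(im.astype(np.float64).transpose(2, 0, 1) / 255.0)
    return np.stack(arrs)


def detect_images(model: Detector, images: list[LabeledImage] | list[np.ndarray],
                  config: SuppressionConfig, conf_threshold: float = 0.001,
                  batch_size: int = 8) -> list[list[Detection]]:
    """Per-image suppressed detections in the coordinates of the model input.

    Images are processed in eval mode (frozen batch-norm statistics).
    """
    model.eval()
    pixels = [im.pixels if isinstance(im, LabeledImage) else im for im in images]
    size = model.config.input_size
    out: list[list[Detection]] = []
    for i in range(0, len(pixels), batch_size):
        batch = prepare_batch(pixels[i:i + batch_size], size)
        raw = model(batch)
        decoded = decode_predictions(raw, model.config.anchors,
                                     model.config.num_classes, size,
                                     conf_threshold)
        out.extend(suppress(d, config) for d in decoded)
    return out


def draw_detections(image: np.ndarray, detections: list[Detection],
                    color=(255, 64, 32)) -> np.ndarray:
    """Return a copy of the image with detection rectangles burned in."""
    out = image.copy()
    H, W = out.shape[:2]
    for det in detections:
        x0, y0, x1, y1 = (int(round(v)) for v in det.box.corners)
        x0, x1 = np.clip([x0, x1], 0, W - 1)
        y0, y1 = np.clip([y0, y1], 0, H - 1)
        out[y0, x0:x1 + 1] = color
        out[y1, x0:x1 + 1] = color
        out[y0:y1 + 1, x0] = color
        out[y0:y1 + 1, x1] = color
    return out
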