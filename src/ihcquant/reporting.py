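"""Result rendering: pseudo-colored segmentations, result cards, montages.

Fill mode paints DAB particles brown and hematoxylin-only particles blue on
white, so the reader can eyeball the segmentation against the original
field.  Outline mode traces particle boundaries in red over the original
image.  Text is drawn with Pillow's built-in bitmap font so output is
deterministic across platforms.
"""

from __future__ import annotations

import math

import numpy as np
from PIL import Image, ImageDraw, ImageFont
from skimage.segmentation import find_boundaries

from .core_images import validate_rgb
from .errors import ValidationError

DAB_COLOR = (160, 90, 30)
H_COLOR = (70, 100, 200)
OUTLINE_COLOR = (255, 0, 0)
BACKGROUND_COLOR = (255, 255, 255)
HEADER_HEIGHT = 24
MARGIN = 8


def render_pseudocolor(
    dab_labels: np.ndarray,
    h_labels: np.ndarray,
    mode: str = "fill",
    original: np.ndarray | None = None,
    *,
    dab_color: tuple[int, int, int] = DAB_COLOR,
    h_color: tuple[int, int, int] = H_COLOR,
) -> np.ndarray:
    """Render the two label maps as a pseudo-colored RGB image.

    ``fill``: DAB particles brown, hematoxylin-only particles blue, white
    background (overlap pixels follow the DAB assignment of the index).
    ``outline``: particle boundaries red over ``original`` (white canvas if
    no original is given).
    """
    dab = np.asarray(dab_labels)
    h = np.asarray(h_labels)
    if dab.shape != h.shape:
        raise ValidationError("label maps must share dimensions")
    if mode == "fill":
        out = np.full(dab.shape + (3,), 255, dtype=np.uint8)
        out[h > 0] = h_color
        out[dab > 0] = dab_color
        return out
    if mode == "outline":
        if original is not None:
            out = validate_rgb(original).copy()
        else:
            out = np.full(dab.shape + (3,), 255, dtype=np.uint8)
        boundaries = find_boundaries(dab, mode="inner") | find_boundaries(h, mode="inner")
        out[boundaries] = OUTLINE_COLOR
        return out
    raise ValidationError(f"unknown render mode {mode!r}")


def _draw_header(width: int, text: str) -> np.ndarray:
    img = Image.new("RGB", (width, HEADER_HEIGHT), BACKGROUND_COLOR)
    draw = ImageDraw.Draw(img)
    draw.text((MARGIN, 5), text, fill=(0, 0, 0), font=ImageFont.load_default())
    return np.asarray(img)


def format_index(value: float) -> str:
    """Index as printed on cards: one decimal, or the no-area marker."""
    if value != value:  # NaN: no nuclear area found
        return "n/a"
    return f"{value:.1f}%"


def render_result_card(
    original: np.ndarray,
    pseudo_colored: np.ndarray,
    labeling_index_pct: float,
    id_string: str,
    analysis_date: str,
) -> np.ndarray:
    """Header band (id, date, index to one decimal) over original | pseudo-colored."""
    original = validate_rgb(original)
    pseudo_colored = validate_rgb(pseudo_colored)
    if original.shape != pseudo_colored.shape:
        raise ValidationError("original and pseudo-colored images must share dimensions")
    h, w = original.shape[:2]
    width = 2 * w + 3 * MARGIN
    height = HEADER_HEIGHT + h + MARGIN
    canvas = np.full((height, width, 3), 255, dtype=np.uint8)
    text = f"{id_string}  |  {analysis_date}  |  labeling index: {format_index(labeling_index_pct)}"
    canvas[:HEADER_HEIGHT, :, :] = _draw_header(width, text)
    y = HEADER_HEIGHT
    canvas[y : y + h, MARGIN : MARGIN + w] = original
    canvas[y : y + h, 2 * MARGIN + w : 2 * MARGIN + 2 * w] = pseudo_colored
    return canvas


def render_montage(cards, mean_index_pct: float | None = None) -> np.ndarray:
    """Grid of result cards (ceil(sqrt n) columns) under a sample header."""
    cards = [validate_rgb(c) for c in cards]
    if not cards:
        raise ValidationError("montage needs at least one card")
    n = len(cards)
    ncols = math.ceil(math.sqrt(n))
    nrows = math.ceil(n / ncols)
    cell_h = max(c.shape[0] for c in cards)
    cell_w = max(c.shape[1] for c in cards)
    width = ncols * cell_w + (ncols + 1) * MARGIN
    height = HEADER_HEIGHT + nrows * cell_h + (nrows + 1) * MARGIN
    canvas = np.full((height, width, 3), 255, dtype=np.uint8)
    if mean_index_pct is not None:
        text = f"sample mean labeling index: {format_index(mean_index_pct)} (n = {n})"
    else:
        text = f"n = {n} images"
    canvas[:HEADER_HEIGHT, :, :] = _draw_header(width, text)
    for i, card in enumerate(cards):
        row, col = divmod(i, ncols)
        y = HEADER_HEIGHT + MARGIN + row * (cell_h + MARGIN)
        x = MARGIN + col * (cell_w + MARGIN)
        canvas[y : y + card.shape[0], x : x + card.shape[1]] = card
    return canvas
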