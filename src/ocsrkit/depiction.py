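"""2D depiction rendering, binarization, and model-input preparation.

Molecules are drawn as black-on-white line diagrams, thresholded to a
one-channel binary image (ink = 1, background = 0), padded to a square,
resized with nearest-neighbour interpolation (which preserves the binary
value set), and replicated to three identical channels — the input format
the image-to-sequence network consumes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from PIL import Image
from rdkit import Chem
from rdkit.Chem.Draw import rdMolDraw2D

try:  # condensed-formula abbreviations (NO2, CF3, ...) where available
    from rdkit.Chem import rdAbbreviations

    _ABBREVIATIONS = rdAbbreviations.GetDefaultAbbreviations()
except ImportError:  # pragma: no cover
    _ABBREVIATIONS = None

from .corpus import CorpusRecord
from .vocab import Vocabulary

DEFAULT_IMAGE_SIZE = 224


class DepictionError(RuntimeError):
    """Raised when a molecule cannot be depicted or yields a blank image."""


@dataclass(frozen=True)
class DepictionStyle:
    """Rendering style knobs approximating literature depiction conventions.

    ``canvas`` is the raw render size before downscaling; ``rotation_jitter``
    is the half-range (degrees) of the random rotation drawn per molecule;
    ``condensed_formulas`` toggles abbreviation of common groups to their
    condensed text form (CF3, NO2, ...).
    """

    canvas: int = 384
    bond_line_width: float = 1.5
    min_font_size: int = 10
    max_font_size: int = 16
    atom_label_padding: float = 0.1
    rotation_jitter: float = 30.0
    condensed_formulas: bool = False
    fixed_bond_length: float = -1.0  # cap on bond length in px (-1: autoscale)

    def with_(self, **kwargs) -> "DepictionStyle":
        return dc_replace(self, **kwargs)


def render(
    record: CorpusRecord | str,
    style: DepictionStyle | None = None,
    rng: random.Random | None = None,
) -> np.ndarray:
    """Render a molecule as a grayscale image (uint8, dark ink on white).

    Deterministic for a fixed (record, style, rng state) triple.

    Raises
    ------
    DepictionError
        If depiction fails or produces no ink.
    """
    style = style or DepictionStyle()
    rng = rng or random.Random(0)
    smiles = record.smiles if isinstance(record, CorpusRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DepictionError(f"cannot parse {smiles!r} for depiction")
    if style.condensed_formulas and _ABBREVIATIONS is not None:
        try:
            mol = rdAbbreviations.CondenseMolAbbreviations(mol, _ABBREVIATIONS)
        except Exception:
            pass  # fall back to the expanded structure

    drawer = rdMolDraw2D.MolDraw2DCairo(style.canvas, style.canvas)
    opts = drawer.drawOptions()
    opts.bondLineWidth = style.bond_line_width
    opts.minFontSize = style.min_font_size
    opts.maxFontSize = style.max_font_size
    opts.additionalAtomLabelPadding = style.atom_label_padding
    if style.fixed_bond_length > 0:
        opts.fixedBondLength = style.fixed_bond_length
    opts.rotate = rng.uniform(-style.rotation_jitter, style.rotation_jitter)
    try:
        rdMolDraw2D.PrepareAndDrawMolecule(drawer, mol)
        drawer.FinishDrawing()
        png = drawer.GetDrawingText()
    except Exception as exc:
        raise DepictionError(f"depiction failed for {smiles!r}: {exc}") from exc

    import io

    gray = np.asarray(Image.open(io.BytesIO(png)).convert("L"))
    if int((gray < 250).sum()) == 0:
        raise DepictionError(f"blank depiction for {smiles!r}")
    return gray


def binarize(image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a grayscale image to an ink mask (ink = 1, background = 0).

    A pixel is ink when its intensity is below ``threshold`` of the full
    range, so raising the threshold never removes ink pixels.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    arr = np.asarray(image)
    if arr.ndim == 3:  # RGBA / RGB input: luminance first
        arr = np.asarray(Image.fromarray(arr.astype(np.uint8)).convert("L"))
    return (arr < threshold * 255.0).astype(np.uint8)


def to_model_input(binary: np.ndarray, size: int = DEFAULT_IMAGE_SIZE) -> np.ndarray:
    """Pad a binary image to a square, resize, and replicate to 3 channels.

    Nearest-neighbour resizing keeps pixel values in {0, 1}; padding uses
    the background value so the ink bounding box keeps its aspect ratio.
    Returns a ``size x size x 3`` uint8 array with identical channels.
    """
    arr = np.asarray(binary, dtype=np.uint8)
    if arr.ndim != 2:
        raise ValueError("expected a single-channel binary image")
    h, w = arr.shape
    side = max(h, w)
    padded = np.zeros((side, side), dtype=np.uint8)
    top, left = (side - h) // 2, (side - w) // 2
    padded[top : top + h, left : left + w] = arr
    resized = np.asarray(
        Image.fromarray(padded, mode="L").resize((size, size), Image.NEAREST)
    )
    return np.repeat(resized[:, :, None], 3, axis=2)


@dataclass
class RenderedSample:
    """A model-ready image paired with its encoded label sequence."""

    image: np.ndarray  # size x size x 3, values in {0, 1}
    label_ids: np.ndarray
    record: CorpusRecord


def render_sample(
    record: CorpusRecord,
    vocab: Vocabulary,
    max_len: int,
    style: DepictionStyle | None = None,
    rng: random.Random | None = None,
    image_size: int = DEFAULT_IMAGE_SIZE,
    threshold: float = 0.5,
) -> RenderedSample:
    gray = render(record, style, rng)
    binary = binarize(gray, threshold)
    if not binary.any():
        raise DepictionError(f"blank after thresholding: {record.smiles!r}")
    return RenderedSample(
        image=to_model_input(binary, image_size),
        label_ids=vocab.encode(record.deepsmiles, max_len),
        record=record,
    )


def render_dataset(records, vocab, max_len, style=None, seed=0,
                   image_size=DEFAULT_IMAGE_SIZE, threshold=0.5):
    """Render all records; failures are excluded and returned with reasons."""
    rng = random.Random(seed)
    samples, excluded = [], []
    for record in records:
        try:
            samples.append(
                render_sample(record, vocab, max_len, style, rng, image_size, threshold)
            )
        except Exception as exc:  # depiction or label-encoding failure
            excluded.append((record, str(exc)))
    return samples, excluded


def save_png(binary_or_sample, path) -> None:
    """Export an ink mask (or sample) as a black-on-white PNG."""
    arr = (
        binary_or_sample.image[:, :, 0]
        if isinstance(binary_or_sample, RenderedSample)
        else np.asarray(binary_or_sample)
    )
    Image.fromarray(((1 - arr) * 255).astype(np.uint8), mode="L").save(path)


def load_png_as_input(path, size: int = DEFAULT_IMAGE_SIZE, threshold: float = 0.5) -> np.ndarray:
    """Read a PNG and produce the model input array."""
    gray = np.asarray(Image.open(path).convert("L"))
    return to_model_input(binarize(gray, threshold), size)
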