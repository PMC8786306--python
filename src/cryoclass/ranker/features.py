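"""Per-class features and preprocessing for the class ranker.

Each 2D class average is cropped to the circular classification mask,
rescaled to 64 x 64 pixels and standardized; an 18-component feature
vector accompanies it:

* 12 density moments: mean, variance, skewness, kurtosis of the values in
  an automatically segmented protein region, the solvent region and a
  ring at the outer mask diameter;
* estimated rotational alignment accuracy (degrees) and translational
  accuracy (pixels);
* estimated resolution 1/d (1/A) and the weighted resolution d^2 / ln N
  (N = particles in the class);
* log10 class size and the protein-mask area fraction.

The exact composition of the original 18-feature vector is not public;
this ordering is this package's reconstruction and is fixed in
``FEATURE_NAMES``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, zoom

__all__ = ["ClassFeatures", "FEATURE_NAMES", "prepare_image",
           "weighted_resolution", "auto_masks", "compute_features",
           "select_classes", "fpr", "fnr"]

FEATURE_NAMES = tuple(
    [f"{region}_{m}" for region in ("protein", "solvent", "ring")
     for m in ("mean", "var", "skew", "kurt")]
    + ["acc_rotation", "acc_translation", "inv_resolution",
       "weighted_resolution", "log_class_size", "protein_area_fraction"])

RANKER_BOX = 64


@dataclass
class ClassFeatures:
    """The 18-feature vector of one 2D class, plus bookkeeping flags."""

    values: np.ndarray
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features, "
                             f"got {self.values.shape}")

    def as_dict(self) -> dict:
        return dict(zip(FEATURE_NAMES, self.values))


def _circle_mask(box: int, radius: float) -> np.ndarray:
    c = (box - 1) / 2.0
    jj, ii = np.meshgrid(np.arange(box), np.arange(box))
    return np.hypot(ii - c, jj - c) <= radius


def prepare_image(class_avg: np.ndarray, mask_diameter: float,
                  pixel_size: float = 1.0) -> tuple[np.ndarray, bool]:
    """Crop to the circular-mask bounding square, rescale to 64 x 64 and
    standardize to zero mean / unit variance inside the mask.

    Returns (image, flagged); ``flagged`` is True when the input had zero
    variance inside the mask and standardization was skipped.
    """
    box = class_avg.shape[0]
    radius_px = min(mask_diameter / (2.0 * pixel_size), box / 2.0)
    half = int(np.ceil(radius_px))
    c = box // 2
    lo, hi = max(c - half, 0), min(c + half, box)
    crop = class_avg[lo:hi, lo:hi]
    scale = RANKER_BOX / crop.shape[0]
    img = zoom(crop.astype(np.float64), scale, order=1)
    if img.shape != (RANKER_BOX, RANKER_BOX):   # guard against rounding
        img = img[:RANKER_BOX, :RANKER_BOX]
        pad = RANKER_BOX - img.shape[0]
        if pad > 0:
            img = np.pad(img, ((0, pad), (0, pad)))
    mask = _circle_mask(RANKER_BOX, RANKER_BOX / 2.0)
    inside = img[mask]
    sd = inside.std()
    if sd == 0:
        return np.zeros_like(img), True
    return (img - inside.mean()) / sd, False


def weighted_resolution(d: float, n_cls: int) -> tuple[float, bool]:
    """Weighted resolution d^2 / ln(N) in A^2 per nat.

    For n_cls < 2 the quantity is undefined (ln 1 = 0); returns
    (sentinel 0, flagged=True).
    """
    if d <= 0:
        raise ValueError("resolution d must be positive")
    if n_cls < 2:
        return 0.0, True
    return d * d / np.log(n_cls), False


def auto_masks(class_avg: np.ndarray, mask_diameter: float,
               pixel_size: float = 1.0, ring_width: float = 3.0,
               smooth_sigma: float = 1.0):
    """Segment a class average into protein, solvent and outer-ring masks.

    Protein: smoothed density above mean + 0.5 sd of in-circle values;
    ring: annulus of ``ring_width`` pixels at the circular mask's radius;
    solvent: remainder of the circle.  The three regions are disjoint.
    Returns (protein, solvent, ring, flagged) boolean arrays; ``flagged``
    marks an empty protein mask.
    """
    box = class_avg.shape[0]
    radius = min(mask_diameter / (2.0 * pixel_size), box / 2.0)
    circle = _circle_mask(box, radius)
    ring = circle & ~_circle_mask(box, max(radius - ring_width, 0.0))
    smoothed = gaussian_filter(class_avg.astype(np.float64), smooth_sigma)
    inside = smoothed[circle]
    thresh = inside.mean() + 0.5 * inside.std()
    protein = (smoothed > thresh) & circle & ~ring
    solvent = circle & ~protein & ~ring
    flagged = not protein.any()
    return protein, solvent, ring, flagged


def _region_moments(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """(mean, variance, skewness, excess-free kurtosis) of region values.

    Zero-variance (or empty) regions give skewness/kurtosis 0 with a flag.
    """
    if values.size == 0:
        return np.zeros(4), True
    mean = values.mean()
    var = values.var()
    if var == 0:
        return np.array([mean, 0.0, 0.0, 0.0]), True
    z = (values - mean) / np.sqrt(var)
    return np.array([mean, var, (z ** 3).mean(), (z ** 4).mean()]), False


def compute_features(class_avg: np.ndarray, metadata: dict,
                     mask_diameter: float, pixel_size: float = 1.0) -> ClassFeatures:
    """Assemble the 18-feature vector for one class average.

    ``metadata`` must supply: acc_rotation (deg), acc_translation (px),
    resolution (d in A), class_size (particle count).  A missing key
    raises a KeyError naming the field.
    """
    for key in ("acc_rotation", "acc_translation", "resolution", "class_size"):
        if key not in metadata:
            raise KeyError(f"missing metadata field '{key}'")
    protein, solvent, ring, empty_protein = auto_masks(
        class_avg, mask_diameter, pixel_size)
    flags = []
    if empty_protein:
        flags.append("empty_protein_mask")
    vals = []
    for name, mask in (("protein", protein), ("solvent", solvent),
                       ("ring", ring)):
        m, flagged = _region_moments(class_avg[mask])
        if flagged:
            flags.append(f"degenerate_{name}_moments")
        vals.extend(m)
    d = float(metadata["resolution"])
    n_cls = int(metadata["class_size"])
    wres, wflag = weighted_resolution(d, n_cls)
    if wflag:
        flags.append("undefined_weighted_resolution")
    circle = _circle_mask(class_avg.shape[0],
                          min(mask_diameter / (2 * pixel_size),
                              class_avg.shape[0] / 2))
    vals.extend([float(metadata["acc_rotation"]),
                 float(metadata["acc_translation"]),
                 1.0 / d,
                 wres,
                 np.log10(max(n_cls, 1)),
                 protein.sum() / max(circle.sum(), 1)])
    return ClassFeatures(values=np.array(vals), flags=flags)


def select_classes(scores: np.ndarray, threshold: float = 0.15,
                   class_numbers: np.ndarray | None = None) -> np.ndarray:
    """Classes with score >= threshold (inclusive); returns their 1-based
    class numbers, preserving order.  Monotone in the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    scores = np.asarray(scores, dtype=float)
    if class_numbers is None:
        class_numbers = np.arange(1, len(scores) + 1)
    return np.asarray(class_numbers)[scores >= threshold]


def fpr(selected: np.ndarray, reference: np.ndarray) -> float:
    """False-positive rate of a particle selection against a reference:
    |selected \\ reference| / |reference|."""
    sel, ref = set(np.asarray(selected).tolist()), set(np.asarray(reference).tolist())
    if not ref:
        return 0.0
    return len(sel - ref) / len(ref)


def fnr(selected: np.ndarray, reference: np.ndarray) -> float:
    """False-negative rate: |reference \\ selected| / |reference|."""
    sel, ref = set(np.asarray(selected).tolist()), set(np.asarray(reference).tolist())
    if not ref:
        return 0.0
    return len(ref - sel) / len(ref)
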