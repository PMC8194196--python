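"""Synthetic chest-radiograph phantoms with anatomy masks, multi-label
lesions and bounding boxes.

Each phantom is a noisy square image containing two vertically elongated
lung ellipses and one heart ellipse at jittered canonical positions, with
distinct mean intensities.  Disease classes map to lesion shape families:

* ``disc``  — small bright disc inside a lung (nodule-like),
* ``haze``  — diffuse radial-falloff brightening in a lung (infiltration-like),
* ``wedge`` — bright circular sector inside a lung (consolidation-like),
* ``cardio`` — enlarged heart axes plus brightening (cardiomegaly-like).

A sample's label vector has ``labels[k] = 1`` iff at least one lesion of
class ``k`` was inserted; label-bearing lesions lie (>= 80 % of their pixels)
inside the merged lung/heart mask and their tight bounding boxes are
recorded.

The background also contains a few dark *air-pocket* ellipses at lung-like
intensity but outside the lung/heart masks — the phantom analogue of bowel
gas below the diaphragm or axillary air, i.e. radiolucent regions that are
locally indistinguishable from lung tissue.  *Distractor* lesions drawn from
the same shape families as true lesions are rendered inside these pockets
(zero pixel overlap with the merged mask) and carry no label.  Because a
distractor then looks exactly like a lesion in its local neighbourhood,
anatomical position is the only feature separating it from true pathology —
which is precisely what mask-based feature weighting is supposed to exploit
and what a global classifier cannot.

Rendering accumulates in float, then quantises to 8-bit before the final
[0, 1] float conversion, so identical configurations are byte-identical
across runs and platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .localization import BBox
from .segmentation import StructureMaskSet, MergedMask, merge_masks

FAMILIES = ("disc", "haze", "wedge", "cardio")

#: default class templates: name -> (shape family, host structures)
DEFAULT_CLASS_TEMPLATES = (
    ("Cardiomegaly", "cardio"),
    ("Infiltration", "haze"),
    ("Nodule", "disc"),
    ("Consolidation", "wedge"),
)

#: family assignment for the canonical 14-disease label space
FAMILY_BY_CLASS = {
    "Atelectasis": "wedge", "Cardiomegaly": "cardio", "Effusion": "haze",
    "Infiltration": "haze", "Mass": "disc", "Nodule": "disc",
    "Pneumonia": "haze", "Pneumothorax": "wedge", "Consolidation": "wedge",
    "Edema": "haze", "Emphysema": "haze", "Fibrosis": "wedge",
    "Pleural Thickening": "wedge", "Hernia": "disc",
}

# base intensities on the 8-bit scale
BG_LEVEL = 70.0
LUNG_LEVEL = 40.0
HEART_LEVEL = 150.0

MIN_IN_MASK_FRACTION = 0.8


@dataclass(frozen=True)
class LesionSpec:
    """Rendering parameters for one class's lesions."""

    family: str
    size_range: tuple[float, float]        # radius as a fraction of image size
    intensity_range: tuple[float, float]   # additive offset, 8-bit scale

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown lesion family '{self.family}'")


#: the three lung families occupy distinct size scales and non-overlapping
#: additive-intensity bands (haze < wedge < disc) so that phantom classes are
#: separable by construction, as befits a synthetic benchmark
DEFAULT_LESION_SPECS = {
    "disc": LesionSpec("disc", (0.05, 0.08), (95.0, 130.0)),
    "haze": LesionSpec("haze", (0.12, 0.18), (30.0, 45.0)),
    "wedge": LesionSpec("wedge", (0.10, 0.15), (55.0, 75.0)),
    "cardio": LesionSpec("cardio", (0.30, 0.45), (20.0, 30.0)),  # size = axis enlargement
}


def default_class_names(n_classes: int) -> list[str]:
    if n_classes <= len(DEFAULT_CLASS_TEMPLATES):
        return [name for name, _ in DEFAULT_CLASS_TEMPLATES[:n_classes]]
    return list(FAMILY_BY_CLASS)[:n_classes]


def family_for_class(name: str) -> str:
    try:
        return FAMILY_BY_CLASS[name]
    except KeyError:
        raise ValueError(f"no lesion family defined for class '{name}'") from None


@dataclass
class PhantomConfig:
    image_size: int = 224
    n_samples: int = 100
    n_classes: int = 4
    class_names: list[str] | None = None
    lesion_specs: dict[str, LesionSpec] = field(default_factory=lambda: dict(DEFAULT_LESION_SPECS))
    distractor_rate: float = 0.5
    label_prior: float | list[float] = 0.3
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not (1 <= self.n_classes <= 14):
            raise ValueError("n_classes must be in [1, 14]")
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")
        if not (0.0 <= self.distractor_rate <= 1.0):
            raise ValueError("distractor_rate must lie in [0, 1]")
        if not (0.0 <= self.noise_sd <= 1.0):
            raise ValueError("noise_sd must lie in [0, 1]")
        if self.class_names is None:
            self.class_names = default_class_names(self.n_classes)
        if len(self.class_names) != self.n_classes:
            raise ValueError("class_names length must equal n_classes")
        priors = self.priors()
        if np.any(priors < 0) or np.any(priors > 1):
            raise ValueError("label_prior probabilities must lie in [0, 1]")

    def priors(self) -> np.ndarray:
        p = np.asarray(self.label_prior, dtype=np.float64)
        return np.full(self.n_classes, float(p)) if p.ndim == 0 else p


@dataclass
class PhantomSample:
    """One synthetic radiograph with its masks, labels and lesion boxes."""

    sample_id: str
    image: np.ndarray                      # [3, H, W] float32 in [0, 1]
    masks: StructureMaskSet
    labels: np.ndarray                     # [c] uint8
    boxes: list[tuple[int, BBox]]          # (class index, box) per label-bearing lesion
    distractor_boxes: list[BBox]

    @property
    def merged_mask(self) -> MergedMask:
        return merge_masks(self.masks)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ellipse(size: int, cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def _tight_box(support: np.ndarray) -> BBox:
    ys, xs = np.nonzero(support)
    return BBox(int(xs.min()), int(ys.min()),
                int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1))


def _lesion_support_and_offset(family: str, spec: LesionSpec, size: int,
                               cx: int, cy: int, rng: np.random.Generator):
    """Boolean support and additive intensity field for one lesion."""
    s = size
    r = max(2.0, rng.uniform(*spec.size_range) * s)
    amp = rng.uniform(*spec.intensity_range)
    yy, xx = np.mgrid[0:s, 0:s]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    if family == "disc":
        support = d2 <= r * r
        offset = np.where(support, amp, 0.0)
    elif family == "haze":
        falloff = np.clip(1.0 - d2 / (r * r), 0.0, None)
        offset = amp * falloff
        support = falloff >= 0.3
    elif family == "wedge":
        theta0 = rng.uniform(0.0, 2 * np.pi)
        ang = np.arctan2(yy - cy, xx - cx)
        dtheta = np.mod(ang - theta0, 2 * np.pi)
        support = (d2 <= r * r) & (dtheta <= np.pi / 2)
        offset = np.where(support, amp, 0.0)
    else:
        raise ValueError(family)
    return support, offset


def _render_sample(config: PhantomConfig, index: int) -> PhantomSample:
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) % (2 ** 31), index]))
    s = config.image_size
    priors = config.priors()
    labels = (rng.random(config.n_classes) < priors).astype(np.uint8)

    # --- anatomy: jittered canonical ellipse layout -----------------------
    def jit(v, frac=0.10):
        return v * rng.uniform(1.0 - frac, 1.0 + frac)

    lungs = {}
    for name, cxf in (("right_lung", 0.32), ("left_lung", 0.68)):
        cx, cy = jit(cxf * s, 0.03), jit(0.44 * s, 0.03)
        ax, ay = jit(0.15 * s), jit(0.27 * s)
        lungs[name] = (cx, cy, ax, ay)
    heart_cx, heart_cy = jit(0.56 * s, 0.03), jit(0.63 * s, 0.03)
    heart_ax, heart_ay = jit(0.155 * s), jit(0.125 * s)

    cardio_on = False
    cardio_idx = None
    for k, name in enumerate(config.class_names):
        if labels[k] and family_for_class(name) == "cardio":
            cardio_on = True
            cardio_idx = k
    if cardio_on:
        spec = config.lesion_specs["cardio"]
        enlarge = 1.0 + rng.uniform(*spec.size_range)
        heart_ax *= enlarge
        heart_ay *= 1.0 + 0.4 * (enlarge - 1.0)

    lung_masks = {name: _ellipse(s, *geom) for name, geom in lungs.items()}
    heart_mask = _ellipse(s, heart_cx, heart_cy, heart_ax, heart_ay)
    masks = StructureMaskSet(left_lung=lung_masks["left_lung"].astype(np.uint8),
                             right_lung=lung_masks["right_lung"].astype(np.uint8),
                             heart=heart_mask.astype(np.uint8))
    merged = merge_masks(masks).mask[0].astype(bool)

    canvas = np.full((s, s), BG_LEVEL, dtype=np.float64)

    # dark lung-like "air pockets" outside the anatomy (bowel gas, axillary
    # air): candidate hosts for distractor lesions
    pockets = np.zeros((s, s), dtype=bool)
    n_pockets = int(rng.integers(2, 5))
    for _ in range(n_pockets):
        for _attempt in range(40):
            pcx, pcy = rng.uniform(0.08 * s, 0.92 * s, 2)
            pax = rng.uniform(0.09, 0.14) * s
            pay = rng.uniform(0.09, 0.15) * s
            pocket = _ellipse(s, pcx, pcy, pax, pay)
            if pocket.any() and not (pocket & merged).any():
                pockets |= pocket
                break

    canvas[pockets] = LUNG_LEVEL
    canvas[lung_masks["right_lung"]] = LUNG_LEVEL
    canvas[lung_masks["left_lung"]] = LUNG_LEVEL
    canvas[heart_mask] = HEART_LEVEL

    # structured background clutter outside the anatomy: the phantom analogue
    # of bowel gas with bright content, implants and film markers.  Each
    # piece is a dark lung-intensity host ellipse carrying a bright interior
    # shape whose intensity spans the lesion bands, so clutter is *locally*
    # indistinguishable from pathology on lung tissue.  A global classifier
    # pooling over the whole image therefore accumulates lesion-band activity
    # unrelated to the labels, while a mask-weighted classifier never sees it.
    n_clutter = int(rng.integers(8, 15))
    for _ in range(n_clutter):
        for _attempt in range(30):
            ccx, ccy = rng.uniform(0.0, s, 2)
            hax = rng.uniform(0.05, 0.11) * s
            hay = rng.uniform(0.05, 0.12) * s
            host = _ellipse(s, ccx, ccy, hax, hay)
            if not host.any() or (host & merged).any():
                continue
            canvas[host] = LUNG_LEVEL
            if rng.random() < 0.5:
                iax = hax * rng.uniform(0.3, 0.6)
                iay = hay * rng.uniform(0.3, 0.6)
            else:  # bar-like interior (marker analogue)
                iax = hax * rng.uniform(0.15, 0.3)
                iay = hay * rng.uniform(0.6, 0.9)
            inner = _ellipse(s, ccx, ccy, iax, iay) & host
            canvas[inner] += rng.uniform(25.0, 125.0)
            break

    # --- label-bearing lesions -------------------------------------------
    boxes: list[tuple[int, BBox]] = []
    for k, name in enumerate(config.class_names):
        if not labels[k]:
            continue
        family = family_for_class(name)
        if family == "cardio":
            spec = config.lesion_specs["cardio"]
            canvas[heart_mask] += rng.uniform(*spec.intensity_range)
            boxes.append((k, _tight_box(heart_mask)))
            continue
        spec = config.lesion_specs[family]
        lung_name = "left_lung" if rng.random() < 0.5 else "right_lung"
        host = lung_masks[lung_name]
        hy, hx = np.nonzero(host)
        placed = False
        for _ in range(30):
            j = rng.integers(len(hy))
            cx, cy = int(hx[j]), int(hy[j])
            support, offset = _lesion_support_and_offset(family, spec, s, cx, cy, rng)
            if support.sum() == 0:
                continue
            frac_in = (support & merged).sum() / support.sum()
            if frac_in >= MIN_IN_MASK_FRACTION:
                canvas += offset
                boxes.append((k, _tight_box(support)))
                placed = True
                break
        if not placed:
            labels[k] = 0  # insertion failed: the label must reflect the image

    # --- distractor lesion outside the anatomy ----------------------------
    # placed inside an air pocket so it is locally indistinguishable from a
    # true lesion; only its anatomical position differs
    distractor_boxes: list[BBox] = []
    if rng.random() < config.distractor_rate and pockets.any():
        family = ("disc", "haze", "wedge")[rng.integers(3)]
        spec = config.lesion_specs[family]
        py, px = np.nonzero(pockets)
        for _ in range(100):
            j = rng.integers(len(py))
            cx, cy = int(px[j]), int(py[j])
            support, offset = _lesion_support_and_offset(family, spec, s, cx, cy, rng)
            if support.sum() == 0 or (support & merged).any():
                continue
            box = _tight_box(support)
            # the recorded box itself must not touch the merged mask
            if merged[box.y:box.y2, box.x:box.x2].any():
                continue
            canvas += offset
            distractor_boxes.append(box)
            break

    canvas += rng.normal(0.0, config.noise_sd * 255.0, size=canvas.shape)
    quantised = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    image = np.repeat((quantised.astype(np.float32) / 255.0)[None], 3, axis=0)

    return PhantomSample(sample_id=f"phantom_{index:05d}.png", image=image,
                         masks=masks, labels=labels, boxes=boxes,
                         distractor_boxes=distractor_boxes)


def generate_phantom(config: PhantomConfig) -> list[PhantomSample]:
    """Generate ``config.n_samples`` phantoms, deterministic given the seed
    (per-sample sub-generators are derived from a counter)."""
    return [_render_sample(config, i) for i in range(config.n_samples)]


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_phantom(samples: list[PhantomSample], train_frac: float = 0.9,
                  val_frac: float = 0.1, seed: int = 0):
    """Split into (train, val, test); the test split holds the
    ``1 - train_frac`` remainder and the validation split is ``val_frac`` *of
    the train split* (mirroring the common per-disease 10 %-of-train rule).

    Rounding rule: ``n_test = round(n * (1 - train_frac))``, then
    ``n_val = round((n - n_test) * val_frac)``.  Stratified on the label
    combination where group sizes allow; otherwise falls back to an
    unstratified split with a warning.  Deterministic given the seed.
    """
    if not (0.0 < train_frac < 1.0) or not (0.0 < val_frac < 1.0):
        raise ValueError("fractions must lie in (0, 1)")
    n = len(samples)
    n_test = int(round(n * (1.0 - train_frac)))
    n_val = int(round((n - n_test) * val_frac))
    if n_test < 1 or n_val < 1 or n_test + n_val >= n:
        raise ValueError("splits require at least one sample each")
    from sklearn.model_selection import train_test_split

    idx = np.arange(n)
    combos = np.array(["".join(map(str, s.labels)) for s in samples])

    def _split(ids, strata, size, rs):
        try:
            return train_test_split(ids, test_size=size, random_state=rs, stratify=strata)
        except ValueError:
            warnings.warn("too few samples per label combination; unstratified split")
            return train_test_split(ids, test_size=size, random_state=rs, stratify=None)

    rest, test_idx = _split(idx, combos, n_test, seed % (2 ** 31))
    train_idx, val_idx = _split(rest, combos[rest], n_val, (seed + 1) % (2 ** 31))
    pick = lambda ids: [samples[i] for i in sorted(ids)]
    return pick(train_idx), pick(val_idx), pick(test_idx)
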