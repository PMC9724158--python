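"""Seeded synthetic two-modality phantom generator.

Renders co-registered pairs of grayscale slices from a shared tissue-label
geometry: a nested-ellipse "head" (outer skull ring, inner brain region, and
one or more interior structures, Shepp-Logan-like) is drawn once per sample,
then rendered into two imaging domains A and B through per-tissue intensity
lookup tables on a 12-bit [0, 4095] scale, with boundary smoothing and
additive Gaussian noise. Because both domains share the geometry and the
tissue-wise map A->B is injective, a perfect lookup translator exists and
serves as an error floor for any trained model.

Unpaired sets are produced by shuffling targets (the permutation is recorded
for evaluation but withheld from trainers); motion-corrupted variants replace
a subset of k-space (2-D DFT) lines with lines from a rigidly shifted copy,
the standard ghosting simulation for subject motion during acquisition.

All randomness is keyed by ``(seed, index, purpose)`` through
``numpy.random.SeedSequence`` so adding samples never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

INTENSITY_MAX = 4095.0

# Default per-tissue mean intensities (12-bit). Domain A is MRI-like
# (bright soft tissue, dark bone); domain B is CT-like (bright bone).
DEFAULT_TABLE_A = (0.0, 800.0, 2600.0, 3400.0, 1500.0, 2100.0)
DEFAULT_TABLE_B = (0.0, 3600.0, 1200.0, 600.0, 2800.0, 2000.0)

DEFAULT_GEOMETRY = {
    "skull_axes": (0.32, 0.42),      # semi-axes, fraction of image size
    "skull_thickness": (0.03, 0.06),  # ring thickness, fraction
    "inner_axes": (0.05, 0.12),      # interior structure semi-axes, fraction
    "center_jitter": 0.02,           # head centre jitter, fraction
    "rotation": (-0.6, 0.6),         # radians
}


class InvalidSpecError(ValueError):
    """Phantom geometry or tables that cannot produce a valid sample."""


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic two-domain dataset."""

    image_size: int = 256
    n_tissues: int = 5
    geometry_ranges: dict = field(default_factory=lambda: dict(DEFAULT_GEOMETRY))
    intensity_table_A: tuple = None
    intensity_table_B: tuple = None
    noise_sigma: tuple = (40.0, 40.0)  # (domain A, domain B), 12-bit units
    smoothing_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.image_size <= 0 or self.image_size % 2:
            raise InvalidSpecError("image_size must be positive and even")
        if not 2 <= self.n_tissues <= 6:
            raise InvalidSpecError("n_tissues must be in [2, 6]")
        if self.intensity_table_A is None:
            self.intensity_table_A = DEFAULT_TABLE_A[: self.n_tissues]
        if self.intensity_table_B is None:
            self.intensity_table_B = DEFAULT_TABLE_B[: self.n_tissues]
        self.intensity_table_A = tuple(float(v) for v in self.intensity_table_A)
        self.intensity_table_B = tuple(float(v) for v in self.intensity_table_B)
        for name, table in (("A", self.intensity_table_A), ("B", self.intensity_table_B)):
            if len(table) != self.n_tissues:
                raise InvalidSpecError(
                    f"intensity_table_{name} must have {self.n_tissues} entries"
                )
            if any(not 0 <= v <= INTENSITY_MAX for v in table):
                raise InvalidSpecError(f"intensity_table_{name} outside [0, 4095]")
        # a deterministic A->B translation must exist wherever A is injective
        a, b = self.intensity_table_A, self.intensity_table_B
        for i in range(self.n_tissues):
            for j in range(i + 1, self.n_tissues):
                if a[i] != a[j] and b[i] == b[j]:
                    raise InvalidSpecError(
                        "table B collapses tissues that table A distinguishes"
                    )
        if isinstance(self.noise_sigma, (int, float)):
            self.noise_sigma = (float(self.noise_sigma), float(self.noise_sigma))
        gr = dict(DEFAULT_GEOMETRY)
        gr.update(self.geometry_ranges)
        self.geometry_ranges = {
            k: tuple(v) if isinstance(v, (list, tuple)) else float(v)
            for k, v in gr.items()
        }
        gr = self.geometry_ranges
        hi_ax = gr["skull_axes"][1] + gr["center_jitter"]
        if hi_ax >= 0.5 - 2.0 / self.image_size:
            raise InvalidSpecError(
                "skull axes + centre jitter cannot fit inside the image border"
            )


@dataclass
class TissueLabelMap:
    """Integer tissue-region map both domains are rendered from."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def n_present(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class Image2D:
    """One grayscale slice plus intensity-range metadata."""

    pixels: np.ndarray
    intensity_max: float = INTENSITY_MAX
    domain_tag: str = "A"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")

    @property
    def shape(self):
        return self.pixels.shape

    def to_network(self) -> np.ndarray:
        """Map [0, intensity_max] to the network range [-1, 1]."""
        return self.pixels / self.intensity_max * 2.0 - 1.0

    @classmethod
    def from_network(cls, arr: np.ndarray, intensity_max: float = INTENSITY_MAX,
                     domain_tag: str = "A") -> "Image2D":
        pix = np.clip((np.asarray(arr) + 1.0) / 2.0, 0.0, 1.0) * intensity_max
        return cls(pix, intensity_max, domain_tag)


@dataclass
class MotionSpec:
    """Parameters of the k-space line-replacement ghosting model."""

    n_corrupt_lines: int = 32
    max_shift: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_corrupt_lines < 0:
            raise ValueError("n_corrupt_lines must be >= 0")
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")


@dataclass
class SampleSet:
    """Ordered source/target image collections with recorded pairing."""

    sources: list
    targets: list
    paired: bool
    pairing_permutation: np.ndarray

    def __post_init__(self):
        if len(self.sources) != len(self.targets):
            raise ValueError("sources and targets must have equal length")
        perm = np.asarray(self.pairing_permutation, dtype=np.int64)
        if sorted(perm.tolist()) != list(range(len(self.sources))):
            raise ValueError("pairing_permutation must be a permutation of indices")
        if self.paired and not np.array_equal(perm, np.arange(len(perm))):
            raise ValueError("paired sets require the identity permutation")
        self.pairing_permutation = perm

    def __len__(self):
        return len(self.sources)

    def unpaired_view(self):
        """(sources, targets) only — what an unpaired trainer may see."""
        return list(self.sources), list(self.targets)

    def true_pairs(self):
        """Co-registered (source, target) pairs, undoing any shuffle.

        Evaluation-only: recovers the hidden pairing of an unpaired set.
        """
        inverse = np.argsort(self.pairing_permutation)
        return [(self.sources[i], self.targets[inverse[i]])
                for i in range(len(self.sources))]


# -- geometry --------------------------------------------------------------

def _rng_for(spec: PhantomSpec, index: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), int(index), int(purpose)])
    )


def generate_label_map(spec: PhantomSpec, index: int) -> TissueLabelMap:
    """Draw the nested-ellipse head geometry for sample ``index``.

    Deterministic given ``(spec.seed, index)``. Labels: 0 background,
    1 skull ring, 2 brain, 3.. interior structures; all ``n_tissues``
    labels are guaranteed present.
    """
    rng = _rng_for(spec, index, purpose=0)
    size = spec.image_size
    gr = spec.geometry_ranges
    labels = np.zeros((size, size), dtype=np.int64)

    cy = size / 2 + rng.uniform(-1, 1) * gr["center_jitter"] * size
    cx = size / 2 + rng.uniform(-1, 1) * gr["center_jitter"] * size
    ax_r = rng.uniform(*gr["skull_axes"]) * size
    ax_c = rng.uniform(*gr["skull_axes"]) * size
    rot = rng.uniform(*gr["rotation"])
    thickness = rng.uniform(*gr["skull_thickness"]) * size

    rr, cc = draw_ellipse(cy, cx, ax_r, ax_c, shape=labels.shape, rotation=rot)
    labels[rr, cc] = 1  # skull
    inner_r = ax_r - thickness
    inner_c = ax_c - thickness
    if inner_r < 4 or inner_c < 4:
        raise InvalidSpecError("skull ring leaves no room for the brain region")
    rr, cc = draw_ellipse(cy, cx, inner_r, inner_c, shape=labels.shape, rotation=rot)
    if spec.n_tissues > 2:
        labels[rr, cc] = 2  # brain

    for tissue in range(3, spec.n_tissues):
        brain_mask = labels == 2  # refreshed so structures never overlap
        for _attempt in range(64):
            sr = rng.uniform(*gr["inner_axes"]) * size
            sc = rng.uniform(*gr["inner_axes"]) * size
            oy = cy + rng.uniform(-0.5, 0.5) * inner_r
            ox = cx + rng.uniform(-0.5, 0.5) * inner_c
            srot = rng.uniform(*gr["rotation"])
            rr, cc = draw_ellipse(oy, ox, sr, sc, shape=labels.shape, rotation=srot)
            if len(rr) and brain_mask[rr, cc].all():
                labels[rr, cc] = tissue
                break
        else:
            raise InvalidSpecError(
                f"could not place interior structure {tissue} inside the brain"
            )

    border = np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    assert (border == 0).all(), "background must cover the image border ring"
    present = set(np.unique(labels).tolist())
    expected = set(range(spec.n_tissues)) if spec.n_tissues > 2 else {0, 1}
    if present != expected:
        raise InvalidSpecError(f"labels {sorted(present)} != expected {sorted(expected)}")
    return TissueLabelMap(labels)


def render_domain(label_map: TissueLabelMap, table, noise_sigma: float,
                  smoothing_sigma: float, rng: np.random.Generator,
                  domain_tag: str = "A") -> Image2D:
    """Render tissue labels into intensities: lookup, blur, noise, clip."""
    labels = label_map.labels
    table = np.asarray(table, dtype=np.float64)
    if labels.max() >= len(table):
        raise ValueError(
            f"table has {len(table)} entries but labels reach {labels.max()}"
        )
    img = table[labels]
    if smoothing_sigma > 0:
        img = ndimage.gaussian_filter(img, smoothing_sigma)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    return Image2D(np.clip(img, 0.0, INTENSITY_MAX), INTENSITY_MAX, domain_tag)


def render_pair(spec: PhantomSpec, index: int) -> tuple[Image2D, Image2D]:
    """Co-registered (A, B) renderings of sample ``index``'s geometry."""
    label_map = generate_label_map(spec, index)
    img_a = render_domain(label_map, spec.intensity_table_A, spec.noise_sigma[0],
                          spec.smoothing_sigma, _rng_for(spec, index, 1), "A")
    img_b = render_domain(label_map, spec.intensity_table_B, spec.noise_sigma[1],
                          spec.smoothing_sigma, _rng_for(spec, index, 2), "B")
    return img_a, img_b


def corrupt_with_motion(img: Image2D, m: MotionSpec) -> Image2D:
    """Replace k-space lines with lines from a rigidly shifted copy.

    ``n_corrupt_lines`` rows of the 2-D DFT are swapped for the corresponding
    rows of the DFT of an in-plane translated copy (shift uniform in
    [-max_shift, max_shift] per axis), then inverse-transformed; the
    magnitude is taken and clipped. Zero lines returns the input unchanged.
    """
    h, w = img.pixels.shape
    if h != w:
        raise ValueError("motion corruption expects a square image")
    if m.n_corrupt_lines >= h:
        raise ValueError("n_corrupt_lines must be < image size")
    if m.n_corrupt_lines == 0:
        return Image2D(img.pixels.copy(), img.intensity_max, img.domain_tag)
    rng = np.random.default_rng(np.random.SeedSequence([int(m.seed), 3]))
    shift = rng.uniform(-m.max_shift, m.max_shift, size=2)
    shifted = ndimage.shift(img.pixels, shift, order=1, mode="nearest")
    k_clean = np.fft.fft2(img.pixels)
    k_moved = np.fft.fft2(shifted)
    rows = rng.choice(h, size=m.n_corrupt_lines, replace=False)
    k_clean[rows] = k_moved[rows]
    out = np.abs(np.fft.ifft2(k_clean))
    return Image2D(np.clip(out, 0.0, INTENSITY_MAX), img.intensity_max, "motion")


def make_dataset(spec: PhantomSpec, n: int, paired: bool = True,
                 motion: MotionSpec | None = None) -> SampleSet:
    """Build an n-sample dataset.

    paired: co-registered (A_i, B_i). Unpaired: targets shuffled with a
    recorded permutation (re-drawn, deterministically, in the unlikely event
    more than 10% of indices map to themselves). With ``motion`` set, the
    task becomes motion correction: source = corrupted copy of the clean
    domain-A image, target = the clean image itself.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sources, targets = [], []
    for i in range(n):
        img_a, img_b = render_pair(spec, i)
        if motion is not None:
            m_i = MotionSpec(motion.n_corrupt_lines, motion.max_shift,
                             seed=int(np.random.SeedSequence(
                                 [int(motion.seed), int(i)]).generate_state(1)[0] % (2 ** 31)))
            sources.append(corrupt_with_motion(img_a, m_i))
            targets.append(img_a)
        else:
            sources.append(img_a)
            targets.append(img_b)
    if paired:
        perm = np.arange(n)
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 10_001]))
        perm = rng.permutation(n)
        if n > 1:
            while np.mean(perm == np.arange(n)) > 0.10:
                perm = rng.permutation(n)
        targets = [targets[j] for j in perm]
        # targets[i] == original target perm[i]; identity pairing is target
        # index inverse(perm)[i] for source i, recovered by true_pairs().
    return SampleSet(sources, targets, paired, perm)


def lookup_translator(spec: PhantomSpec):
    """The tissue-wise lookup table as a perfect A->B translator.

    With zero noise and zero smoothing this maps each rendered A intensity
    to the corresponding B intensity exactly; it is the error floor any
    trained model can be compared against. Pixels between table entries
    (boundary blur) are mapped by nearest table-A intensity.
    """
    table_a = np.asarray(spec.intensity_table_A)
    table_b = np.asarray(spec.intensity_table_B)

    def translate(img: Image2D) -> Image2D:
        dist = np.abs(img.pixels[..., None] - table_a[None, None, :])
        nearest = np.argmin(dist, axis=-1)
        return Image2D(table_b[nearest], img.intensity_max, "B")

    return translate
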