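"""Synthetic ovarian-ultrasound phantoms.

Clinical transvaginal images cannot be redistributed, so validation runs on
phantoms that emulate their defining features: dark (hypoechoic) elliptical
follicles of varied size inside a brighter ovary, a darker far field, faint
blurred follicle walls, a smooth multiplicative bias (beam inhomogeneity),
and multiplicative gamma speckle (the average-of-looks surrogate: shape =
``speckle_looks``, mean 1, relative std = looks^-1/2).

Determinism: one seed drives two separated generator streams — follicle
*placement* and *noise*.  Masks depend only on the placement stream, so the
same spec with different noise draws keeps identical ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = ["PlacementError", "PhantomSpec", "PRESETS", "apply_preset", "generate", "generate_suite"]

_MAX_ATTEMPTS_PER_FOLLICLE = 400


class PlacementError(RuntimeError):
    """Could not place the requested follicles without overlap."""


@dataclass(frozen=True)
class PhantomSpec:
    """Scene and degradation parameters for one phantom.

    Intensities are on [0, 1] with ``follicle_level < stroma_level``
    (hypoechoic follicles).  ``speckle_looks`` is the gamma shape (larger =
    less noise, 0 disables); ``inhomogeneity_amp`` bounds the smooth
    multiplicative bias field; ``boundary_softness`` is the Gaussian blur
    sigma in pixels that softens follicle walls.
    """

    height: int = 160
    width: int = 160
    ovary: tuple[float, float, float, float, float] | None = None  # (cr, cc, a, b, theta)
    n_follicles: int = 12
    radius_range: tuple[float, float] = (6.0, 14.0)
    follicle_level: float = 0.10
    stroma_level: float = 0.50
    background_level: float = 0.45
    boundary_softness: float = 1.5
    speckle_looks: float = 4.0
    inhomogeneity_amp: float = 0.20
    allow_touching: bool = False
    seed: int = 0
    noise_seed: int | None = None  # re-seed only the noise stream; layout kept

    def __post_init__(self):
        if self.height < 16 or self.width < 16:
            raise ValueError("PhantomSpec: image must be at least 16 x 16")
        if not (0.0 <= self.follicle_level < self.stroma_level <= 1.0):
            raise ValueError("PhantomSpec: need 0 <= follicle_level < stroma_level <= 1")
        if self.n_follicles < 1:
            raise ValueError("PhantomSpec: n_follicles must be >= 1")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError("PhantomSpec: invalid radius_range")
        if self.speckle_looks < 0:
            raise ValueError("PhantomSpec: speckle_looks must be >= 0 (0 disables)")
        if not (0.0 <= self.inhomogeneity_amp < 1.0):
            raise ValueError("PhantomSpec: inhomogeneity_amp must be in [0, 1)")
        if self.ovary is None:
            # (center_row, center_col, semi-axis along cols, along rows, angle)
            h, w = self.height, self.width
            object.__setattr__(self, "ovary", (h / 2, w / 2, 0.47 * w, 0.44 * h, 0.0))


#: Named parameter presets.  ``dark_regime`` emulates globally dark scans
#: where follicle and wall intensities nearly merge; ``light_regime``
#: emulates bright scans with well-lit walls; ``clean`` disables every
#: degradation (exact three-level render).
PRESETS: dict[str, dict] = {
    "dark_regime": dict(
        follicle_level=0.10, stroma_level=0.50, background_level=0.45,
        boundary_softness=1.5, speckle_looks=4.0, inhomogeneity_amp=0.20,
    ),
    "light_regime": dict(
        follicle_level=0.18, stroma_level=0.75, background_level=0.70,
        boundary_softness=1.0, speckle_looks=8.0, inhomogeneity_amp=0.15,
    ),
    "clean": dict(
        follicle_level=0.10, stroma_level=0.50, background_level=0.45,
        boundary_softness=0.0, speckle_looks=0.0, inhomogeneity_amp=0.0,
    ),
}


def apply_preset(preset: str, **overrides) -> PhantomSpec:
    """Build a spec from a named preset plus keyword overrides."""
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return PhantomSpec(**{**PRESETS[preset], **overrides})


def _ellipse_mask(h, w, cr, cc, a, b, theta) -> np.ndarray:
    rr, cc_grid = np.mgrid[0:h, 0:w]
    dy = rr - cr
    dx = cc_grid - cc
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_follicles(spec: PhantomSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping follicle ellipses inside the ovary.

    Sizes are drawn up front and placed largest-first, which keeps dense
    polycystic scenes (>= 12 follicles) placeable without overlap.
    """
    ocr, occ, oa, ob, otheta = spec.ovary
    lo, hi = spec.radius_range
    sizes = sorted(
        (rng.uniform(lo, hi, size=2) for _ in range(spec.n_follicles)),
        key=lambda ab: -(ab[0] * ab[1]),
    )
    placed: list[tuple[float, float, float, float, float]] = []
    for i in range(spec.n_follicles):
        a, b = sizes[i]
        for _ in range(_MAX_ATTEMPTS_PER_FOLLICLE):
            theta = rng.uniform(0, np.pi)
            r = max(a, b)
            # conservative containment: center inside the ovary shrunk by r
            if oa - r <= 1 or ob - r <= 1:
                continue
            cr = ocr + rng.uniform(-1, 1) * (ob - r - 1)
            cc = occ + rng.uniform(-1, 1) * (oa - r - 1)
            du = (cc - occ) * np.cos(otheta) + (cr - ocr) * np.sin(otheta)
            dv = -(cc - occ) * np.sin(otheta) + (cr - ocr) * np.cos(otheta)
            if (du / (oa - r)) ** 2 + (dv / (ob - r)) ** 2 > 1.0:
                continue
            if not spec.allow_touching and any(
                np.hypot(cr - pr, cc - pc) <= r + max(pa, pb) + 1
                for pr, pc, pa, pb, _ in placed
            ):
                continue
            placed.append((cr, cc, a, b, theta))
            break
        else:
            raise PlacementError(
                f"could not place follicle {i + 1}/{spec.n_follicles}; "
                "try fewer or smaller follicles"
            )
    return placed


def _bias_field(shape, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative bias 1 + amp * f, with f zero-mean, |f| <= 1."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    f = np.zeros(shape, dtype=np.float64)
    for _ in range(3):
        fr = rng.uniform(0.5, 2.0)
        fc = rng.uniform(0.5, 2.0)
        phase = rng.uniform(0, 2 * np.pi)
        weight = rng.uniform(0.3, 1.0)
        f += weight * np.cos(2 * np.pi * (fr * rr / h + fc * cc / w) + phase)
    f -= f.mean()
    peak = np.abs(f).max()
    if peak > 0:
        f /= peak
    return 1.0 + amp * f


def generate(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom: (8-bit image, boolean ground-truth mask).

    The mask is the exact union of follicle ellipses before any blur or
    noise.  Identical spec (including seed) gives bit-identical outputs.
    """
    place_ss, noise_ss = np.random.SeedSequence(spec.seed).spawn(2)
    place_rng = np.random.default_rng(place_ss)
    if spec.noise_seed is not None:
        noise_ss = np.random.SeedSequence(spec.noise_seed)
    noise_rng = np.random.default_rng(noise_ss)
    h, w = spec.height, spec.width

    follicles = _place_follicles(spec, place_rng)

    clean = np.full((h, w), spec.background_level, dtype=np.float64)
    clean[_ellipse_mask(h, w, *spec.ovary)] = spec.stroma_level
    mask = np.zeros((h, w), dtype=bool)
    for cr, cc, a, b, theta in follicles:
        fm = _ellipse_mask(h, w, cr, cc, a, b, theta)
        mask |= fm
        clean[fm] = spec.follicle_level

    img = clean
    if spec.boundary_softness > 0:
        img = ndimage.gaussian_filter(img, spec.boundary_softness)
    if spec.inhomogeneity_amp > 0:
        img = img * _bias_field((h, w), spec.inhomogeneity_amp, noise_rng)
    if spec.speckle_looks > 0:
        looks = spec.speckle_looks
        img = img * noise_rng.gamma(shape=looks, scale=1.0 / looks, size=(h, w))
    img = np.clip(img, 0.0, 1.0)
    return np.rint(255.0 * img).astype(np.uint8), mask


def _suite_specs(n: int, base_spec: PhantomSpec, seed: int) -> list[PhantomSpec]:
    """Per-image specs with jittered follicle counts, one substream each.

    The follicle count is jittered uniformly on {base-2, ..., base+2}
    (clipped to >= 1) to emulate inter-patient variation.
    """
    if n < 1:
        raise ValueError("generate_suite: n must be >= 1")
    specs = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        jitter = int(rng.integers(-2, 3))
        child_seed = int(rng.integers(2**31))
        specs.append(
            replace(base_spec, n_follicles=max(1, base_spec.n_follicles + jitter), seed=child_seed)
        )
    return specs


def generate_suite(
    n: int, base_spec: PhantomSpec | None = None, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generate ``n`` phantoms from seed-derived substreams (deterministic)."""
    base_spec = base_spec or PhantomSpec()
    return [generate(s) for s in _suite_specs(n, base_spec, seed)]
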