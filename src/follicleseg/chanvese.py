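"""Chan-Vese active contour without edges.

The two-phase piecewise-constant energy of a contour C with region means
c1 (inside) and c2 (outside) over an image I on domain Omega is

    E(c1, c2, C) = mu * length(C) + nu * area(inside C)
                   + lambda1 * int_inside  (I - c1)^2
                   + lambda2 * int_outside (I - c2)^2 ,

with mu, nu >= 0 and lambda1, lambda2 > 0.  The contour is carried
implicitly by a level-set field phi (inside = {phi > 0}, contour =
{phi = 0}) and evolved by explicit gradient descent

    d phi / dt = delta_eps(phi) * [ mu * kappa(phi) - nu
                                    - lambda1 (I - c1)^2
                                    + lambda2 (I - c2)^2 ],

where kappa = div(grad phi / |grad phi|) is the contour curvature and
H_eps(z) = (1/2)(1 + (2/pi) arctan(z/eps)), delta_eps = H_eps', are the
smoothed Heaviside/Dirac pair.  Region means are recomputed from H_eps at
every step.  No image gradient enters the model, which is what makes it
usable on speckled ultrasound where follicle walls have weak edges.

The hybrid method seeds phi with the signed distance to the multilevel-Otsu
foreground mask; the classical baseline starts from a rectangle inset 5%
from the frame and shrinks inward onto dark structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .otsu import histogram, multilevel_otsu, otsu_mask
from .preprocess import preprocess

logger = logging.getLogger("follicleseg.chanvese")

__all__ = [
    "CVParams",
    "LevelSetState",
    "DegenerateInitError",
    "DegenerateRegionError",
    "NumericalFailureError",
    "init_from_mask",
    "init_classical",
    "region_means",
    "energy_value",
    "evolve",
    "segment",
]

_GRAD_FLOOR = 1e-8


class DegenerateInitError(ValueError):
    """Initial mask is empty or fills the whole frame."""


class DegenerateRegionError(ValueError):
    """One of the two phases carries zero Heaviside weight."""


class NumericalFailureError(FloatingPointError):
    """Non-finite values appeared during the evolution."""

    def __init__(self, iteration: int):
        super().__init__(f"non-finite level-set values at iteration {iteration}")
        self.iteration = iteration


@dataclass
class CVParams:
    """Evolution parameters.

    Intensities live on [0, 1] and lengths on the pixel grid, so the
    defaults are the canonical ones for this functional: a mild length
    penalty, no area (balloon) force, symmetric fidelity weights, a
    one-pixel Heaviside width, and periodic signed-distance
    reinitialization.  ``n_iter`` defaults to 500 fixed steps with no
    early exit.
    """

    mu: float = 0.2
    nu: float = 0.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    epsilon: float = 1.0
    dt: float = 0.5
    n_iter: int = 500
    reinit_every: int = 50
    early_exit_tol: float = 0.0  # > 0 enables stopping when the mask is static

    def __post_init__(self):
        if self.mu < 0 or self.nu < 0:
            raise ValueError("CVParams: mu and nu must be >= 0")
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("CVParams: lambda1 and lambda2 must be > 0")
        if self.epsilon <= 0 or self.dt <= 0:
            raise ValueError("CVParams: epsilon and dt must be > 0")
        if self.n_iter < 1:
            raise ValueError("CVParams: n_iter must be >= 1")
        if self.reinit_every < 0:
            raise ValueError("CVParams: reinit_every must be >= 0 (0 disables)")


@dataclass
class LevelSetState:
    """Final level-set field with region means and the energy trajectory."""

    phi: np.ndarray
    c1: float
    c2: float
    energy: float
    energy_history: np.ndarray = field(repr=False, default=None)
    n_iter: int = 0

    @property
    def mask(self) -> np.ndarray:
        """Positive phase {phi > 0}."""
        return self.phi > 0


def _heaviside(z: np.ndarray, eps: float) -> np.ndarray:
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(z / eps))


def _dirac(z: np.ndarray, eps: float) -> np.ndarray:
    return (eps / np.pi) / (eps * eps + z * z)


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    # Distance to the True/False interface, taken to run half a pixel
    # outside the foreground pixels; positive inside.
    d_in = ndimage.distance_transform_edt(mask)
    d_out = ndimage.distance_transform_edt(~mask)
    return np.where(mask, d_in - 0.5, 0.5 - d_out)


def init_from_mask(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary, positive inside.

    The sign partition reproduces the mask exactly: (phi > 0) == mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any() or mask.all():
        raise DegenerateInitError("init_from_mask: mask must be non-empty and not full")
    return _signed_distance(mask)


def init_classical(shape: tuple[int, int], inset_frac: float = 0.05) -> np.ndarray:
    """Classical initialization: rectangle inset from each border.

    The positive phase starts just inside the frame and the contour shrinks
    inward onto interior structures.  The inset is clamped so at least one
    interior row/column survives even for degenerate fractions.
    """
    h, w = shape
    if h < 16 or w < 16:
        raise ValueError(f"init_classical: image too small {shape}, need >= 16 x 16")
    ir = min(int(round(inset_frac * h)), (h - 1) // 2)
    ic = min(int(round(inset_frac * w)), (w - 1) // 2)
    mask = np.zeros((h, w), dtype=bool)
    mask[ir : h - ir, ic : w - ic] = True
    return _signed_distance(mask)


def region_means(img: np.ndarray, phi: np.ndarray, epsilon: float = 1.0) -> tuple[float, float]:
    """Heaviside-weighted means inside (c1) and outside (c2) the contour.

    c1 = sum(I * H_eps(phi)) / sum(H_eps(phi)), c2 likewise with 1 - H_eps.
    """
    h = _heaviside(np.asarray(phi, dtype=np.float64), epsilon)
    w1 = h.sum()
    w2 = h.size - w1
    if w1 <= 0.0 or w2 <= 0.0:
        raise DegenerateRegionError("region_means: a phase has zero total weight")
    i = np.asarray(img, dtype=np.float64)
    return float((i * h).sum() / w1), float((i * (1.0 - h)).sum() / w2)


def _curvature(phi: np.ndarray) -> np.ndarray:
    gy, gx = np.gradient(phi)
    norm = np.maximum(np.sqrt(gx * gx + gy * gy), _GRAD_FLOOR)
    ny = gy / norm
    nx = gx / norm
    return np.gradient(ny, axis=0) + np.gradient(nx, axis=1)


def energy_value(img: np.ndarray, phi: np.ndarray, c1: float, c2: float, params: CVParams) -> float:
    """Smoothed-Heaviside evaluation of the segmentation energy."""
    h = _heaviside(phi, params.epsilon)
    d = _dirac(phi, params.epsilon)
    gy, gx = np.gradient(phi)
    length = float((d * np.sqrt(gx * gx + gy * gy)).sum())
    area = float(h.sum())
    fid1 = float((((img - c1) ** 2) * h).sum())
    fid2 = float((((img - c2) ** 2) * (1.0 - h)).sum())
    return params.mu * length + params.nu * area + params.lambda1 * fid1 + params.lambda2 * fid2


def evolve(img: np.ndarray, phi0: np.ndarray, params: CVParams | None = None) -> LevelSetState:
    """Run the fixed-step level-set evolution.

    ``img`` must be a float image on [0, 1].  Exactly ``params.n_iter``
    explicit steps are taken (unless ``early_exit_tol`` is enabled), with
    the region means refreshed every step and optional signed-distance
    reinitialization every ``reinit_every`` steps.
    """
    params = params or CVParams()
    img = np.asarray(img, dtype=np.float64)
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("evolve: image must be scaled to [0, 1]")
    phi = np.array(phi0, dtype=np.float64, copy=True)
    if phi.shape != img.shape:
        raise ValueError(f"evolve: phi shape {phi.shape} != image shape {img.shape}")
    if not np.isfinite(phi).all():
        raise NumericalFailureError(0)

    history = np.empty(params.n_iter)
    c1 = c2 = float(img.mean())
    n_done = 0
    for it in range(params.n_iter):
        c1, c2 = region_means(img, phi, params.epsilon)
        force = (
            params.mu * _curvature(phi)
            - params.nu
            - params.lambda1 * (img - c1) ** 2
            + params.lambda2 * (img - c2) ** 2
        )
        prev_mask = phi > 0
        phi += params.dt * _dirac(phi, params.epsilon) * force
        if not np.isfinite(phi).all():
            raise NumericalFailureError(it)
        if params.reinit_every and (it + 1) % params.reinit_every == 0:
            pos = phi > 0
            if pos.any() and not pos.all():
                phi = _signed_distance(pos)
        history[it] = energy_value(img, phi, c1, c2, params)
        logger.debug("iter %d: energy %.6g", it, history[it])
        n_done = it + 1
        if params.early_exit_tol > 0:
            changed = np.count_nonzero((phi > 0) != prev_mask)
            if changed <= params.early_exit_tol * phi.size and it > 0:
                break

    c1, c2 = region_means(img, phi, params.epsilon)
    return LevelSetState(
        phi=phi,
        c1=c1,
        c2=c2,
        energy=energy_value(img, phi, c1, c2, params),
        energy_history=history[:n_done],
        n_iter=n_done,
    )


def segment(
    img: np.ndarray,
    mode: str = "hybrid",
    params: CVParams | None = None,
    *,
    preprocessed: bool = False,
    otsu_k: int = 4,
    fg_classes: tuple[int, ...] = (0,),
    fg_phase: str = "darker",
    preprocess_kwargs: dict | None = None,
    return_state: bool = False,
):
    """Segment follicles with either arm of the study design.

    ``mode='classical'`` starts the contour from an inset rectangle;
    ``mode='hybrid'`` seeds it with the darkest-class multilevel-Otsu mask
    of the (already enhanced) image.  Input is 8-bit; set
    ``preprocessed=True`` when the enhancement chain has been applied
    upstream.  The returned foreground is the phase with the darker mean
    (``fg_phase='brighter'`` flips this for inverted-contrast material), so
    the output means "follicle" regardless of any sign drift in phi.
    """
    if mode not in ("classical", "hybrid"):
        raise ValueError(f"segment: unknown mode {mode!r}")
    if fg_phase not in ("darker", "brighter"):
        raise ValueError(f"segment: fg_phase must be 'darker' or 'brighter', got {fg_phase!r}")
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise ValueError("segment: expected an 8-bit image")
    if not preprocessed:
        img = preprocess(img, **(preprocess_kwargs or {}))

    if mode == "classical":
        phi0 = init_classical(img.shape)
    else:
        hist = histogram(img)
        occupied = int(np.count_nonzero(hist))
        k = min(otsu_k, occupied - 1)
        if k < 1:
            raise DegenerateInitError("segment: constant image, no Otsu seed possible")
        fg = tuple(c for c in fg_classes if c <= k)
        ts = multilevel_otsu(hist, k=k)
        seed = otsu_mask(img, ts, fg_classes=fg or (0,))
        phi0 = init_from_mask(seed)

    state = evolve(img / 255.0, phi0, params)
    darker_inside = state.c1 <= state.c2
    want_inside = darker_inside if fg_phase == "darker" else not darker_inside
    mask = state.phi > 0 if want_inside else state.phi < 0
    return (mask, state) if return_state else mask
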