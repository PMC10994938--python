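"""Synthetic fixture generator: brain-like phantoms and cine series.

Training and evaluation need high-resolution labels with plausible MR
statistics — smooth compartments, sharp boundaries, thin curvilinear
structures, several contrast profiles — without downloading anything.
The phantoms here are nested anti-aliased ellipse composites with
sinuous thin curves and mild texture, emitted in three contrast
profiles loosely analogous to T1-weighted, T2-weighted and FLAIR
appearance.  They are deterministic per seed and analytic enough to
serve as ground truth for masking and centroid checks; they are not
anatomy renders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import GrayImage
from .tracking_sim import MotionTrace, PhantomSpec, render_frame

__all__ = [
    "PhantomRecipe",
    "CineSeries",
    "gen_anatomy_phantom",
    "gen_label_set",
    "gen_cine",
]

CONTRAST_PROFILES = ("t1-like", "t2-like", "flair-like")

# per-profile base intensities (fraction of full range):
#                  outer ring, brain,  ventricle, lesion span
_PROFILE = {
    "t1-like":    (0.95, 0.55, 0.12, (0.3, 0.8)),
    "t2-like":    (0.25, 0.40, 0.95, (0.5, 0.9)),
    "flair-like": (0.35, 0.55, 0.10, (0.7, 0.95)),
}


@dataclass(frozen=True)
class PhantomRecipe:
    """Recipe for one deterministic brain-like phantom."""

    seed: int = 0
    matrix: int = 256
    n_ellipses: int = 8
    intensity_range: tuple[float, float] = (0.0, 4096.0)
    contrast: str = "t1-like"
    fine_structure_density: float = 1.0

    def __post_init__(self) -> None:
        if self.matrix < 32:
            raise ValueError("matrix must be >= 32")
        if self.contrast not in _PROFILE:
            raise ValueError(f"unknown contrast profile {self.contrast!r}")
        lo, hi = self.intensity_range
        if not (0 <= lo < hi <= 4096):
            raise ValueError("intensity range must lie within [0, 4096]")


def _ellipse_coverage(yy, xx, cy, cx, ry, rx, theta, px) -> np.ndarray:
    """Anti-aliased filled ellipse: ~1-pixel smooth edge."""
    c, s = np.cos(theta), np.sin(theta)
    u = (xx - cx) * c + (yy - cy) * s
    v = -(xx - cx) * s + (yy - cy) * c
    # signed distance approximation to the ellipse boundary
    q = np.sqrt((u / rx) ** 2 + (v / ry) ** 2)
    dist = (q - 1.0) * min(rx, ry)
    return np.clip(0.5 - dist / px, 0.0, 1.0)


def gen_anatomy_phantom(recipe: PhantomRecipe) -> GrayImage:
    """Render one phantom; bitwise deterministic for a given recipe."""
    rng = np.random.default_rng(recipe.seed)
    n = recipe.matrix
    px = 2.0 / n
    ax = np.linspace(-1, 1, n, endpoint=False) + 1.0 / n
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    ring_v, brain_v, vent_v, lesion_span = _PROFILE[recipe.contrast]

    img = np.zeros((n, n))
    # outer ring (skull analogue) and brain compartment
    outer = _ellipse_coverage(yy, xx, 0.0, 0.0, 0.88, 0.72, 0.0, px)
    inner = _ellipse_coverage(yy, xx, 0.0, 0.0, 0.80, 0.64, 0.0, px)
    img += ring_v * (outer - inner)
    img += brain_v * inner
    # paired ventricle analogues
    for sx in (-1, 1):
        vent = _ellipse_coverage(yy, xx, -0.08, sx * 0.14, 0.28, 0.09,
                                 sx * 0.25, px)
        img += (vent_v - brain_v) * vent * inner
    # random internal ellipses (lesion / structure analogues)
    for _ in range(recipe.n_ellipses):
        cy, cx = rng.uniform(-0.45, 0.45, 2)
        ry, rx = rng.uniform(0.03, 0.18, 2)
        th = rng.uniform(0, np.pi)
        val = rng.uniform(*lesion_span) - brain_v
        img += val * _ellipse_coverage(yy, xx, cy, cx, ry, rx, th, px) * inner

    # thin curvilinear structures (sulci/vessel analogues): bilinear splats
    n_curves = max(1, int(round(6 * recipe.fine_structure_density)))
    for _ in range(n_curves):
        t = np.linspace(0, 1, 4 * n)
        y0, x0 = rng.uniform(-0.4, 0.4, 2)
        angle = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.3, 0.9)
        wav = rng.uniform(4, 9)
        amp = rng.uniform(0.02, 0.06)
        cy = y0 + length * t * np.sin(angle) + amp * np.sin(wav * np.pi * t)
        cx = x0 + length * t * np.cos(angle) + amp * np.cos(wav * np.pi * t)
        rows = (cy + 1) / px - 0.5
        cols = (cx + 1) / px - 0.5
        ok = (rows > 0) & (rows < n - 2) & (cols > 0) & (cols < n - 2)
        rows, cols = rows[ok], cols[ok]
        r0, c0 = np.floor(rows).astype(int), np.floor(cols).astype(int)
        fr, fc = rows - r0, cols - c0
        val = rng.uniform(-0.35, 0.35)
        splat = np.zeros_like(img)
        np.add.at(splat, (r0, c0), (1 - fr) * (1 - fc))
        np.add.at(splat, (r0 + 1, c0), fr * (1 - fc))
        np.add.at(splat, (r0, c0 + 1), (1 - fr) * fc)
        np.add.at(splat, (r0 + 1, c0 + 1), fr * fc)
        img += val * np.clip(splat / 4.0, 0, 1) * inner

    # mild smooth texture
    tex = gaussian_filter(rng.standard_normal((n, n)), 1.5)
    img += 0.02 * tex / max(tex.std(), 1e-12) * inner

    lo, hi = recipe.intensity_range
    img = np.clip(img, 0.0, None)
    img = lo + (hi - lo) * img / max(img.max(), 1e-12)
    return GrayImage(np.clip(img, lo, hi), (1.5625, 1.5625))


def gen_label_set(n: int, seed: int = 0, matrix: int = 256) -> list[GrayImage]:
    """n distinct phantoms, the three contrast profiles mixed uniformly."""
    labels = []
    for i in range(n):
        recipe = PhantomRecipe(seed=seed * 100003 + i, matrix=matrix,
                               n_ellipses=6 + (i % 5),
                               contrast=CONTRAST_PROFILES[i % 3])
        labels.append(gen_anatomy_phantom(recipe))
    return labels


@dataclass(frozen=True)
class CineSeries:
    """A rendered frame sequence with its timestamps."""

    t: np.ndarray
    frames: list

    def __len__(self) -> int:
        return len(self.frames)


def gen_cine(spec: PhantomSpec, trace: MotionTrace, seed: int = 0,
             matrix: int | None = None) -> CineSeries:
    """One rendered frame per trace sample (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    matrix = matrix or spec.hr_matrix
    frames = [render_frame(spec, float(x), matrix, rng) for x in trace.x]
    return CineSeries(trace.t.copy(), frames)
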