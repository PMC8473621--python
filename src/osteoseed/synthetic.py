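"""Ground-truthed synthetic inputs.

Two families of fixtures make every stage of the package testable
without any external data:

* synthetic radiographs — a parallel projection of the titanium lattice
  rendered as saturated (overexposed) metal on a dark background, with
  trabecular-bone speckle planted at a configurable base fraction plus
  radial/vertical gradients.  The planted label image is returned
  alongside the rendered grayscale, and the planted bone-pixel count is
  exact before noise, so threshold recovery can be asserted tightly.

* analytic flow states — uniform flow, linear shear, and a quiescent
  settling column on a rectangular box, for which shear rate and
  particle dynamics have closed forms.

Speckle is thresholded smoothed noise: Gaussian-filtered white noise is
rank-transformed to a uniform field and compared against the local
target fraction, then the selection is trimmed to the exact planted
count.  This mimics the patchy trabecular texture of real micrographs
while keeping the ground truth sharp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .flow import BoxDomain, FlowConfig, FlowSolver
from .geometry import LatticeModel
from .quant import BONE_PX, OTHER_PX, SCAFFOLD_PX, LabelImage
from .rheology import MarrowRheology

# rendered intensities: scaffold is driven past the 8-bit ceiling so
# that, like an overexposed metal implant, it stays > 250 under noise
_SCAFFOLD_LEVEL = 270.0
_BONE_LEVEL = 120.0
_BACKGROUND_LEVEL = 30.0


@dataclass(frozen=True)
class IngrowthModel:
    """Planted bone-ingrowth field for synthetic radiographs.

    The local bone fraction at normalized radius rho (0 centre, 1 edge)
    and normalized height zh (0 bottom, 1 top) is

        p = clip(base_fraction + radial_gradient * rho
                 + vertical_gradient * zh, 0, 1).

    Defaults emulate the observed ingrowth pattern: about 30% of the
    void filled in the middle, over 50% at the sides, slightly less
    toward the top.
    """

    base_fraction: float = 0.32
    radial_gradient: float = 0.22
    vertical_gradient: float = -0.04
    speckle_scale: float = 3.0     # px, smoothing length of the texture
    noise_sigma: float = 0.0       # grayscale noise after rendering
    seed: int = 0


def render_radiograph(lattice: LatticeModel, ingrowth: IngrowthModel,
                      size_px: int = 256, margin_mm: float = 0.4):
    """Project the lattice and plant bone speckle; returns (image, truth).

    ``image`` is the noisy uint8 radiograph, ``truth`` the pre-noise
    :class:`LabelImage`.  Scaffold pixels are those whose projection ray
    (along y) meets metal; bone pixels are drawn among the remaining
    pixels so their total count equals ``round(sum(p))`` exactly.
    """
    spec = lattice.spec
    rt = spec.top_diameter / 2.0
    h = spec.height
    width = 2 * rt + 2 * margin_mm
    height = h + 2 * margin_mm
    px = max(width, height) / size_px
    n_cols = int(round(width / px))
    n_rows = int(round(height / px))
    if spec.n_sublayers > 0 and px > spec.beam_diameter / 2.0:
        raise ValueError("image too small to resolve the beams")
    xs = -width / 2.0 + (np.arange(n_cols) + 0.5) * px
    zs = height - margin_mm - (np.arange(n_rows) + 0.5) * px  # row 0 at top
    ys = np.linspace(-rt, rt, max(int(2 * rt / (spec.beam_diameter / 4.0)), 8))
    X, Z = np.meshgrid(xs, zs, indexing="xy")      # (n_rows, n_cols)
    proj = np.zeros(X.shape, bool)
    pts = np.empty(X.shape + (3,))
    pts[..., 0] = X
    pts[..., 2] = Z
    for y in ys:
        pts[..., 1] = y
        proj |= lattice.contains(pts)

    rng = np.random.default_rng(ingrowth.seed)
    rho = np.clip(np.abs(X) / rt, 0.0, 1.0)
    zh = np.clip(Z / max(h, 1e-9), 0.0, 1.0)
    p = np.clip(ingrowth.base_fraction + ingrowth.radial_gradient * rho
                + ingrowth.vertical_gradient * zh, 0.0, 1.0)
    p = np.where(proj, 0.0, p)
    candidates = ~proj
    n_bone = int(round(float(p[candidates].sum())))
    noise = rng.standard_normal(X.shape)
    if ingrowth.speckle_scale > 0:
        noise = ndimage.gaussian_filter(noise, ingrowth.speckle_scale)
    # rank-transform to uniform so the local selection rate tracks p
    flat = noise[candidates]
    order = np.argsort(flat, kind="stable")
    uniform = np.empty_like(flat)
    uniform[order] = (np.arange(flat.size) + 0.5) / flat.size
    score = uniform - p[candidates]
    bone_flat = np.zeros(flat.size, bool)
    bone_flat[np.argsort(score, kind="stable")[:n_bone]] = True
    bone = np.zeros(X.shape, bool)
    bone[candidates] = bone_flat

    labels = np.full(X.shape, OTHER_PX, np.uint8)
    labels[bone] = BONE_PX
    labels[proj] = SCAFFOLD_PX
    clean = np.full(X.shape, _BACKGROUND_LEVEL)
    clean[bone] = _BONE_LEVEL
    clean[proj] = _SCAFFOLD_LEVEL
    noisy = clean
    if ingrowth.noise_sigma > 0:
        noisy = clean + rng.normal(0.0, ingrowth.noise_sigma, X.shape)
    image = np.clip(noisy, 0, 255).astype(np.uint8)
    truth = LabelImage(labels=labels, pixel_size=px)
    return image, truth


def make_flow_fixture(kind: str, nx: int = 16, nz: int = 24,
                      lx: float = 1e-3, lz: float = 1.5e-3,
                      speed: float = 1e-3, shear: float = 10.0,
                      rheo: MarrowRheology | None = None):
    """Analytic flow states on a box; returns (domain, state, solver).

    kind='uniform': u = speed everywhere (zero shear rate);
    kind='linear_shear': u = shear * z (constant shear rate);
    kind='settling_column': quiescent marrow column for settling tests.
    """
    rheo = rheo or MarrowRheology()
    domain = BoxDomain(nx, nz, lx=lx, lz=lz)
    cfg = FlowConfig(fill_duration=0.0, total_duration=1.0, gravity=(0, 0))
    solver = FlowSolver(domain, rheo, cfg)
    state = solver.initialize_state(alpha0=1.0)
    zc_u = (np.arange(nz) + 0.5) * domain.dz
    if kind == "uniform":
        state.u[:, :] = speed
    elif kind == "linear_shear":
        state.u[:, :] = shear * zc_u[None, :]
    elif kind == "settling_column":
        pass
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return domain, state, solver
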