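"""Seeded synthetic fixtures: LGE-like phantoms and mechanistic substrates.

Patient imaging cannot be shared, so this module generates the two kinds of
inputs the toolkit consumes, deterministically from (spec, seed):

* LGE-like grayscale phantoms with a myocardium mask and known ground-truth
  scar/fibrosis masks, for validating intensity segmentation.  Class
  intensities are drawn from truncated normal distributions (+-1.3 class SD)
  so that, without added noise, the SD-threshold bands recover the ground
  truth exactly.

* 2D tissue substrates reproducing the two reentry mechanisms seen in
  genotype-matched ARVC models: a channel ("isthmus") between two dense
  scar islands wrapped in diffuse fibrosis, and a band of diffuse fibrosis
  of varying width crossing the sheet.

All generators are pure functions of their spec (which embeds the seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tissue import TissueGrid, MonodomainConfig, NORMAL, FIBROSIS, SCAR

__all__ = [
    "PhantomSpec", "SubstrateSpec", "gen_lge_phantom",
    "gen_isthmus_substrate", "gen_fibrosis_band_substrate",
    "mechanism_config",
]


class FixtureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# LGE-like phantom

@dataclass(frozen=True)
class PhantomSpec:
    """Intensity phantom specification.

    Fractions are percentages of the myocardium mask.  Class mean ordering
    must be normal < fibrosis < scar; class SDs are the intrinsic intensity
    spread of each tissue class, and noise_sd adds global Gaussian noise on
    top (0 = noiseless phantom).
    """

    shape: tuple = (128, 128)
    scar_fraction: float = 5.0       # % of mask (dense scar, DS)
    fibrosis_fraction: float = 14.0  # % of mask (diffuse fibrosis, DF)
    mean_normal: float = 30.0
    mean_fibrosis: float = 41.0
    mean_scar: float = 55.0
    sd_normal: float = 5.0
    sd_fibrosis: float = 1.0
    sd_scar: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.scar_fraction < 0 or self.fibrosis_fraction < 0:
            raise FixtureError("fractions must be >= 0")
        if self.scar_fraction + self.fibrosis_fraction > 100:
            raise FixtureError("fractions sum above 100%")
        if not (self.mean_normal < self.mean_fibrosis < self.mean_scar):
            raise FixtureError("class means must be ordered normal < fibrosis < scar")


def _truncnorm(rng, mean, sd, size, clip=1.3):
    x = rng.standard_normal(size)
    # resample the tails so values stay within +-clip SD
    bad = np.abs(x) > clip
    while bad.any():
        x[bad] = rng.standard_normal(bad.sum())
        bad = np.abs(x) > clip
    return mean + sd * x


def _grow_blob(rng, mask: np.ndarray, n_pixels: int, forbidden: np.ndarray,
               seed_point=None) -> np.ndarray:
    """Contiguous blob of exactly n_pixels inside mask, grown by a seeded
    stochastic flood (random-walk-weighted region growth)."""
    ny, nx = mask.shape
    ok = mask & ~forbidden
    ys, xs = np.nonzero(ok)
    if len(ys) < n_pixels:
        raise FixtureError("not enough free pixels for requested fraction")
    if seed_point is None:
        k = rng.integers(len(ys))
        seed_point = (ys[k], xs[k])
    blob = np.zeros_like(mask)
    frontier = [seed_point]
    blob[seed_point] = True
    count = 1
    while count < n_pixels:
        if not frontier:
            # restart from a random free pixel adjacent-agnostic (disjoint
            # pocket); keeps the pixel count exact
            free = ok & ~blob
            fy, fx = np.nonzero(free)
            if len(fy) == 0:
                raise FixtureError("ran out of pixels while growing blob")
            k = rng.integers(len(fy))
            frontier = [(fy[k], fx[k])]
            blob[frontier[0]] = True
            count += 1
            continue
        k = rng.integers(len(frontier))
        cy, cx = frontier[k]
        nbrs = [(cy + 1, cx), (cy - 1, cx), (cy, cx + 1), (cy, cx - 1)]
        rng.shuffle(nbrs)
        grown = False
        for (jy, jx) in nbrs:
            if 0 <= jy < ny and 0 <= jx < nx and ok[jy, jx] and \
                    not blob[jy, jx]:
                blob[jy, jx] = True
                frontier.append((jy, jx))
                count += 1
                grown = True
                break
        if not grown:
            frontier.pop(k)
    return blob


def gen_lge_phantom(spec: PhantomSpec):
    """Generate (image, myocardium_mask, truth) for an LGE-like phantom.

    truth is a dict with boolean 'scar' and 'fibrosis' masks whose pixel
    counts equal round(fraction/100 * mask size) exactly.
    """
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    mask = (((yy - cy) / (0.45 * ny)) ** 2 +
            ((xx - cx) / (0.45 * nx)) ** 2) <= 1.0
    n_mask = int(mask.sum())
    n_scar = int(round(spec.scar_fraction / 100.0 * n_mask))
    n_fib = int(round(spec.fibrosis_fraction / 100.0 * n_mask))

    scar = _grow_blob(rng, mask, n_scar, np.zeros_like(mask)) if n_scar else \
        np.zeros_like(mask)
    fib = _grow_blob(rng, mask, n_fib, scar) if n_fib else np.zeros_like(mask)

    img = np.zeros(spec.shape)
    normal = mask & ~scar & ~fib
    img[normal] = _truncnorm(rng, spec.mean_normal, spec.sd_normal,
                             int(normal.sum()))
    img[fib] = _truncnorm(rng, spec.mean_fibrosis, spec.sd_fibrosis,
                          int(fib.sum()))
    img[scar] = _truncnorm(rng, spec.mean_scar, spec.sd_scar,
                           int(scar.sum()))
    if spec.noise_sd > 0:
        img[mask] += rng.normal(0.0, spec.noise_sd, n_mask)
    return img, mask, {"scar": scar, "fibrosis": fib}


# ---------------------------------------------------------------------------
# Mechanistic tissue substrates

@dataclass(frozen=True)
class SubstrateSpec:
    """2D substrate geometry.

    Default sheet: 5 x 5 cm at 500 um spacing (100 x 100 nodes), fibers
    horizontal.  Isthmus geometry: two dense-scar islands in the mid band
    with a conducting channel of ``isthmus_width_mm`` between them, wrapped
    in a diffuse-fibrosis halo of ``halo_mm``.  Band geometry: a horizontal
    fibrosis band whose width varies smoothly from band_min_mm at the edges
    to band_max_mm in the sheet center.
    """

    shape: tuple = (100, 100)
    dx: float = 500.0             # um
    fiber_angle: float = 0.0      # radians
    # isthmus geometry
    island_half_mm: tuple = (9.0, 6.0)   # half-height, half-width of islands
    isthmus_width_mm: float = 4.0
    halo_mm: float = 2.0
    channel_wall_mm: float = 1.0   # fibrotic lining of the channel walls
    cap_mm: float = 0.0            # optional fibrotic cap on the channel exit
    flank_mm: float = 0.0          # optional fibrotic patch, left corridor
    center_row_frac: float = 0.5
    center_col_frac: float = 0.46  # horizontal placement of the complex
    corner_mm: float = 16.0        # scar quarter-discs at the sheet corners
                                   # (confine the peri-scar circuit)
    plug_mm: float = 5.0           # radius of the fibrotic plug sealing the
                                   # bottom-left track section (0 = off)
    plug_pos: tuple = (0.74, 0.20)  # (row_frac, col_frac) of the plug center
    # fibrosis-band geometry
    band_min_mm: float = 2.0
    band_max_mm: float = 10.0
    band_row_frac: float = 0.5
    band_extent_frac: float = 1.0   # band spans x in [0, extent)
    seed: int = 0

    def __post_init__(self):
        if self.isthmus_width_mm <= 0:
            raise FixtureError("isthmus width must be > 0")


def _finish_grid(labels: np.ndarray, spec: SubstrateSpec) -> TissueGrid:
    fa = np.full(spec.shape, spec.fiber_angle)
    g = TissueGrid(labels, fa, spec.dx)
    g.assign_regions()
    g.default_pacing_sites()
    return g


def gen_isthmus_substrate(spec: SubstrateSpec = SubstrateSpec()) -> TissueGrid:
    """Two dense scar islands with fibrosis halos and a conducting channel
    (isthmus) between them.

    The channel core conducts (normal myocardium lined by a thin fibrotic
    wall), while a patch of diffuse fibrosis seals the channel's top exit.
    This reproduces the protected-isthmus architecture that supports
    figure-of-eight reentry: a premature wavefront blocks at the
    long-refractory cap, side wavefronts travel around the scars, and the
    recovered exit is re-invaded retrogradely.
    """
    ny, nx = spec.shape
    labels = np.full(spec.shape, NORMAL, dtype=np.int8)
    px_mm = 1000.0 / spec.dx   # pixels per mm
    hy = spec.island_half_mm[0] * px_mm
    hx = spec.island_half_mm[1] * px_mm
    gap = spec.isthmus_width_mm * px_mm
    halo = spec.halo_mm * px_mm
    wall = spec.channel_wall_mm * px_mm
    cap = spec.cap_mm * px_mm
    cy = spec.center_row_frac * ny
    cx = spec.center_col_frac * (nx - 1)
    yy, xx = np.mgrid[0:ny, 0:nx]
    left_cx = cx - gap / 2.0 - hx
    right_cx = cx + gap / 2.0 + hx
    # islands may clip at the sheet edge (scar reaching the border), but the
    # channel itself must lie inside the sheet
    if gap <= 0 or gap <= 2 * wall or cx - gap / 2.0 < 1 or \
            cx + gap / 2.0 > nx - 2 or hy + halo >= ny / 2.0:
        raise FixtureError("isthmus geometry overflows the sheet")

    def ellipse(cy_, cx_, ry, rx):
        return (((yy - cy_) / ry) ** 2 + ((xx - cx_) / rx) ** 2) <= 1.0

    scar = ellipse(cy, left_cx, hy, hx) | ellipse(cy, right_cx, hy, hx)
    if spec.halo_mm > 0:
        fib = (ellipse(cy, left_cx, hy + halo, hx + halo) |
               ellipse(cy, right_cx, hy + halo, hx + halo)) & ~scar
    else:
        fib = np.zeros_like(scar)
    # conducting channel core between the islands
    core = (np.abs(xx - cx) <= gap / 2.0 - wall) & \
        (np.abs(yy - cy) <= hy + 0.5 * halo)
    fib &= ~core
    # fibrotic cap over the channel's top (apical) exit
    if spec.cap_mm > 0:
        cap_cy = cy - hy - cap / 2.0
        cap_mask = ellipse(cap_cy, cx, cap / 2.0 + halo,
                           gap / 2.0 + hx * 0.7)
        fib |= cap_mask & ~scar
    # fibrotic patch sealing the left lateral corridor: the premature wave
    # must take the long route (channel / right corridor, across the top)
    # and re-enter the corridor from above once the patch recovers
    if spec.flank_mm > 0:
        flank = spec.flank_mm * px_mm
        corr_cx = (left_cx - hx) / 2.0   # center of the left corridor
        corr_rx = (left_cx - hx) / 2.0 + halo
        fmask = ellipse(cy, corr_cx, flank / 2.0, corr_rx) & (xx <= left_cx)
        fib |= fmask & ~scar
    # fibrotic plug sealing one section of the peri-complex track: the
    # short-path wavefront meets it refractory (unidirectional block), the
    # long-path wavefront arrives after it recovers
    if spec.plug_mm > 0:
        pr = spec.plug_mm * px_mm
        pcy = spec.plug_pos[0] * (ny - 1)
        pcx = spec.plug_pos[1] * (nx - 1)
        fib |= (((yy - pcy) ** 2 + (xx - pcx) ** 2) <= pr * pr) & ~scar
    # optional corner scars confining the peri-complex circuit to an
    # annular track (anatomical boundaries of the clinical VT circuit)
    if spec.corner_mm > 0:
        r = spec.corner_mm * px_mm
        for ccy, ccx in ((0, 0), (0, nx - 1), (ny - 1, 0), (ny - 1, nx - 1)):
            scar |= ((yy - ccy) ** 2 + (xx - ccx) ** 2) <= r * r
    labels[fib] = FIBROSIS
    labels[scar] = SCAR
    return _finish_grid(labels, spec)


def gen_fibrosis_band_substrate(spec: SubstrateSpec = SubstrateSpec()
                                ) -> TissueGrid:
    """Horizontal diffuse-fibrosis band of smoothly varying width.

    The band runs from the left (anterior) edge and ends free at
    ``band_extent_frac`` of the sheet width; its width rises from
    band_min_mm at the anchored edge to band_max_mm and back, so a wavefront
    from below is delayed most in the wide mid-portion while conduction
    around the free end stays available.
    """
    ny, nx = spec.shape
    labels = np.full(spec.shape, NORMAL, dtype=np.int8)
    px_mm = 1000.0 / spec.dx
    cy = spec.band_row_frac * ny
    wmin = spec.band_min_mm * px_mm
    wmax = spec.band_max_mm * px_mm
    n_ext = int(round(spec.band_extent_frac * nx))
    for ix in range(n_ext):
        u = ix / max(1.0, n_ext - 1.0)
        w = wmin + (wmax - wmin) * 0.5 * (1.0 - math.cos(2.0 * math.pi * u))
        half = w / 2.0
        y0 = int(math.ceil(cy - half))
        y1 = int(math.floor(cy + half))
        labels[max(0, y0):min(ny, y1 + 1), ix] = FIBROSIS
    if spec.corner_mm > 0:
        yy, xx = np.mgrid[0:ny, 0:nx]
        r = spec.corner_mm * px_mm
        for ccy, ccx in ((0, 0), (0, nx - 1), (ny - 1, 0), (ny - 1, nx - 1)):
            labels[((yy - ccy) ** 2 + (xx - ccx) ** 2) <= r * r] = SCAR
    return _finish_grid(labels, spec)


def band_area_fraction(spec: SubstrateSpec) -> float:
    """Analytic area fraction of the fibrosis band (continuous limit)."""
    ny, nx = spec.shape
    mean_w_mm = spec.band_min_mm + (spec.band_max_mm - spec.band_min_mm) * 0.5
    sheet_h_mm = ny * spec.dx / 1000.0
    return spec.band_extent_frac * mean_w_mm / sheet_h_mm


def mechanism_config(dt: float = 0.05,
                     fibrosis_sigma_scale: float = 0.25) -> MonodomainConfig:
    """Solver configuration used for the mechanistic substrates: default
    conductivities, and reduced conductivity inside diffuse fibrosis (the
    isthmus of low conductivity)."""
    return MonodomainConfig(dt=dt, fibrosis_sigma_scale=fibrosis_sigma_scale)
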