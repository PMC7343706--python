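"""Forward-model OCT phantom: polar B-scans with known tissue maps.

The simulator renders annular three-tissue plaque geometries around a
smooth lumen, following the same single-scattering signal model the fitter
inverts: per A-line, the expected intensity inside tissue is

    I(r) = I0(tissue) * T(r) * s(r) * exp(-tau(r)),

with ``tau`` the attenuation accumulated from the tissue entry point across
any tissue transitions along the ray, ``T`` the confocal PSF and ``s`` the
roll-off (see :mod:`octplaq.optics`).  On top of the deterministic decay it
adds

* fully developed speckle: multiplicative unit-mean gamma noise with shape
  ``L`` ("looks"; L -> infinity is the noiseless limit),
* a per-tissue multiplicative texture field ``1 + amp * smoothed noise``
  whose correlation length and amplitude differ between tissue types,
* a bright 2-px border ring on calcified regions, emulating the sharply
  delineated internal/external calcification boundaries seen on OCT,
* a guide-wire shadow sector in which the signal beyond the lumen boundary
  collapses to the noise floor.

Everything is driven by a single seed, so a phantom is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_oct import (BACKGROUND, CALCIFIED, FIBROUS, LABEL_NAMES, LIPID,
                     PolarImage, TissueLabelMap)
from .optics import SystemParams, confocal_psf, rolloff

__all__ = [
    "TissueOpticalParams",
    "SystemParams",
    "PhantomSpec",
    "DEFAULT_TISSUE_PARAMS",
    "render_aline",
    "generate_phantom",
    "phantom_suite_specs",
]


@dataclass
class TissueOpticalParams:
    """Optical and textural parameters of one tissue class.

    mu_t : attenuation coefficient, mm^-1 (> 0)
    i0_scale : backscatter intercept on the linear intensity scale (> 0)
    texture_corr_len : correlation length of the multiplicative texture
        field, pixels (>= 0; 0 means white noise)
    texture_amp : texture modulation amplitude, dimensionless in [0, 1)
    """

    mu_t: float
    i0_scale: float
    texture_corr_len: float = 0.0
    texture_amp: float = 0.0

    def __post_init__(self) -> None:
        if not self.mu_t > 0:
            raise ValueError("mu_t must be positive")
        if not self.i0_scale > 0:
            raise ValueError("i0_scale must be positive")
        if self.texture_corr_len < 0:
            raise ValueError("texture_corr_len must be non-negative")
        if not 0 <= self.texture_amp < 1:
            raise ValueError("texture_amp must lie in [0, 1)")


#: Default tissue parameterisation of the three plaque components.  Lipid
#: attenuates strongly and backscatters brightly at the surface; calcified
#: tissue backscatters weakly but is texturally busy with sharp borders;
#: fibrous tissue is bright, homogeneous and moderately attenuating.
DEFAULT_TISSUE_PARAMS: dict[int, TissueOpticalParams] = {
    FIBROUS: TissueOpticalParams(mu_t=2.0, i0_scale=16000.0,
                                 texture_corr_len=2.0, texture_amp=0.12),
    CALCIFIED: TissueOpticalParams(mu_t=3.2, i0_scale=9000.0,
                                   texture_corr_len=1.0, texture_amp=0.45),
    LIPID: TissueOpticalParams(mu_t=6.5, i0_scale=20000.0,
                               texture_corr_len=3.0, texture_amp=0.06),
}


@dataclass
class PhantomSpec:
    """Geometry and noise description of one phantom frame.

    The lumen radius varies smoothly with angle theta as

        R(theta) = lumen_radius + sum_k amp_k * cos(k * theta + phase_k)

    and ``tissue_sectors`` assigns one tissue label and radial thickness to
    each angular sector; the sectors must tile [0, 360) without gaps or
    overlap.  Thickness must be >= 1 mm so a 1-mm analysis band from the
    lumen stays inside tissue.
    """

    lumen_radius: float = 0.8  # mm
    lumen_harmonics: tuple = ()  # (order, amplitude_mm, phase_rad) triples
    tissue_sectors: tuple = ((0.0, 360.0, FIBROUS, 1.2),)
    guidewire_sector: tuple | None = None  # (start_deg, end_deg)
    speckle_looks: float | None = 4
    seed: int = 0
    n_depth: int = 220
    noise_floor: float = 20.0

    def __post_init__(self) -> None:
        sectors = sorted(self.tissue_sectors, key=lambda s: s[0])
        if not sectors:
            raise ValueError("at least one tissue sector is required")
        if sectors[0][0] != 0.0 or sectors[-1][1] != 360.0:
            raise ValueError("tissue sectors must cover [0, 360) exactly")
        for (s0, e0, *_), (s1, _, *_) in zip(sectors, sectors[1:]):
            if e0 != s1:
                raise ValueError(
                    f"tissue sectors leave a gap or overlap at {e0} vs {s1} deg")
        for s0, e0, lab, thick in sectors:
            if e0 <= s0:
                raise ValueError("sector end must exceed its start")
            if lab not in LABEL_NAMES or lab == BACKGROUND:
                raise ValueError(f"unknown tissue label {lab!r}")
            if thick < 1.0:
                raise ValueError("sector thickness must be >= 1 mm")
        self.tissue_sectors = tuple(sectors)
        if self.speckle_looks is not None and not self.speckle_looks >= 1:
            raise ValueError("speckle_looks must be >= 1 (or None)")

    def lumen_radius_mm(self, theta_deg: np.ndarray) -> np.ndarray:
        th = np.deg2rad(np.asarray(theta_deg, dtype=np.float64))
        r = np.full(th.shape, float(self.lumen_radius))
        for order, amp, phase in self.lumen_harmonics:
            r += amp * np.cos(order * th + phase)
        return r


def _speckle(rng: np.random.Generator, shape, looks) -> np.ndarray:
    """Unit-mean multiplicative gamma speckle with shape `looks`."""
    if looks is None or np.isinf(looks):
        return np.ones(shape)
    return rng.gamma(shape=looks, scale=1.0 / looks, size=shape)


def render_aline(labels_along_ray, params_by_label: dict,
                 sys: SystemParams, L: float | None = 4,
                 rng: np.random.Generator | int | None = None,
                 noise_floor: float = 20.0) -> np.ndarray:
    """Render one A-line from a per-depth-pixel tissue label vector.

    Attenuation accumulates across tissue transitions along the ray and is
    measured from the tissue entry point, so the log-intensity slope inside
    a homogeneous segment equals ``-mu_t`` of that tissue exactly (noiseless
    mode, ``L=None``).  Background (lumen) pixels sit at the noise floor.
    """
    labels = np.asarray(labels_along_ray, dtype=int)
    unknown = set(np.unique(labels)) - {BACKGROUND} - set(params_by_label)
    if unknown:
        raise ValueError(f"unknown tissue label(s) in map: {sorted(unknown)}")
    rng = np.random.default_rng(rng)
    spacing = sys.axial_spacing
    r = np.arange(labels.size) * spacing
    mu = np.zeros(labels.size)
    i0 = np.full(labels.size, noise_floor)
    tissue = labels != BACKGROUND
    for lab, par in params_by_label.items():
        sel = labels == lab
        mu[sel] = par.mu_t
        i0[sel] = par.i0_scale
    # optical depth from the entry point; the entry pixel itself has tau=0
    tau = np.concatenate(([0.0], np.cumsum(mu * spacing)[:-1]))
    expected = np.where(
        tissue,
        i0 * confocal_psf(r, sys.z0, sys.zR) * rolloff(r, sys.zC, sys.zW)
        * np.exp(-tau),
        noise_floor)
    return expected * _speckle(rng, labels.shape, L)


def _sector_of(theta: float, sectors) -> tuple[int, float]:
    for s0, e0, lab, thick in sectors:
        if s0 <= theta < e0:
            return lab, thick
    return sectors[-1][2], sectors[-1][3]


def generate_phantom(spec: PhantomSpec, params_by_label: dict | None = None,
                     sys: SystemParams | None = None):
    """Render a full phantom frame.

    Returns ``(PolarImage, TissueLabelMap, boundary)`` sharing raster
    geometry; ``boundary[i]`` is the true lumen column index of A-line i.
    Intensities are rounded to integers on the 16-bit range, matching the
    on-disk representation, and identical seeds give identical output.
    """
    if params_by_label is None:
        params_by_label = DEFAULT_TISSUE_PARAMS
    if sys is None:
        sys = SystemParams()
    rng = np.random.default_rng(spec.seed)
    n_rows, n_cols = sys.n_alines, spec.n_depth
    theta = np.arange(n_rows) * (360.0 / n_rows)
    boundary = np.rint(spec.lumen_radius_mm(theta) / sys.axial_spacing
                       ).astype(int)
    if (boundary < 1).any() or (boundary >= n_cols).any():
        raise ValueError("lumen boundary leaves the raster")

    labels = np.zeros((n_rows, n_cols), dtype=np.uint8)
    cols = np.arange(n_cols)
    thick_px = {}
    for i in range(n_rows):
        lab, thick = _sector_of(theta[i], spec.tissue_sectors)
        t_px = int(round(thick / sys.axial_spacing))
        thick_px[i] = t_px
        band = (cols >= boundary[i]) & (cols < min(boundary[i] + t_px, n_cols))
        labels[i, band] = lab

    # deterministic expected intensity (vectorized over the raster)
    mu = np.zeros((n_rows, n_cols))
    i0 = np.full((n_rows, n_cols), spec.noise_floor)
    for lab, par in params_by_label.items():
        sel = labels == lab
        mu[sel] = par.mu_t
        i0[sel] = par.i0_scale
    present = set(np.unique(labels)) - {BACKGROUND}
    missing = present - set(params_by_label)
    if missing:
        raise ValueError(f"unknown tissue label(s) in map: {sorted(missing)}")
    dtau = mu * sys.axial_spacing
    tau = np.cumsum(dtau, axis=1) - dtau  # exclusive prefix: entry pixel = 0
    r = cols * sys.axial_spacing
    depth_gain = confocal_psf(r, sys.z0, sys.zR) * rolloff(r, sys.zC, sys.zW)
    tissue = labels != BACKGROUND
    expected = np.where(tissue, i0 * depth_gain[None, :] * np.exp(-tau),
                        spec.noise_floor)

    # per-tissue multiplicative texture fields (seam-continuous in angle)
    for lab in sorted(present):
        par = params_by_label[lab]
        if par.texture_amp <= 0:
            continue
        g = rng.standard_normal((n_rows, n_cols))
        if par.texture_corr_len > 0:
            g = gaussian_filter(g, sigma=par.texture_corr_len,
                                mode=("wrap", "nearest"))
            sd = g.std()
            if sd > 0:
                g /= sd
        fld = np.clip(1.0 + par.texture_amp * g, 0.05, None)
        sel = labels == lab
        expected[sel] *= fld[sel]

    # bright 2-px rings on the inner and outer calcified borders
    if CALCIFIED in present:
        ring = np.zeros((n_rows, n_cols), dtype=bool)
        for i in range(n_rows):
            if labels[i, boundary[i]] == CALCIFIED:
                lo = boundary[i]
                hi = min(boundary[i] + thick_px[i], n_cols)
                ring[i, lo:min(lo + 2, n_cols)] = True
                ring[i, max(hi - 2, lo):hi] = True
        expected[ring] *= 1.8

    # guide-wire shadow: signal beyond the lumen collapses to the floor
    if spec.guidewire_sector is not None:
        g0, g1 = spec.guidewire_sector
        shadow_rows = (theta >= g0) & (theta < g1)
        for i in np.flatnonzero(shadow_rows):
            expected[i, boundary[i]:] = spec.noise_floor

    img = expected * _speckle(rng, expected.shape, spec.speckle_looks)
    img = np.rint(np.clip(img, 0, 65535))
    return (PolarImage(img, axial_spacing=sys.axial_spacing),
            TissueLabelMap(labels), boundary)


def phantom_suite_specs(n_images: int = 50, n_patients: int = 10,
                        seed: int = 0, guidewire: bool = True):
    """Specs for a multi-patient phantom study suite.

    Images are grouped into synthetic "patients": frames of one patient
    share a base lumen geometry and sector layout with small frame-to-frame
    jitter, the way consecutive pullback frames of one specimen do.  Every
    frame contains all three tissue classes in randomized sector order and
    extent, plus (optionally) a ~20 deg guide-wire shadow at random angle.

    Returns a list of ``(PhantomSpec, patient_id)`` pairs.
    """
    if n_images % n_patients:
        raise ValueError("n_images must be a multiple of n_patients")
    master = np.random.default_rng(seed)
    per = n_images // n_patients
    out = []
    for p in range(n_patients):
        prng = np.random.default_rng(master.integers(2 ** 31))
        base_radius = prng.uniform(0.65, 0.85)
        base_phase = prng.uniform(0, 2 * np.pi, size=2)
        base_cuts = np.sort(prng.uniform(0, 360, size=3))
        order = prng.permutation([FIBROUS, CALCIFIED, LIPID])
        for f in range(per):
            cuts = (base_cuts + prng.uniform(-10, 10, size=3)) % 360
            cuts = np.sort(cuts)
            # enforce a minimal 40 deg sector extent
            for _ in range(20):
                ext = np.diff(np.concatenate((cuts, [cuts[0] + 360])))
                if ext.min() >= 40:
                    break
                cuts = np.sort(prng.uniform(0, 360, size=3))
            sectors = []
            edges = [0.0, *(c - cuts[0] for c in cuts[1:]), 360.0]
            rot = cuts[0]  # rotate so sector 0 starts at angle 0
            for k in range(3):
                thick = prng.uniform(1.1, 1.3)
                sectors.append((edges[k], edges[k + 1], int(order[k]), thick))
            gw = None
            if guidewire:
                g0 = prng.uniform(0, 340)
                gw = (g0, g0 + 20.0)
            spec = PhantomSpec(
                lumen_radius=base_radius + prng.uniform(-0.03, 0.03),
                lumen_harmonics=((1, prng.uniform(0.01, 0.04),
                                  base_phase[0] + np.deg2rad(rot)),
                                 (2, prng.uniform(0.005, 0.03),
                                  base_phase[1] + np.deg2rad(rot))),
                tissue_sectors=tuple(sectors),
                guidewire_sector=gw,
                speckle_looks=4,
                seed=int(prng.integers(2 ** 31)),
            )
            out.append((spec, p))
    return out
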