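"""ISO 25178-2 areal surface texture parameters.

Computed from a scale-limited surface (the roughness component left after
form removal and Gaussian filtration).  Valid points carry equal area
weight; invalid points are excluded from every sum with renormalisation —
never interpolated.  Heights are re-centred to zero mean before anything
else, so all parameters refer to the mean plane.

Parameter groups
----------------
height     Sa, Sq, Ssk, Sku, Sp, Sv, Sz                     [µm / –]
spatial    Sal, Str (autocorrelation, threshold s = 0.2), Std [µm / – / °]
hybrid     Sdq (RMS gradient, –), Sdr (developed area excess, %)
functional Smr (at c = 1 µm below mean plane, %), Smc (at 10%, µm),
           Sxp (between 2.5% and 50%, µm)
volume     Vm, Vv, Vmp (10%), Vmc (10–80%), Vvc (10–80%), Vvv (80%)
           [µm³/µm²]

Feature parameters requiring watershed segmentation (Spd, Spc, S5p, S5v,
Sda, Sha, Sdv, Shv) are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .heightmap import HeightMap

__all__ = ["TextureParameterSet", "compute_texture_parameters", "PARAMETER_NAMES"]

PARAMETER_NAMES = (
    "Sa", "Sq", "Ssk", "Sku", "Sp", "Sv", "Sz",
    "Sal", "Str", "Std",
    "Sdq", "Sdr",
    "Smr", "Smc", "Sxp",
    "Vm", "Vv", "Vmp", "Vmc", "Vvc", "Vvv",
)

#: autocorrelation decay threshold for Sal / Str
ACF_THRESHOLD = 0.2


@dataclass(frozen=True)
class TextureParameterSet:
    """Named ISO 25178-2 parameter values from one scale-limited surface.

    ``flags`` records parameters that are undefined or degenerate for the
    surface (e.g. Ssk/Sku of a constant surface, Sal exceeding the field).
    """

    values: dict
    flags: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def as_row(self, specimen_id: str | None = None) -> dict:
        row = {} if specimen_id is None else {"id": specimen_id}
        row.update({k: self.values.get(k, np.nan) for k in PARAMETER_NAMES})
        return row


# ---------------------------------------------------------------------------

def _masked_acf(z: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Normalised areal autocorrelation on the centred lag grid.

    Zero-padded FFT (no circular wrap-around); each lag normalised by the
    number of overlapping valid pairs, then by the lag-0 value.
    """
    ny, nx = z.shape
    py, px = 2 * ny, 2 * nx
    zm = np.where(mask, z, 0.0)
    F = np.fft.rfft2(zm, s=(py, px))
    M = np.fft.rfft2(mask.astype(float), s=(py, px))
    num = np.fft.irfft2(F * np.conj(F), s=(py, px))
    cnt = np.fft.irfft2(M * np.conj(M), s=(py, px))
    num = np.fft.fftshift(num)
    cnt = np.fft.fftshift(cnt)
    with np.errstate(invalid="ignore", divide="ignore"):
        acf = np.where(cnt > 0.5, num / np.maximum(cnt, 1e-12), np.nan)
    c0 = acf[py // 2, px // 2]
    return acf / c0 if c0 > 0 else np.full_like(acf, np.nan)


def _acf_decay_lengths(acf, dx, dy, n_angles=180):
    """Distance from lag origin to the first crossing below the threshold,
    per direction.  Directions where the ACF never decays within the
    available lag range return inf."""
    py, px = acf.shape
    cy, cx = py // 2, px // 2
    max_r = min((px // 2 - 1) * dx, (py // 2 - 1) * dy)
    step = 0.5 * min(dx, dy)
    radii = np.arange(step, max_r, step)
    angles = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    lengths = np.full(n_angles, np.inf)
    for i, th in enumerate(angles):
        xs = cx + radii * np.cos(th) / dx
        ys = cy + radii * np.sin(th) / dy
        vals = map_coordinates(np.nan_to_num(acf, nan=1.0), [ys, xs], order=1)
        below = np.nonzero(vals < ACF_THRESHOLD)[0]
        if below.size:
            lengths[i] = radii[below[0]]
    return lengths


def _texture_direction(z, mask, dx, dy) -> float:
    """Std: dominant lay direction in degrees, 0 ≤ Std < 180, measured from
    the +x axis (ridges along x → Std = 0)."""
    zm = np.where(mask, z, 0.0)
    F = np.fft.fft2(zm)
    P = np.abs(F) ** 2
    fy = np.fft.fftfreq(z.shape[0], d=dy)
    fx = np.fft.fftfreq(z.shape[1], d=dx)
    FX, FY = np.meshgrid(fx, fy)
    P[0, 0] = 0.0  # remove DC
    ang = np.degrees(np.arctan2(FY, FX)) % 180.0
    bins = np.clip((ang).astype(int), 0, 179)
    spectrum = np.bincount(bins.ravel(), weights=P.ravel(), minlength=180)
    spectral_angle = float(np.argmax(spectrum))
    return (spectral_angle + 90.0) % 180.0


def _facet_area(z, mask, dx, dy):
    """Developed (triangulated) surface area and projected area over cells
    whose four corners are all valid."""
    z = np.where(mask, z, 0.0)  # keep NaN out of the excluded cells' algebra
    z00, z10 = z[:-1, :-1], z[:-1, 1:]
    z01, z11 = z[1:, :-1], z[1:, 1:]
    good = mask[:-1, :-1] & mask[:-1, 1:] & mask[1:, :-1] & mask[1:, 1:]

    def tri_area(pa, pb, pc):
        # vertices as (dx_off, dy_off, z); cross-product magnitude / 2
        ux, uy, uz = pb[0] - pa[0], pb[1] - pa[1], pb[2] - pa[2]
        vx, vy, vz = pc[0] - pa[0], pc[1] - pa[1], pc[2] - pa[2]
        nx_ = uy * vz - uz * vy
        ny_ = uz * vx - ux * vz
        nz_ = ux * vy - uy * vx
        return 0.5 * np.sqrt(nx_**2 + ny_**2 + nz_**2)

    a1 = tri_area((0, 0, z00), (dx, 0, z10), (0, dy, z01))
    a2 = tri_area((dx, 0, z10), (dx, dy, z11), (0, dy, z01))
    developed = ((a1 + a2) * good).sum()
    projected = good.sum() * dx * dy
    return developed, projected


def _material_ratio_curve(z_valid: np.ndarray, n_grid: int = 2001):
    """Height ζ(q) exceeded by fraction q of the surface, on a fine q grid."""
    q = np.linspace(0.0, 1.0, n_grid)
    zeta = np.quantile(z_valid, 1.0 - q)
    return q, zeta


def compute_texture_parameters(s: HeightMap) -> TextureParameterSet:
    """Compute all supported ISO 25178-2 parameters from a scale-limited
    surface.

    The surface is re-centred (mean of valid heights subtracted) first.
    Degenerate cases are flagged rather than raised: a constant surface
    yields Sa = Sq = 0 with Ssk/Sku undefined; an autocorrelation that
    never decays below the threshold flags Sal as exceeding the field.
    """
    s.require_stage("scale_limited")
    mask = s.mask
    if mask.mean() < 0.8:
        raise ValueError("fewer than 80% valid points; parameters unreliable")
    z = s.heights - s.heights[mask].mean()  # enforce mean plane at zero
    if np.ptp(s.heights[mask]) == 0:
        z = np.where(mask, 0.0, z)  # constant surface: exact zeros, no FP dust
    zv = z[mask]
    n = zv.size
    vals: dict = {}
    flags: dict = {}

    # height parameters
    sq = float(np.sqrt(np.mean(zv**2)))
    vals["Sa"] = float(np.mean(np.abs(zv)))
    vals["Sq"] = sq
    if sq == 0.0:
        vals["Ssk"] = np.nan
        vals["Sku"] = np.nan
        flags["Ssk"] = flags["Sku"] = "undefined: constant surface"
    else:
        vals["Ssk"] = float(np.mean(zv**3) / sq**3)
        vals["Sku"] = float(np.mean(zv**4) / sq**4)
    vals["Sp"] = float(zv.max())
    vals["Sv"] = float(-zv.min())
    vals["Sz"] = vals["Sp"] + vals["Sv"]

    # spatial parameters
    if sq == 0.0:
        vals["Sal"] = np.nan
        vals["Str"] = np.nan
        vals["Std"] = np.nan
        flags["Sal"] = flags["Str"] = flags["Std"] = "undefined: constant surface"
    else:
        acf = _masked_acf(z, mask)
        lengths = _acf_decay_lengths(acf, s.dx, s.dy)
        finite = np.isfinite(lengths)
        if not finite.any():
            vals["Sal"] = np.nan
            vals["Str"] = np.nan
            flags["Sal"] = "autocorrelation never below threshold: exceeds field size"
            flags["Str"] = "undefined: Sal exceeds field size"
        else:
            vals["Sal"] = float(lengths[finite].min())
            if finite.all():
                vals["Str"] = float(lengths.min() / lengths.max())
            else:
                # slowest direction never decays inside the field
                ext = min(s.extent_um) / 2
                vals["Str"] = float(lengths[finite].min() / ext)
                flags["Str"] = "truncated: slowest decay direction exceeds field"
        vals["Std"] = _texture_direction(z, mask, s.dx, s.dy)

    # hybrid parameters
    zg = np.where(mask, z, np.nan)
    gy, gx = np.gradient(zg, s.dy, s.dx)  # central diffs, one-sided at borders
    g2 = gx**2 + gy**2
    vals["Sdq"] = float(np.sqrt(np.nanmean(g2))) if np.isfinite(g2).any() else np.nan
    developed, projected = _facet_area(z, mask, s.dx, s.dy)
    vals["Sdr"] = float((developed / projected - 1.0) * 100.0) if projected > 0 else np.nan

    # material ratio / functional parameters
    q, zeta = _material_ratio_curve(zv)
    smc10 = float(np.quantile(zv, 0.9))          # ζ(0.10)
    vals["Smc"] = smc10
    vals["Smr"] = float(np.mean(zv >= -1.0) * 100.0)  # material ratio at 1 µm below mean plane
    vals["Sxp"] = float(np.quantile(zv, 0.975) - np.quantile(zv, 0.5))  # ζ(2.5%) − ζ(50%)

    # volume parameters: Vm(p) = ∫0^p (ζ(u) − ζ(p)) du ; Vv(p) = ∫p^1 (ζ(p) − ζ(u)) du
    def vm(p):
        sel = q <= p
        return float(np.trapezoid(zeta[sel] - np.interp(p, q, zeta), q[sel]))
    def vv(p):
        sel = q >= p
        return float(np.trapezoid(np.interp(p, q, zeta) - zeta[sel], q[sel]))
    vals["Vmp"] = vm(0.10)
    vals["Vmc"] = vm(0.80) - vm(0.10)
    vals["Vvc"] = vv(0.10) - vv(0.80)
    vals["Vvv"] = vv(0.80)
    vals["Vm"] = vals["Vmp"]
    vals["Vv"] = vv(0.10)

    return TextureParameterSet(values=vals, flags=flags)
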