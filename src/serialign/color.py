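"""CAM16-UCS colour appearance conversions.

The registration pipeline standardizes stain appearance by flattening the
chroma/hue of every pixel in the perceptually uniform CAM16-UCS space
(Li et al., 2017, "Comprehensive color solutions: CAM16, CAT16, and
CAM16-UCS"), and builds tissue masks from colour distances in the same
space.  Only the parts of the appearance model needed for those two jobs
are implemented: sRGB <-> CAM16-UCS (J', a', b') under fixed viewing
conditions.

Viewing conditions follow the common defaults for display imagery:
sRGB / D65 white point, 20% background luminance, "average" surround,
adapting luminance L_A = (64 / pi) / 5 cd/m^2.  All arrays are vectorized
over the trailing colour axis.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "srgb_to_cam16ucs",
    "cam16ucs_to_srgb",
    "srgb_to_jch",
    "jch_to_srgb",
]

# sRGB (IEC 61966-2-1) primaries -> CIE XYZ, D65 white
_RGB_TO_XYZ = np.array(
    [
        [0.4123907992659595, 0.3575843393838780, 0.1804807884018343],
        [0.2126390058715104, 0.7151686787677559, 0.0721923153607337],
        [0.0193308187155918, 0.1191947797946259, 0.9505321522496607],
    ]
)
_XYZ_TO_RGB = np.linalg.inv(_RGB_TO_XYZ)

# CAM16 cone-like transform
_M16 = np.array(
    [
        [0.401288, 0.650173, -0.051461],
        [-0.250268, 1.204414, 0.045854],
        [-0.002079, 0.048952, 0.953127],
    ]
)
_M16_INV = np.linalg.inv(_M16)


def _srgb_eotf_inverse(v: np.ndarray) -> np.ndarray:
    """Gamma-encode linear sRGB."""
    v = np.clip(v, 0.0, 1.0)
    return np.where(v <= 0.0031308, 12.92 * v, 1.055 * v ** (1 / 2.4) - 0.055)


def _srgb_eotf(v: np.ndarray) -> np.ndarray:
    """Linearize gamma-encoded sRGB."""
    v = np.asarray(v, dtype=float)
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


class _ViewingConditions:
    """Precomputed CAM16 viewing-condition constants (module-level singleton)."""

    def __init__(self, L_A: float = 64.0 / np.pi / 5.0, Y_b: float = 20.0):
        # D65 white, Y_w = 100
        XYZ_w = _RGB_TO_XYZ @ np.ones(3) * 100.0
        self.XYZ_w = XYZ_w
        Y_w = XYZ_w[1]
        RGB_w = _M16 @ XYZ_w
        # "average" surround
        F, self.c, self.N_c = 1.0, 0.69, 1.0
        D = np.clip(F * (1 - (1 / 3.6) * np.exp((-L_A - 42) / 92)), 0, 1)
        self.D_RGB = D * Y_w / RGB_w + 1 - D
        k = 1.0 / (5 * L_A + 1)
        self.F_L = 0.2 * k**4 * 5 * L_A + 0.1 * (1 - k**4) ** 2 * (5 * L_A) ** (1 / 3)
        self.n = Y_b / Y_w
        self.z = 1.48 + np.sqrt(self.n)
        self.N_bb = self.N_cb = 0.725 * self.n ** (-0.2)
        RGB_wc = self.D_RGB * RGB_w
        RGB_aw = self._adapt(RGB_wc)
        self.A_w = (2 * RGB_aw[0] + RGB_aw[1] + 0.05 * RGB_aw[2] - 0.305) * self.N_bb

    def _adapt(self, rgb):
        x = (self.F_L * np.abs(rgb) / 100.0) ** 0.42
        return np.sign(rgb) * 400.0 * x / (x + 27.13) + 0.1

    def _adapt_inverse(self, rgb_a):
        x = rgb_a - 0.1
        ax = np.abs(x)
        # 400 - |x| can hit 0 for out-of-gamut extremes; clamp
        return np.sign(x) * (100.0 / self.F_L) * (
            27.13 * ax / np.maximum(400.0 - ax, 1e-9)
        ) ** (1 / 0.42)


_VC = _ViewingConditions()


def _xyz_to_cam16_jmh(xyz: np.ndarray):
    """CIE XYZ (Y in [0,100]) -> CAM16 lightness J, colourfulness M, hue h (deg)."""
    vc = _VC
    rgb_c = vc.D_RGB * (xyz @ _M16.T)
    rgb_a = vc._adapt(rgb_c)
    R, G, B = rgb_a[..., 0], rgb_a[..., 1], rgb_a[..., 2]
    a = R - 12 * G / 11 + B / 11
    b = (R + G - 2 * B) / 9
    h = np.degrees(np.arctan2(b, a)) % 360.0
    e_t = 0.25 * (np.cos(np.radians(h) + 2.0) + 3.8)
    A = (2 * R + G + 0.05 * B - 0.305) * vc.N_bb
    A = np.maximum(A, 0.0)
    J = 100.0 * (A / vc.A_w) ** (vc.c * vc.z)
    denom = R + G + 21 * B / 20
    t = (
        (50000.0 / 13.0)
        * vc.N_c
        * vc.N_cb
        * e_t
        * np.hypot(a, b)
        / np.maximum(denom, 1e-9)
    )
    C = t**0.9 * np.sqrt(J / 100.0) * (1.64 - 0.29**vc.n) ** 0.73
    M = C * vc.F_L**0.25
    return J, M, h


def _cam16_jmh_to_xyz(J: np.ndarray, M: np.ndarray, h: np.ndarray) -> np.ndarray:
    vc = _VC
    J = np.maximum(np.asarray(J, dtype=float), 0.0)
    M = np.maximum(np.asarray(M, dtype=float), 0.0)
    hr = np.radians(h)
    C = M / vc.F_L**0.25
    sqrtJ = np.sqrt(J / 100.0)
    t = np.zeros_like(J)
    nz = sqrtJ > 1e-9
    t[nz] = (C[nz] / (sqrtJ[nz] * (1.64 - 0.29**vc.n) ** 0.73)) ** (1 / 0.9)
    e_t = 0.25 * (np.cos(hr + 2.0) + 3.8)
    A = vc.A_w * (J / 100.0) ** (1 / (vc.c * vc.z))
    p2 = A / vc.N_bb + 0.305

    # solve for the opponent signals a, b (standard CIECAM02/CAM16 inverse)
    a = np.zeros_like(J)
    b = np.zeros_like(J)
    has_c = t > 1e-12
    p1 = np.full_like(J, np.inf)
    p1[has_c] = (50000.0 / 13.0) * vc.N_c * vc.N_cb * e_t[has_c] / t[has_c]
    sin_h, cos_h = np.sin(hr), np.cos(hr)
    use_sin = has_c & (np.abs(sin_h) >= np.abs(cos_h))
    use_cos = has_c & ~use_sin
    if np.any(use_sin):
        p4 = p1[use_sin] / sin_h[use_sin]
        num = p2[use_sin] * (2 + 21.0 / 20.0) * (460.0 / 1403.0)
        den = (
            p4
            + (2 + 21.0 / 20.0) * (220.0 / 1403.0) * (cos_h[use_sin] / sin_h[use_sin])
            - 27.0 / 1403.0
            + (21.0 / 20.0) * (6300.0 / 1403.0)
        )
        b[use_sin] = num / den
        a[use_sin] = b[use_sin] * cos_h[use_sin] / sin_h[use_sin]
    if np.any(use_cos):
        p5 = p1[use_cos] / cos_h[use_cos]
        num = p2[use_cos] * (2 + 21.0 / 20.0) * (460.0 / 1403.0)
        den = (
            p5
            + (2 + 21.0 / 20.0) * (220.0 / 1403.0)
            - (27.0 / 1403.0 - (21.0 / 20.0) * (6300.0 / 1403.0))
            * (sin_h[use_cos] / cos_h[use_cos])
        )
        a[use_cos] = num / den
        b[use_cos] = a[use_cos] * sin_h[use_cos] / cos_h[use_cos]

    R_a = (460.0 * p2 + 451.0 * a + 288.0 * b) / 1403.0
    G_a = (460.0 * p2 - 891.0 * a - 261.0 * b) / 1403.0
    B_a = (460.0 * p2 - 220.0 * a - 6300.0 * b) / 1403.0
    rgb_c = vc._adapt_inverse(np.stack([R_a, G_a, B_a], axis=-1))
    rgb = rgb_c / vc.D_RGB
    return rgb @ _M16_INV.T


def _ucs_from_jmh(J, M, h):
    """CAM16 J, M, h -> CAM16-UCS J', a', b' (reference scale, J' in [0,100])."""
    Jp = 1.7 * J / (1 + 0.007 * J)
    Mp = np.log1p(0.0228 * M) / 0.0228
    hr = np.radians(h)
    return Jp, Mp * np.cos(hr), Mp * np.sin(hr)


def _jmh_from_ucs(Jp, ap, bp):
    Jp = np.asarray(Jp, dtype=float)
    J = Jp / (1.7 - 0.007 * Jp)
    Mp = np.hypot(ap, bp)
    M = np.expm1(0.0228 * Mp) / 0.0228
    h = np.degrees(np.arctan2(bp, ap)) % 360.0
    return J, M, h


def srgb_to_cam16ucs(rgb: np.ndarray) -> np.ndarray:
    """Convert sRGB in [0, 1] (..., 3) to CAM16-UCS (J', a', b') on unit scale.

    Unit scale divides the reference-scale coordinates by 100, so J' is in
    [0, 1] and a'/b' are roughly in [-0.5, 0.5]; a chroma of 0.2 on this
    scale equals M' = 20 on the reference scale.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError("expected a trailing axis of 3 (RGB)")
    xyz = _srgb_eotf(rgb) @ _RGB_TO_XYZ.T * 100.0
    J, M, h = _xyz_to_cam16_jmh(xyz)
    Jp, ap, bp = _ucs_from_jmh(J, M, h)
    return np.stack([Jp, ap, bp], axis=-1) / 100.0


def cam16ucs_to_srgb(jab: np.ndarray) -> np.ndarray:
    """Inverse of :func:`srgb_to_cam16ucs`; output clipped into [0, 1]."""
    jab = np.asarray(jab, dtype=float) * 100.0
    J, M, h = _jmh_from_ucs(jab[..., 0], jab[..., 1], jab[..., 2])
    xyz = _cam16_jmh_to_xyz(J, M, h)
    lin = xyz / 100.0 @ _XYZ_TO_RGB.T
    return _srgb_eotf_inverse(lin)


def srgb_to_jch(rgb: np.ndarray) -> np.ndarray:
    """sRGB -> polar CAM16-UCS (J', C', h) with J', C' on unit scale, h in degrees."""
    jab = srgb_to_cam16ucs(rgb)
    C = np.hypot(jab[..., 1], jab[..., 2])
    h = np.degrees(np.arctan2(jab[..., 2], jab[..., 1])) % 360.0
    return np.stack([jab[..., 0], C, h], axis=-1)


def jch_to_srgb(jch: np.ndarray) -> np.ndarray:
    """Inverse of :func:`srgb_to_jch`."""
    jch = np.asarray(jch, dtype=float)
    hr = np.radians(jch[..., 2])
    jab = np.stack(
        [jch[..., 0], jch[..., 1] * np.cos(hr), jch[..., 1] * np.sin(hr)], axis=-1
    )
    return cam16ucs_to_srgb(jab)
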