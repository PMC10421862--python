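"""Slice-wise texture filter bank and region summaries.

Four filter families produce per-pixel response maps on each annotated
axial slice:

* 13 Haralick features computed per pixel from a sliding-window gray-level
  co-occurrence matrix (GLCM),
* 25 Laws maps (outer products of the L5/E5/S5/R5/W5 vectors),
* 25 Laws-Laplacian maps (Laplacian-of-Gaussian smoothing, then Laws),
* 48 Gabor magnitude maps (8 orientations x 6 wavelengths).

That is 111 maps; pooling each map's pixels over all annotated slices and
summarizing with five first-order statistics (mean, median, SD, skewness,
kurtosis) gives 555 texture statistics per region, 1110 across the
intratumoral and peritumoral regions.

Conventions (also recorded in the settings hash): GLCM uses 64 equal-width
gray levels over the region's intensity range, the four distance-1 offsets,
symmetric counts, features averaged over offsets, logs base 2 with
0*log(0) = 0; Laws/Gabor responses are raw (not energy-windowed) with
reflect border padding; kurtosis is excess; SD uses the n-1 denominator;
zero-variance pools report SD = skewness = kurtosis = 0.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats
from skimage.filters import gabor_kernel

# ---------------------------------------------------------------------------
# filter-bank identifiers

HARALICK_NAMES = [
    "asm", "contrast", "correlation", "variance", "idm",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "difference_variance", "difference_entropy", "imc1", "imc2",
]

LAWS_VECTORS = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
}
_LAWS_ORDER = ["L5", "E5", "S5", "R5", "W5"]
LAWS_NAMES = [a + b for a in _LAWS_ORDER for b in _LAWS_ORDER]

DEFAULT_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))
DEFAULT_WAVELENGTHS = (2, 4, 6, 8, 10, 12)
STAT_NAMES = ["mean", "median", "sd", "skewness", "kurtosis"]
REGION_NAMES = ("tumor", "rim")


def gabor_filter_ids(n_orientations: int = 8, wavelengths=DEFAULT_WAVELENGTHS):
    return [f"o{k}_w{w}" for k in range(n_orientations) for w in wavelengths]


def filter_names(n_orientations: int = 8, wavelengths=DEFAULT_WAVELENGTHS):
    """The full list of (family, filter) identifiers — 111 by default."""
    out = [("haralick", n) for n in HARALICK_NAMES]
    out += [("laws", n) for n in LAWS_NAMES]
    out += [("laws_laplacian", n) for n in LAWS_NAMES]
    out += [("gabor", g) for g in gabor_filter_ids(n_orientations, wavelengths)]
    return out


@dataclass
class TextureConfig:
    glcm_levels: int = 64
    glcm_offsets: tuple = DEFAULT_OFFSETS
    haralick_window: int = 5          # sliding-window side for per-pixel maps
    log_sigma: float = 1.0            # Laplacian-of-Gaussian sigma, px
    gabor_orientations: int = 8
    gabor_wavelengths: tuple = DEFAULT_WAVELENGTHS
    gabor_sigma_factor: float = 0.56  # sigma = factor * wavelength

    def settings_hash(self) -> str:
        blob = json.dumps({
            "glcm_levels": self.glcm_levels,
            "glcm_offsets": [list(o) for o in self.glcm_offsets],
            "haralick_window": self.haralick_window,
            "log_sigma": self.log_sigma,
            "gabor_orientations": self.gabor_orientations,
            "gabor_wavelengths": list(self.gabor_wavelengths),
            "gabor_sigma_factor": self.gabor_sigma_factor,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# GLCM + Haralick


@dataclass
class GLCMMatrix:
    """Per-offset symmetric co-occurrence probabilities.

    ``probabilities`` has shape (n_offsets, Ng, Ng); each offset's matrix
    sums to 1.  ``missing`` marks a region with no valid pixel pair.
    """

    probabilities: np.ndarray
    levels: int
    offsets: tuple
    symmetric: bool = True
    missing: bool = False


def quantize(slice2d: np.ndarray, region2d: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization over the region's intensity range.

    Returns an int array with values in [0, levels) inside the region and
    -1 outside.  A constant region maps entirely to level 0.
    """
    q = np.full(slice2d.shape, -1, dtype=np.int64)
    vals = slice2d[region2d]
    if vals.size == 0:
        return q
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        q[region2d] = 0
        return q
    scaled = (slice2d[region2d] - lo) / (hi - lo) * levels
    q[region2d] = np.clip(scaled.astype(np.int64), 0, levels - 1)
    return q


def _pair_codes(q: np.ndarray, offset, levels: int) -> np.ndarray:
    """Code map: q[r,c]*Ng + q[r+dr,c+dc] where both pixels are in-region,
    else -1.  Shape matches q; positions whose partner falls outside the
    slice are -1."""
    dr, dc = offset
    H, W = q.shape
    codes = np.full((H, W), -1, dtype=np.int64)
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = (a >= 0) & (b >= 0)
    block = np.where(valid, a * levels + b, -1)
    codes[r0:r1, c0:c1] = block
    return codes


def compute_glcm(slice2d: np.ndarray, region2d: np.ndarray,
                 levels: int = 64, offsets=DEFAULT_OFFSETS) -> GLCMMatrix:
    """Symmetric, normalized GLCM of the region pixels of one slice.

    Counts pixel pairs with both members inside the region, per offset;
    symmetrizes by adding the transposed counts; normalizes each offset's
    matrix to sum to 1.  Fewer than one valid pair for every offset yields
    a flagged-missing GLCM.
    """
    region2d = np.asarray(region2d) > 0
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if region2d.sum() < 2:
        return GLCMMatrix(np.zeros((len(offsets), levels, levels)),
                          levels, tuple(offsets), missing=True)
    q = quantize(np.asarray(slice2d, dtype=float), region2d, levels)
    mats = np.zeros((len(offsets), levels, levels))
    any_pairs = False
    for k, off in enumerate(offsets):
        codes = _pair_codes(q, off, levels)
        flat = codes[codes >= 0]
        if flat.size == 0:
            continue
        counts = np.bincount(flat, minlength=levels * levels).reshape(levels, levels)
        counts = counts + counts.T          # symmetrize
        mats[k] = counts / counts.sum()
        any_pairs = True
    return GLCMMatrix(mats, levels, tuple(offsets), missing=not any_pairs)


def _entropy2(p):
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _haralick_sparse(ii, jj, pp, levels):
    """The 13 Haralick features from sparse GLCM entries (i, j, p).

    Logs are base 2 with 0*log(0) := 0; correlation is 0 for a
    zero-variance marginal; sum variance is taken about the sum average.
    """
    f = np.zeros(13)
    px = np.bincount(ii, weights=pp, minlength=levels)
    py = np.bincount(jj, weights=pp, minlength=levels)
    mu_x = float((np.arange(levels) * px).sum())
    mu_y = float((np.arange(levels) * py).sum())
    var_x = float(((np.arange(levels) - mu_x) ** 2 * px).sum())
    var_y = float(((np.arange(levels) - mu_y) ** 2 * py).sum())

    diff = ii - jj
    f[0] = (pp ** 2).sum()                                   # ASM
    f[1] = (pp * diff.astype(float) ** 2).sum()              # contrast
    if var_x > 0 and var_y > 0:
        f[2] = ((ii * jj * pp).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y)
    f[3] = ((ii - mu_x) ** 2 * pp).sum()                     # sum of squares: variance
    f[4] = (pp / (1.0 + diff.astype(float) ** 2)).sum()      # inverse difference moment

    psum = np.bincount(ii + jj, weights=pp, minlength=2 * levels - 1)
    ks = np.arange(psum.size)
    f[5] = (ks * psum).sum()                                 # sum average
    f[6] = ((ks - f[5]) ** 2 * psum).sum()                   # sum variance
    f[7] = _entropy2(psum)                                   # sum entropy
    f[8] = _entropy2(pp)                                     # entropy

    pdiff = np.bincount(np.abs(diff), weights=pp, minlength=levels)
    kd = np.arange(pdiff.size)
    mu_d = (kd * pdiff).sum()
    f[9] = ((kd - mu_d) ** 2 * pdiff).sum()                  # difference variance
    f[10] = _entropy2(pdiff)                                 # difference entropy

    hx, hy, hxy = _entropy2(px), _entropy2(py), f[8]
    with np.errstate(divide="ignore"):
        lpxpy = np.log2(px[ii] * py[jj])
    hxy1 = float(-(pp * lpxpy).sum())
    nz_x, nz_y = px[px > 0], py[py > 0]
    outer = np.outer(nz_x, nz_y)
    hxy2 = float(-(outer * np.log2(outer)).sum())
    denom = max(hx, hy)
    f[11] = (hxy - hxy1) / denom if denom > 0 else 0.0       # IMC1
    f[12] = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))  # IMC2
    return f


def haralick_features(glcm: GLCMMatrix) -> dict:
    """13 Haralick features, averaged over the GLCM's offsets."""
    if glcm.missing:
        return {n: np.nan for n in HARALICK_NAMES}
    feats = []
    for P in glcm.probabilities:
        if P.sum() == 0:
            continue
        ii, jj = np.nonzero(P)
        feats.append(_haralick_sparse(ii, jj, P[ii, jj], glcm.levels))
    mean = np.mean(feats, axis=0)
    return dict(zip(HARALICK_NAMES, mean))


def haralick_maps(slice2d: np.ndarray, region2d: np.ndarray,
                  levels: int = 64, offsets=DEFAULT_OFFSETS,
                  window: int = 5) -> dict:
    """Per-pixel Haralick maps via a sliding-window GLCM.

    The slice is quantized once over the whole region's range; each region
    pixel's GLCM pools the offset pairs whose both endpoints lie in the
    centred ``window`` x ``window`` box intersected with the region.
    Pixels whose window holds no valid pair are NaN.  Returns
    {feature_name: 2D float map (NaN outside region)}.
    """
    region2d = np.asarray(region2d) > 0
    H, W = region2d.shape
    w = window // 2
    q = quantize(np.asarray(slice2d, dtype=float), region2d, levels)
    code_maps = [_pair_codes(q, off, levels) for off in offsets]
    out = {n: np.full((H, W), np.nan) for n in HARALICK_NAMES}
    rows, cols = np.nonzero(region2d)
    for r0, c0 in zip(rows, cols):
        codes = []
        for cm, (dr, dc) in zip(code_maps, offsets):
            # both pair endpoints inside the window and the slice
            rlo = max(r0 - w, 0)
            rhi = min(r0 + w - dr, H - 1 - dr)
            clo = max(c0 - w, 0, c0 - w - dc, -dc)
            chi = min(c0 + w, W - 1, c0 + w - dc, W - 1 - dc)
            if rhi < rlo or chi < clo:
                continue
            block = cm[rlo:rhi + 1, clo:chi + 1].ravel()
            block = block[block >= 0]
            if block.size:
                codes.append(block)
        if not codes:
            continue
        codes = np.concatenate(codes)
        codes = np.concatenate([codes, (codes % levels) * levels + codes // levels])
        uniq, counts = np.unique(codes, return_counts=True)
        pp = counts / counts.sum()
        vals = _haralick_sparse(uniq // levels, uniq % levels, pp, levels)
        for n, v in zip(HARALICK_NAMES, vals):
            out[n][r0, c0] = v
    return out


# ---------------------------------------------------------------------------
# Laws / Laws-Laplacian / Gabor


def laws_kernels() -> dict:
    """The 25 5x5 Laws kernels as outer products of the five 1D vectors."""
    return {a + b: np.outer(LAWS_VECTORS[a], LAWS_VECTORS[b])
            for a in _LAWS_ORDER for b in _LAWS_ORDER}


def laws_response_maps(slice2d: np.ndarray, region2d=None) -> dict:
    """Raw responses of the 25 Laws kernels (reflect padding)."""
    img = np.asarray(slice2d, dtype=float)
    return {name: ndimage.convolve(img, k, mode="reflect")
            for name, k in laws_kernels().items()}


def log_kernel(sigma: float = 1.0, truncate: float = 4.0) -> np.ndarray:
    """Analytic Laplacian-of-Gaussian kernel, mean-subtracted so its sum is
    exactly zero (a constant image responds exactly 0)."""
    r = int(np.ceil(truncate * sigma))
    y, x = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    rr = x ** 2 + y ** 2
    k = (rr - 2 * sigma ** 2) / sigma ** 4 * np.exp(-rr / (2 * sigma ** 2))
    k /= 2 * np.pi * sigma ** 2
    return k - k.mean()


def laws_laplacian_maps(slice2d: np.ndarray, region2d=None,
                        sigma: float = 1.0) -> dict:
    """Laws responses of the Laplacian-of-Gaussian smoothed slice."""
    img = _conv_reflect(np.asarray(slice2d, dtype=float), log_kernel(sigma))
    return laws_response_maps(img)


def gabor_bank(n_orientations: int = 8, wavelengths=DEFAULT_WAVELENGTHS,
               sigma_factor: float = 0.56) -> dict:
    """DC-corrected complex Gabor kernels, 8 orientations x 6 wavelengths."""
    bank = {}
    for k in range(n_orientations):
        theta = k * np.pi / n_orientations
        for lam in wavelengths:
            sig = sigma_factor * lam
            ker = gabor_kernel(frequency=1.0 / lam, theta=theta,
                               sigma_x=sig, sigma_y=sig)
            ker = ker - ker.real.mean()   # remove DC so constants respond 0
            bank[f"o{k}_w{lam}"] = ker
    return bank


def _conv_reflect(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same' convolution with reflect boundary (FFT for large kernels)."""
    pr, pc = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(img, ((pr, pr), (pc, pc)), mode="reflect")
    if kernel.size <= 49:
        out = signal.convolve(padded, kernel, mode="same")
    else:
        out = signal.fftconvolve(padded, kernel, mode="same")
    return out[pr:pr + img.shape[0], pc:pc + img.shape[1]]


def gabor_response_maps(slice2d: np.ndarray, region2d=None,
                        bank: dict = None) -> dict:
    """Magnitudes of the complex Gabor responses, one map per bank filter."""
    if bank is None:
        bank = gabor_bank()
    img = np.asarray(slice2d, dtype=float)
    return {name: np.abs(_conv_reflect(img, ker)) for name, ker in bank.items()}


# ---------------------------------------------------------------------------
# region summaries


def five_stats(values: np.ndarray) -> dict:
    """Mean, median, SD (n-1), skewness, excess kurtosis of pooled pixels.

    Zero-variance (or singleton) pools report SD = skewness = kurtosis = 0;
    empty pools report all five as NaN.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {s: np.nan for s in STAT_NAMES}
    out = {"mean": float(v.mean()), "median": float(np.median(v))}
    if v.size < 2 or np.ptp(v) == 0:
        out.update(sd=0.0, skewness=0.0, kurtosis=0.0)
    else:
        out["sd"] = float(v.std(ddof=1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sk = float(stats.skew(v, bias=True))
            ku = float(stats.kurtosis(v, fisher=True, bias=True))
        # near-constant pools hit catastrophic cancellation; use the
        # zero-variance convention there
        out["skewness"] = sk if np.isfinite(sk) else 0.0
        out["kurtosis"] = ku if np.isfinite(ku) else 0.0
    return out


def summarize_region(pooled: dict, region_label: str) -> dict:
    """Five statistics per pooled map -> {family_filter_stat_region: value}."""
    out = {}
    for (family, filt), values in pooled.items():
        st = five_stats(np.concatenate(values) if values else np.array([]))
        for s in STAT_NAMES:
            out[f"{family}_{filt}_{s}_{region_label}"] = st[s]
    return out


def _region_slice_maps(slice2d, region2d, cfg: TextureConfig, bank):
    """All 111 per-pixel maps for one slice, as {(family, filter): 1D pixel values}."""
    vals = {}
    hmaps = haralick_maps(slice2d, region2d, levels=cfg.glcm_levels,
                          offsets=cfg.glcm_offsets, window=cfg.haralick_window)
    for n in HARALICK_NAMES:
        vals[("haralick", n)] = hmaps[n][region2d]
    for n, m in laws_response_maps(slice2d).items():
        vals[("laws", n)] = m[region2d]
    for n, m in laws_laplacian_maps(slice2d, sigma=cfg.log_sigma).items():
        vals[("laws_laplacian", n)] = m[region2d]
    for n, m in gabor_response_maps(slice2d, bank=bank).items():
        vals[("gabor", n)] = m[region2d]
    return vals


def extract_texture_features(volume, region_pair, cfg: TextureConfig = None) -> dict:
    """The full 1110-entry texture vector of one scan (555 per region).

    Response maps are computed slice-by-slice on every axial slice where a
    region is present; per-pixel responses are pooled across slices before
    the five statistics.  A flagged-empty rim yields NaN rim entries.  The
    returned dict also carries ``_settings_hash`` provenance.
    """
    if cfg is None:
        cfg = TextureConfig()
    bank = gabor_bank(cfg.gabor_orientations, cfg.gabor_wavelengths,
                      cfg.gabor_sigma_factor)
    names = filter_names(cfg.gabor_orientations, cfg.gabor_wavelengths)
    out = {}
    for label in REGION_NAMES:
        mask = region_pair.tumor if label == "tumor" else region_pair.rim
        pooled = {key: [] for key in names}
        if not (label == "rim" and region_pair.rim_empty):
            vox = mask.voxels
            for z in range(vox.shape[2]):
                region2d = vox[:, :, z]
                if not region2d.any():
                    continue
                slice2d = volume.intensities[:, :, z]
                svals = _region_slice_maps(slice2d, region2d, cfg, bank)
                for key in names:
                    pooled[key].append(svals[key])
        out.update(summarize_region(pooled, label))
    out["_settings_hash"] = cfg.settings_hash()
    return out


def export_response_map(volume, mask, family: str, filt: str, path,
                        cfg: TextureConfig = None) -> None:
    """Write one filter's per-pixel response as a NIfTI overlay (NaN outside)."""
    import SimpleITK as sitk

    from .io import _to_sitk

    if cfg is None:
        cfg = TextureConfig()
    bank = gabor_bank(cfg.gabor_orientations, cfg.gabor_wavelengths,
                      cfg.gabor_sigma_factor)
    overlay = np.zeros(volume.shape)
    for z in range(volume.shape[2]):
        region2d = mask.voxels[:, :, z]
        if not region2d.any():
            continue
        svals = _region_slice_maps(volume.intensities[:, :, z], region2d, cfg, bank)
        plane = np.zeros(region2d.shape)
        plane[region2d] = np.nan_to_num(svals[(family, filt)])
        overlay[:, :, z] = plane
    sitk.WriteImage(_to_sitk(overlay, volume.spacing), str(path))
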