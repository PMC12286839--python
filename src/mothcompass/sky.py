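"""Night-sky stimulus algorithms: star detection and three randomizations.

The natural night-sky stimulus is an 8-bit greyscale raster (the study's
reference image spans grey levels 4-255 with a mean of ~62).  Control
stimuli must scramble its spatial (directional) information while keeping
the total light intensity identical:

* ``randomize_pixels`` — every pixel reassigned to a random position
  (an exact permutation; histogram preserved bit-for-bit);
* ``randomize_blocks`` — 13x13-pixel squares permuted (13 px ~ the extent of
  the brightest star), keeping individual stars intact but destroying the
  large-scale pattern; edge margins not divisible by the block size stay in
  place;
* ``randomize_stars`` — stars detected by a multiscale Laplacian-of-Gaussian
  filter with local-maxima detection are cut out and re-placed uniformly at
  random (without overlap) on a uniform background equal to the mean of all
  non-star pixels, with the brightest star pinned to the image centre.

Coordinates are 0-based (row, col), row-major.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max

__all__ = [
    "StarCatalog",
    "DEFAULT_SCALES",
    "load_image",
    "save_image",
    "detect_stars",
    "star_footprint",
    "star_mask",
    "randomize_pixels",
    "randomize_blocks",
    "randomize_stars",
]

DEFAULT_SCALES = (1.0, 1.5, 2.0, 3.0, 4.5, 6.5)


@dataclass
class StarCatalog:
    """Detected (or planted) stars: centre, detection scale, peak intensity."""

    table: pd.DataFrame      # columns: star_id, row, col, sigma_px, peak

    def __len__(self):
        return len(self.table)

    @property
    def brightest(self):
        """Row of the brightest star (max peak; ties by integrated flux proxy
        peak * sigma^2)."""
        t = self.table
        m = t["peak"] == t["peak"].max()
        cand = t[m]
        if len(cand) > 1:
            flux = cand["peak"] * cand["sigma_px"] ** 2
            return cand.loc[flux.idxmax()]
        return cand.iloc[0]

    def to_csv(self, path):
        with open(path, "w") as fh:
            fh.write("# mothcompass-starcatalog v1; coordinates 0-based "
                     "(row, col), row-major\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path, sep="\t", comment="#"))


def load_image(path) -> np.ndarray:
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:
        img = img.mean(axis=2)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def save_image(image: np.ndarray, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


# ---------------------------------------------------------------------------
# Star detection
# ---------------------------------------------------------------------------


def detect_stars(image: np.ndarray, scales=DEFAULT_SCALES,
                 threshold: float = 0.04) -> StarCatalog:
    """Multiscale LoG blob detection of stars in a greyscale image.

    The scale-normalised negative Laplacian of Gaussian (sigma^2 * -LoG) is
    computed at each sigma in ``scales``; local maxima of the 3-D
    (scale, row, col) response above ``threshold`` (on a 0-1 intensity
    scale) become candidate stars, and overlapping detections (centres
    closer than the larger footprint radius) are merged keeping the stronger
    response.  A uniform image yields an empty catalog.
    """
    img = np.asarray(image, dtype=float) / 255.0
    scales = np.asarray(sorted(scales), dtype=float)
    stack = np.stack([-(s**2) * ndimage.gaussian_laplace(img, s) for s in scales])
    peaks = peak_local_max(stack, threshold_abs=threshold, exclude_border=False)
    if peaks.size == 0:
        return StarCatalog(pd.DataFrame(
            columns=["star_id", "row", "col", "sigma_px", "peak"]))
    resp = stack[peaks[:, 0], peaks[:, 1], peaks[:, 2]]
    order = np.argsort(resp)[::-1]
    kept = []
    for i in order:
        s, r, c = peaks[i]
        sig = scales[s]
        rad = 1.5 * sig
        clash = False
        for (_, kr, kc, ksig) in kept:
            if (r - kr) ** 2 + (c - kc) ** 2 < max(rad, 1.5 * ksig) ** 2:
                clash = True
                break
        if not clash:
            kept.append((resp[i], r, c, sig))
    rows = []
    for i, (_, r, c, sig) in enumerate(kept):
        rows.append({"star_id": i, "row": int(r), "col": int(c),
                     "sigma_px": float(sig),
                     "peak": float(image[int(r), int(c)])})
    table = pd.DataFrame(rows).sort_values("peak", ascending=False,
                                           kind="stable").reset_index(drop=True)
    table["star_id"] = np.arange(len(table))
    return StarCatalog(table)


def star_footprint(image: np.ndarray, row: int, col: int, sigma: float,
                   peak: float, frac: float = 0.10) -> np.ndarray:
    """Boolean footprint of one star: pixels within 3 sigma of the centre
    whose value is at least ``frac`` of the star's peak intensity."""
    h, w = image.shape
    rad = max(int(np.ceil(3.0 * sigma)), 1)
    rr, cc = np.ogrid[:h, :w]
    near = (rr - row) ** 2 + (cc - col) ** 2 <= rad**2
    return near & (np.asarray(image, dtype=float) >= frac * peak)


def star_mask(image: np.ndarray, catalog: StarCatalog) -> np.ndarray:
    """Union of all star footprints."""
    mask = np.zeros(image.shape, dtype=bool)
    for _, s in catalog.table.iterrows():
        mask |= star_footprint(image, int(s["row"]), int(s["col"]),
                               float(s["sigma_px"]), float(s["peak"]))
    return mask


# ---------------------------------------------------------------------------
# Randomizations
# ---------------------------------------------------------------------------


def randomize_pixels(image: np.ndarray, seed: int = 0) -> np.ndarray:
    """Reassign every pixel to a random position (exact permutation)."""
    rng = np.random.default_rng(seed)
    flat = np.asarray(image).ravel().copy()
    rng.shuffle(flat)
    return flat.reshape(np.asarray(image).shape)


def randomize_blocks(image: np.ndarray, block: int = 13, seed: int = 0) -> np.ndarray:
    """Permute ``block`` x ``block`` tiles; tile interiors untouched.

    Margins where the image dimensions are not divisible by the block size
    are left in place.
    """
    img = np.asarray(image)
    h, w = img.shape
    if h < block or w < block:
        raise ValueError("image smaller than the block size")
    rng = np.random.default_rng(seed)
    nh, nw = h // block, w // block
    out = img.copy()
    tiles = (img[: nh * block, : nw * block]
             .reshape(nh, block, nw, block).swapaxes(1, 2).reshape(nh * nw, block, block))
    perm = rng.permutation(nh * nw)
    shuffled = tiles[perm].reshape(nh, nw, block, block).swapaxes(1, 2)
    out[: nh * block, : nw * block] = shuffled.reshape(nh * block, nw * block)
    return out


def randomize_stars(image: np.ndarray, catalog: StarCatalog, seed: int = 0,
                    max_retries: int = 10_000) -> np.ndarray:
    """Re-place detected stars uniformly at random on a uniform background.

    The background grey level is the mean of all non-star pixels (rounded to
    the nearest integer level); star footprints keep their original pixel
    values; placements are rejection-sampled so footprints never overlap,
    and the brightest star is placed at the image centre.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    img = np.asarray(image)
    h, w = img.shape
    mask = star_mask(img, catalog)
    bg = int(np.round(img[~mask].mean()))
    out = np.full_like(img, bg)
    occupied = np.zeros_like(mask)
    rng = np.random.default_rng(seed)

    stars = catalog.table.copy()
    b = catalog.brightest
    order = [int(b["star_id"])] + [int(i) for i in stars["star_id"] if int(i) != int(b["star_id"])]

    for k, sid in enumerate(order):
        s = stars[stars["star_id"] == sid].iloc[0]
        r0, c0 = int(s["row"]), int(s["col"])
        fp = star_footprint(img, r0, c0, float(s["sigma_px"]), float(s["peak"]))
        fr, fc = np.nonzero(fp)
        dr, dc = fr - r0, fc - c0
        vals = img[fr, fc]
        placed = False
        tries = 1 if k == 0 else max_retries
        for _ in range(tries):
            if k == 0:
                nr, nc = h // 2, w // 2
            else:
                nr = int(rng.integers(0, h))
                nc = int(rng.integers(0, w))
            rr, cc = nr + dr, nc + dc
            if (rr.min() < 0 or rr.max() >= h or cc.min() < 0 or cc.max() >= w):
                continue
            if occupied[rr, cc].any():
                continue
            out[rr, cc] = vals
            occupied[rr, cc] = True
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place star {sid} without overlap after {max_retries} tries")
    return out
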