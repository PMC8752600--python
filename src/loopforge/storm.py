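"""Super-resolution image colocalization: alignment, cross-correlation, ratios.

Two binarized single-molecule-localization images (e.g. two
immunostained factors in the same nucleus) are aligned on fiducial bead
coordinates, then compared by (i) the FFT pair cross-correlation

    c(r) = Re( IFFT( FFT(Im_A) * conj(FFT(Im_B)) ) / (rho_A * rho_B * N(r)) )

where rho is each channel's on-pixel density within the ROI and N(r) is
the number of overlapping ROI pixels at displacement r, and (ii) the
pixel-by-pixel colocalization ratio (shared on-pixels over each
channel's on-pixels).  c(r) = 1 marks the uncorrelated baseline; for two
identical images c(0) = 1/rho exactly.  Images are zero-padded to twice
the linear size before the FFT so the correlation is aperiodic and N(r)
reflects the true (non-circular) ROI overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StormImage", "CrossCorrelation", "align_by_fiducials", "match_beads",
           "cross_correlation", "coloc_ratios"]


@dataclass
class StormImage:
    """Binary pixel grid with an ROI mask and signal density."""

    pixels: np.ndarray
    roi: np.ndarray | None = None
    pixel_size_nm: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if not np.isin(self.pixels, (0, 1)).all():
            raise ValueError("image must be binary")
        self.pixels = self.pixels.astype(np.uint8)
        if self.roi is None:
            self.roi = np.ones_like(self.pixels)
        else:
            self.roi = np.asarray(self.roi).astype(np.uint8)
            if self.roi.shape != self.pixels.shape:
                raise ValueError("ROI mask shape mismatch")

    @property
    def density(self) -> float:
        """On-pixels inside the ROI over ROI area."""
        roi_area = int(self.roi.sum())
        if roi_area == 0:
            raise ValueError("empty ROI")
        return float((self.pixels * self.roi).sum() / roi_area)


@dataclass
class CrossCorrelation:
    c: np.ndarray           # 2D correlation, displacement (0,0) at the center
    n: np.ndarray           # overlapping ROI pixel count per displacement
    center: tuple[int, int]
    radial_r: np.ndarray = field(default_factory=lambda: np.array([]))
    radial_c: np.ndarray = field(default_factory=lambda: np.array([]))
    radial_counts: np.ndarray = field(default_factory=lambda: np.array([]))

    def at(self, dr: int, dc: int) -> float:
        return float(self.c[self.center[0] + dr, self.center[1] + dc])


def match_beads(beads_a: np.ndarray, beads_b: np.ndarray, gate: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour bead pairing with a distance gate (convenience).

    Returns the matched subsets of both lists in corresponding order.
    """
    beads_a = np.atleast_2d(beads_a)
    beads_b = np.atleast_2d(beads_b)
    pairs_a, pairs_b = [], []
    used = set()
    for pa in beads_a:
        d = np.linalg.norm(beads_b - pa, axis=1)
        order = np.argsort(d)
        for k in order:
            if k in used:
                continue
            if d[k] <= gate:
                used.add(k)
                pairs_a.append(pa)
                pairs_b.append(beads_b[k])
            break
    return np.array(pairs_a), np.array(pairs_b)


def align_by_fiducials(
    image_a: StormImage | np.ndarray,
    beads_a: np.ndarray,
    image_b: StormImage | np.ndarray,
    beads_b: np.ndarray,
    spread_warn: float = 2.0,
) -> dict:
    """Rigid-translate channel B onto channel A using matched bead pairs.

    The shift is the mean bead displacement (b - a), rounded to integer
    pixels; channel B is translated by its negation with zero fill.  A
    bead-displacement spread above ``spread_warn`` pixels attaches a
    warning (the estimate is still returned).
    """
    beads_a = np.atleast_2d(np.asarray(beads_a, dtype=float))
    beads_b = np.atleast_2d(np.asarray(beads_b, dtype=float))
    if beads_a.size == 0 or beads_b.size == 0:
        raise ValueError("need at least one matched bead pair")
    if beads_a.shape != beads_b.shape:
        raise ValueError("bead lists must correspond one-to-one")
    disp = beads_b - beads_a
    shift = np.round(disp.mean(axis=0)).astype(int)
    spread = float(np.max(np.linalg.norm(disp - disp.mean(axis=0), axis=1))) if len(disp) > 1 else 0.0
    warning = None
    if spread > spread_warn:
        warning = f"bead displacements disagree by {spread:.1f} px (> {spread_warn} px)"

    pix = image_b.pixels if isinstance(image_b, StormImage) else np.asarray(image_b)
    out = np.zeros_like(pix)
    r0, c0 = -int(shift[0]), -int(shift[1])
    h, w = pix.shape
    rs_src = slice(max(0, -r0), h - max(0, r0))
    cs_src = slice(max(0, -c0), w - max(0, c0))
    rs_dst = slice(max(0, r0), h - max(0, -r0))
    cs_dst = slice(max(0, c0), w - max(0, -c0))
    out[rs_dst, cs_dst] = pix[rs_src, cs_src]
    aligned = StormImage(out, roi=image_b.roi.copy() if isinstance(image_b, StormImage) else None)
    return {"aligned": aligned, "shift": (int(shift[0]), int(shift[1])), "warning": warning,
            "spread": spread}


def cross_correlation(image_a: StormImage, image_b: StormImage, max_radius: int | None = None) -> CrossCorrelation:
    """Pair cross-correlation of two binary channels on a shared ROI.

    Both channels must share the grid and ROI.  The result grid has
    displacement (0, 0) at ``center``; ``radial_*`` hold the 1-px-wide
    radial average of c over displacements with N(r) > 0.
    """
    if image_a.pixels.shape != image_b.pixels.shape:
        raise ValueError("images must share the pixel grid")
    if not np.array_equal(image_a.roi, image_b.roi):
        raise ValueError("images must share the ROI mask")
    rho_a, rho_b = image_a.density, image_b.density
    if rho_a == 0 or rho_b == 0:
        raise ValueError("zero signal density")

    roi = image_a.roi.astype(float)
    a = image_a.pixels.astype(float) * roi
    b = image_b.pixels.astype(float) * roi
    h, w = a.shape
    H, W = 2 * h, 2 * w  # zero-pad to avoid circular wrap

    fa = np.fft.fft2(a, s=(H, W))
    fb = np.fft.fft2(b, s=(H, W))
    fr = np.fft.fft2(roi, s=(H, W))
    raw = np.real(np.fft.ifft2(fa * np.conj(fb)))
    nr = np.real(np.fft.ifft2(fr * np.conj(fr)))
    raw = np.fft.fftshift(raw)
    nr = np.fft.fftshift(nr)
    nr = np.where(nr > 0.5, np.round(nr), 0.0)  # integer overlap counts

    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(nr > 0, raw / (rho_a * rho_b * np.where(nr > 0, nr, 1.0)), np.nan)
    center = (H // 2, W // 2)

    rr, cc = np.indices(c.shape)
    rad = np.hypot(rr - center[0], cc - center[1])
    rmax = max_radius if max_radius is not None else min(h, w) // 2
    nbin = int(rmax) + 1
    radial_c = np.full(nbin, np.nan)
    radial_counts = np.zeros(nbin, dtype=int)
    valid = nr > 0
    bins = np.floor(rad + 0.5).astype(int)  # bin 0 = |r| in [0, 0.5)
    for k in range(nbin):
        m = valid & (bins == k)
        radial_counts[k] = int(m.sum())
        if radial_counts[k]:
            radial_c[k] = float(np.nanmean(c[m]))
    return CrossCorrelation(c=c, n=nr, center=center,
                            radial_r=np.arange(nbin, dtype=float),
                            radial_c=radial_c, radial_counts=radial_counts)


def coloc_ratios(image_a: StormImage, image_b: StormImage) -> dict:
    """Pixel-by-pixel colocalization percentages between aligned channels."""
    if image_a.pixels.shape != image_b.pixels.shape:
        raise ValueError("images must share the pixel grid")
    on_a = image_a.pixels.astype(bool)
    on_b = image_b.pixels.astype(bool)
    na, nb = int(on_a.sum()), int(on_b.sum())
    if na == 0 or nb == 0:
        raise ValueError("a channel has no signal")
    shared = int((on_a & on_b).sum())
    return {
        "percent_a_with_b": 100.0 * shared / na,
        "percent_b_with_a": 100.0 * shared / nb,
        "n_shared": shared, "n_a": na, "n_b": nb,
    }
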