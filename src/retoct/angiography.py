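"""OCT angiography: complex-difference motion contrast, plexus en-face maps,
vessel binarization, and density / Weber-contrast quantification.

Repeated B-scans at the same location decorrelate only where scatterers move
(blood flow).  After removing the global (bulk) phase offset between repeats,
the angiogram is the averaged magnitude of the complex differences between
consecutive repeats.  En-face maps are maximum-intensity projections over the
superficial vascular plexus (a slab below the ILM) and the deep capillary
plexus (a slab above the posterior OPL).  Binarization follows CLAHE ->
Otsu -> morphological opening/closing (disk radius 1) -> skeletonization ->
5x5 square averaging, any positive response marking a vessel pixel.

Vessel density is the percentage of vessel pixels inside the peripapillary
annulus (whole / superior / inferior); the modified Weber contrast
C_W = (Iv - Ib) / Ib audits the raw angiogram intensity of vessel pixels
against the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, filters, morphology

from .config import AngioConfig
from .errors import ExclusionError, NoContrastError, VolumeValidationError
from .io import OCTVolume
from .layers import AnnulusMask, LayerMap

__all__ = [
    "AngioBscan",
    "AngioEnface",
    "VesselMetrics",
    "bulk_phase_correct",
    "compute_octa",
    "octa_volume",
    "enface_projection",
    "binarize_vessels",
    "vessel_density",
    "weber_contrast",
]


@dataclass
class AngioBscan:
    """Decorrelation image of one B-scan location."""

    decorrelation: np.ndarray        # (x, z), >= 0
    n_pairs: int
    excluded_repeats: list[int] = field(default_factory=list)


@dataclass
class AngioEnface:
    """All intermediates of the binarization pipeline for one plexus."""

    plexus: str
    raw: np.ndarray
    equalized: np.ndarray
    binary: np.ndarray
    skeleton: np.ndarray
    final: np.ndarray


@dataclass
class VesselMetrics:
    plexus: str
    density_whole_pct: float
    density_superior_pct: float
    density_inferior_pct: float
    weber_contrast: float
    mean_vessel_intensity: float
    mean_background_intensity: float


def bulk_phase_correct(
    repeats: np.ndarray, config: AngioConfig | None = None
) -> tuple[np.ndarray, list[int]]:
    """Remove the global phase offset between repeats and screen out repeats
    with uncorrectable motion.

    ``repeats`` is complex ``(n_repeats, x, z)`` for one B-scan location.
    For each adjacent pair the bulk phase is the argument of
    sum(C_{i+1} * conj(C_i)); repeat i+1 is rotated by its conjugate.  A
    repeat whose mean normalized complex difference against the pixel-wise
    median repeat exceeds ``exclusion_threshold`` is dropped.  Fewer than two
    surviving repeats raises :class:`ExclusionError` (the B-scan is excluded,
    mirroring manual screening of motion-corrupted data).

    Returns ``(corrected retained repeats, excluded repeat indices)``.
    """
    cfg = config or AngioConfig()
    reps = np.asarray(repeats)
    if reps.ndim != 3 or reps.shape[0] < 2:
        raise VolumeValidationError("need a (n_repeats >= 2, x, z) complex stack")
    corrected = reps.astype(np.complex64).copy()
    for i in range(reps.shape[0] - 1):
        inner = np.vdot(corrected[i], corrected[i + 1])  # sum conj(C_i) * C_{i+1}
        phi = np.angle(inner)
        corrected[i + 1] = corrected[i + 1] * np.exp(np.complex64(-1j * phi))

    median = np.median(corrected.real, axis=0) + 1j * np.median(corrected.imag, axis=0)
    scale = np.abs(median).mean() + 1e-12
    excluded: list[int] = []
    for i in range(corrected.shape[0]):
        score = np.abs(corrected[i] - median).mean() / scale
        if score > cfg.exclusion_threshold:
            excluded.append(i)
    retained = [i for i in range(corrected.shape[0]) if i not in excluded]
    if len(retained) < 2:
        raise ExclusionError(
            f"B-scan excluded: only {len(retained)} repeats survive motion screening"
        )
    return corrected[retained], excluded


def compute_octa(corrected_repeats: np.ndarray) -> AngioBscan:
    """Averaged magnitude of complex differences between consecutive repeats."""
    reps = np.asarray(corrected_repeats)
    if reps.shape[0] < 2:
        raise VolumeValidationError("need at least 2 retained repeats")
    diffs = np.abs(np.diff(reps, axis=0))
    return AngioBscan(
        decorrelation=diffs.mean(axis=0).astype(np.float32),
        n_pairs=reps.shape[0] - 1,
    )


def octa_volume(
    volume: OCTVolume, config: AngioConfig | None = None
) -> tuple[np.ndarray, list[AngioBscan]]:
    """Bulk-phase-correct and compute OCTA for every B-scan location.

    Uses the combined (co + i-independent cross) signal by operating on the
    co-polarized channel, which carries the bulk of the amplitude.  Excluded
    B-scans get a zero decorrelation image and are flagged in the returned
    records.
    """
    cfg = config or AngioConfig()
    nr, ny, nx, nz = volume.shape
    out = np.zeros((ny, nx, nz), dtype=np.float32)
    records: list[AngioBscan] = []
    for y in range(ny):
        try:
            reps, excl = bulk_phase_correct(volume.co_channel[:, y], cfg)
            b = compute_octa(reps)
            b.excluded_repeats = excl
        except ExclusionError:
            b = AngioBscan(
                decorrelation=np.zeros((nx, nz), np.float32),
                n_pairs=0,
                excluded_repeats=list(range(nr)),
            )
        out[y] = b.decorrelation
        records.append(b)
    return out, records


def enface_projection(
    octa: np.ndarray,
    layer_map: LayerMap,
    plexus: str,
    config: AngioConfig | None = None,
) -> np.ndarray:
    """Maximum-intensity en-face projection over one plexus slab.

    SVP slab: [ILM, ILM + svp_slab_um]; DCP slab:
    [posterior OPL - dcp_slab_um, posterior OPL].
    """
    cfg = config or AngioConfig()
    ny, nx, nz = octa.shape
    pitch = layer_map.axial_pitch_um
    if plexus == "SVP":
        z0 = layer_map.ilm_px
        z1 = layer_map.ilm_px + cfg.svp_slab_um / pitch
    elif plexus == "DCP":
        z0 = layer_map.opl_px - cfg.dcp_slab_um / pitch
        z1 = layer_map.opl_px
    else:
        raise ValueError(f"unknown plexus {plexus!r}")
    lo = np.clip(np.floor(z0).astype(int), 0, nz - 1)
    hi = np.clip(np.ceil(z1).astype(int), 0, nz - 1)
    if (hi <= lo).all():
        raise VolumeValidationError("empty projection slab")
    zz = np.arange(nz)[None, None, :]
    slab = (zz >= lo[:, :, None]) & (zz <= hi[:, :, None])
    return np.where(slab, octa, -np.inf).max(axis=2).astype(np.float32)


def binarize_vessels(
    raw: np.ndarray, plexus: str = "SVP", config: AngioConfig | None = None
) -> AngioEnface:
    """CLAHE -> Otsu -> open/close (disk 1) -> skeletonize -> 5x5 averaging.

    The final binary map marks every pixel with a positive response of the
    square averaging filter applied to the skeleton (equivalently, the
    skeleton dilated by a 5x5 square).
    """
    cfg = config or AngioConfig()
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise VolumeValidationError("empty image")
    lo, hi = float(raw.min()), float(raw.max())
    if hi <= lo:
        raise NoContrastError("no contrast: image is constant")
    norm = (raw - lo) / (hi - lo)
    kernel = max(2, min(norm.shape) // cfg.clahe_tiles)
    eq = exposure.equalize_adapthist(
        norm, kernel_size=kernel, clip_limit=cfg.clahe_clip_limit
    )
    thr = filters.threshold_otsu(eq)
    bw = eq > thr
    selem = morphology.disk(cfg.morph_radius_px)
    bw = morphology.closing(morphology.opening(bw, selem), selem)
    skel = morphology.skeletonize(bw)
    k = cfg.mean_filter_px
    response = ndimage.uniform_filter(skel.astype(float), size=k, mode="constant")
    # "> 0" up to float fuzz: any skeleton pixel in the k x k window counts
    final = response > 0.5 / (k * k)
    return AngioEnface(
        plexus=plexus, raw=raw, equalized=eq, binary=bw, skeleton=skel, final=final
    )


def vessel_density(
    final_map: np.ndarray, annulus: AnnulusMask
) -> tuple[float, float, float]:
    """Percentage of vessel pixels in the whole/superior/inferior annulus."""
    if final_map.shape != annulus.annulus.shape:
        raise VolumeValidationError("vessel map and annulus shapes differ")
    out = []
    for region in ("whole", "superior", "inferior"):
        sel = annulus.region(region)
        n = int(sel.sum())
        if n == 0:
            raise VolumeValidationError(f"empty {region} region")
        out.append(100.0 * float(final_map[sel].sum()) / n)
    return tuple(out)  # type: ignore[return-value]


def weber_contrast(
    raw: np.ndarray, final_map: np.ndarray, annulus: AnnulusMask
) -> tuple[float, float, float]:
    """Modified Weber contrast C_W = (Iv - Ib) / Ib inside the annulus.

    Iv and Ib are the mean raw en-face intensities over vessel and non-vessel
    annulus pixels.  Returns ``(C_W, Iv, Ib)``.
    """
    sel = annulus.annulus
    vess = sel & final_map.astype(bool)
    back = sel & ~final_map.astype(bool)
    if not vess.any() or not back.any():
        raise VolumeValidationError("need both vessel and background pixels in the annulus")
    iv = float(raw[vess].mean())
    ib = float(raw[back].mean())
    if ib == 0:
        raise VolumeValidationError("background intensity is zero")
    return (iv - ib) / ib, iv, ib


def quantify_plexus(
    raw: np.ndarray,
    annulus: AnnulusMask,
    plexus: str,
    config: AngioConfig | None = None,
) -> tuple[VesselMetrics, AngioEnface]:
    """Full quantification of one plexus en-face image."""
    ef = binarize_vessels(raw, plexus=plexus, config=config)
    dw, ds, di = vessel_density(ef.final, annulus)
    cw, iv, ib = weber_contrast(raw, ef.final, annulus)
    return (
        VesselMetrics(
            plexus=plexus,
            density_whole_pct=dw,
            density_superior_pct=ds,
            density_inferior_pct=di,
            weber_contrast=cw,
            mean_vessel_intensity=iv,
            mean_background_intensity=ib,
        ),
        ef,
    )
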