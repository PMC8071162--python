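"""End-to-end convenience pipeline: slice -> segmentation -> scores.

Chains the processing stages the way the interactive workflow does:
bias-corrected level-set segmentation inside a rough user region,
contour extraction, parenchymal ROI scoring (L_Het), surface-segment
scoring (L_Nod) and the combined product. Mostly used for phantom
studies and reproducibility checks; clinical use drives the individual
modules (ROI and segment choice are user decisions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contour import Contour, SurfaceSegment, extract_contour, select_segment
from .heterogeneity import HetResult, lhet_score
from .image import BinaryMask, Image2D
from .lic_levelset import LevelSetParams, SegmentationResult, correct_bias, segment_liver
from .nodularity import NodResult, lnod_score
from .phantom import PhantomSpec, generate_phantom, sample_circular_rois
from .scoring import SubjectScores, make_subject_scores


@dataclass
class PipelineResult:
    image: Image2D
    segmentation: SegmentationResult
    corrected: Image2D
    contour: Contour
    segments: list[SurfaceSegment]
    het: HetResult
    nod: NodResult
    scores: SubjectScores


def equispaced_segments(
    contour: Contour, n_segments: int, fraction: float = 1.0 / 8.0
) -> list[SurfaceSegment]:
    """Cut ``n_segments`` open segments of ``fraction`` of the contour,
    with start points spread evenly around it."""
    n = len(contour)
    span = max(2, int(round(fraction * n)))
    starts = (np.arange(n_segments) * n) // n_segments
    return [select_segment(contour, int(s), int((s + span) % n)) for s in starts]


def default_init_mask(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> BinaryMask:
    """Rough circular user ROI centred on the organ."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return BinaryMask((rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2)


def run_phantom_pipeline(
    spec: PhantomSpec,
    roi_seed: int = 0,
    n_rois: int = 5,
    roi_area_px: int = 40,
    n_segments: int = 3,
    poly_order: int = 3,
    levelset_params: LevelSetParams | None = None,
    subject_id: str = "phantom",
) -> PipelineResult:
    """Generate a phantom and push it through the full scoring chain.

    Deterministic given ``spec`` (which carries the noise seed) and
    ``roi_seed``. ROIs are sampled inside the *segmented* mask eroded
    against the truth-free workflow; segments are equispaced along the
    extracted contour.
    """
    image, truth = generate_phantom(spec)
    min_radius_px = min(
        spec.liver_radii_mm[0] / spec.spacing_mm[1], spec.liver_radii_mm[1] / spec.spacing_mm[0]
    )
    init = default_init_mask(spec.shape, spec.liver_center, 0.6 * min_radius_px)
    seg = segment_liver(image, init, levelset_params)
    corrected = correct_bias(image, seg.bias)
    cont = extract_contour(seg.mask, spacing_mm=spec.spacing_mm)
    segments = equispaced_segments(cont, n_segments)
    # a truth object whose mask is the *segmented* liver, for ROI placement
    from dataclasses import replace

    placement_truth = replace(truth, mask=seg.mask)
    rois = sample_circular_rois(placement_truth, n=n_rois, area_px=roi_area_px, seed=roi_seed)
    het = lhet_score(corrected, seg.mask, rois)
    nod = lnod_score(segments, order=poly_order)
    scores = make_subject_scores(
        subject_id, lhet=het.lhet_score, lnod=nod.lnod_score, n_measurements=1
    )
    return PipelineResult(
        image=image,
        segmentation=seg,
        corrected=corrected,
        contour=cont,
        segments=segments,
        het=het,
        nod=nod,
        scores=scores,
    )


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|)."""
    ga = a.grid if isinstance(a, BinaryMask) else np.asarray(a, bool)
    gb = b.grid if isinstance(b, BinaryMask) else np.asarray(b, bool)
    denom = ga.sum() + gb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(ga, gb).sum() / denom)
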