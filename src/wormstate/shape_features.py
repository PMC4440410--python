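"""Per-frame worm-silhouette shape descriptors and omega-turn classification.

A crawling worm is an elongated, sinusoid silhouette; during an omega turn
the body curls into a nearly closed ring (the posture resembles the letter
Omega).  Three dimensionless descriptors separate the two posture families:

* eccentricity of the ellipse with the same second moments as the mask —
  high for elongated bodies, low for curled ones;
* compactness, perimeter**2 / area — minimized (4*pi) by a disk, large for
  thin elongated shapes;
* solidity, area / convex-hull area — a curled body fills its hull much
  better than a sinusoid does.

A frame is called an omega turn when

    (eccentricity < 0.8  OR  compactness < 30)  AND  solidity > 0.575

with strict inequalities.  All three thresholds are exposed in
:class:`OmegaThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

__all__ = [
    "FrameShape",
    "OmegaThresholds",
    "FrameShapeConfig",
    "shape_descriptors",
    "is_omega_frame",
    "omega_flags_for_movie",
    "descriptor_table",
]


@dataclass(frozen=True)
class FrameShape:
    """Shape descriptors of a single-component binary worm mask."""

    area: float
    perimeter: float
    eccentricity: float
    compactness: float
    solidity: float
    centroid: tuple[float, float]  # (x, y) in pixel coordinates


@dataclass(frozen=True)
class OmegaThresholds:
    """Decision thresholds of the omega-turn rule (strict inequalities)."""

    ecc_max: float = 0.8
    compact_max: float = 30.0
    solidity_min: float = 0.575

    def __post_init__(self) -> None:
        if not (self.ecc_max > 0 and self.compact_max > 0 and 0 < self.solidity_min < 1):
            raise ValueError("thresholds must be positive, solidity_min < 1")


@dataclass(frozen=True)
class FrameShapeConfig:
    """Estimator and rule conventions.

    perimeter_method
        ``"crofton"`` (default): 4-direction Crofton-formula perimeter,
        which converges to the continuous boundary length under refinement.
        ``"weighted_steps"``: classical weighted boundary-step estimator
        (diagonal steps count sqrt(2)); simpler but systematically long on
        smooth boundaries.
    eccentricity_mode
        ``"standard"`` (default): focal distance over major axis of the
        second-moment ellipse, in [0, 1); small for compact shapes, so the
        ``< ecc_max`` branch selects curled postures.  ``"axis_ratio"``:
        minor/major axis ratio, the literal alternative convention.
    rule
        ``"disjunctive"`` (default): (ecc OR compactness) AND solidity.
        ``"conjunctive"``: ecc AND compactness AND solidity.
    """

    perimeter_method: str = "crofton"
    eccentricity_mode: str = "standard"
    rule: str = "disjunctive"
    thresholds: OmegaThresholds = field(default_factory=OmegaThresholds)

    def __post_init__(self) -> None:
        if self.perimeter_method not in ("crofton", "weighted_steps"):
            raise ValueError(f"unknown perimeter_method {self.perimeter_method!r}")
        if self.eccentricity_mode not in ("standard", "axis_ratio"):
            raise ValueError(f"unknown eccentricity_mode {self.eccentricity_mode!r}")
        if self.rule not in ("disjunctive", "conjunctive"):
            raise ValueError(f"unknown rule {self.rule!r}")


def _perimeter(mask: np.ndarray, method: str) -> float:
    if method == "crofton":
        return float(measure.perimeter_crofton(mask, directions=4))
    return float(measure.perimeter(mask, neighborhood=4))


def shape_descriptors(
    mask: np.ndarray, config: FrameShapeConfig | None = None
) -> FrameShape:
    """Compute :class:`FrameShape` descriptors of a binary mask.

    The mask must contain exactly one connected foreground component
    (8-connectivity); empty or fragmented masks are rejected because their
    descriptors would be meaningless for a single animal.
    """
    config = config or FrameShapeConfig()
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask: no foreground pixels")
    _, n_comp = ndimage.label(mask, structure=np.ones((3, 3), int))
    if n_comp != 1:
        raise ValueError(
            f"mask has {n_comp} connected components; expected exactly one worm"
        )
    props = measure.regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    perim = _perimeter(mask, config.perimeter_method)
    if config.eccentricity_mode == "standard":
        ecc = float(props.eccentricity)
    else:
        major = props.axis_major_length
        ecc = float(props.axis_minor_length / major) if major > 0 else 1.0
    cy, cx = props.centroid
    return FrameShape(
        area=area,
        perimeter=perim,
        eccentricity=ecc,
        compactness=perim**2 / area,
        solidity=float(props.solidity),
        centroid=(float(cx), float(cy)),
    )


def is_omega_frame(
    shape: FrameShape,
    thresholds: OmegaThresholds | None = None,
    rule: str = "disjunctive",
) -> bool:
    """Apply the omega-turn posture rule to one frame's descriptors."""
    th = thresholds or OmegaThresholds()
    ecc_ok = shape.eccentricity < th.ecc_max
    comp_ok = shape.compactness < th.compact_max
    sol_ok = shape.solidity > th.solidity_min
    if rule == "conjunctive":
        return ecc_ok and comp_ok and sol_ok
    return (ecc_ok or comp_ok) and sol_ok


def omega_flags_for_movie(
    masks, config: FrameShapeConfig | None = None
) -> np.ndarray:
    """Classify every frame of a mask movie; returns a boolean array."""
    config = config or FrameShapeConfig()
    flags = np.empty(len(masks), bool)
    for i, mask in enumerate(masks):
        shape = shape_descriptors(mask, config)
        flags[i] = is_omega_frame(shape, config.thresholds, config.rule)
    return flags


def descriptor_table(masks, config: FrameShapeConfig | None = None) -> pd.DataFrame:
    """Per-frame descriptor table (frame, area, perimeter, eccentricity,
    compactness, solidity, omega_flag) for a mask movie."""
    config = config or FrameShapeConfig()
    rows = []
    for i, mask in enumerate(masks):
        s = shape_descriptors(mask, config)
        rows.append(
            {
                "frame": i,
                "area": s.area,
                "perimeter": s.perimeter,
                "eccentricity": s.eccentricity,
                "compactness": s.compactness,
                "solidity": s.solidity,
                "omega_flag": is_omega_frame(s, config.thresholds, config.rule),
            }
        )
    return pd.DataFrame(rows)
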