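"""Diagnostic regions and the (T, S) feature vector.

Aggressive posterior disease manifests near the optic disc, so features
are computed inside OD-anchored regions whose sizes are multiples of the
OD radius — which makes them comparable across images acquired at
different scales:

* ``DR1``  — disk of 4 OD radii about the OD centroid;
* ``EDR1`` — disk of 6 OD radii (vessels arch at roughly 4 radii, and
  arching at the DR1 boundary would spuriously inflate tortuosity there;
  the extended disk absorbs that);
* ``DR2``  — annulus from 4 to 8 OD radii (peripheral activity;
  computed and reported for observation, never fed to the classifier).

Per region, the feature vector is the tortuosity index T — the mean of
the top quartile of per-segment arc/chord ratios — and the segment count
S, a proxy for branching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ODGeometry
from .skeleton import SegmentSet, VesselSegment

__all__ = [
    "RegionSpec",
    "REGIONS",
    "FeatureVector",
    "region_mask",
    "assign_to_region",
    "segment_tortuosity",
    "image_tortuosity",
    "segment_count",
    "compute_region_features",
    "features_to_frame",
    "FEATURE_SCHEMA_VERSION",
]

FEATURE_SCHEMA_VERSION = "1"

#: Loop segments have zero chord; they are strong tortuosity signals and
#: are scored at this configurable cap instead of infinity.
DEFAULT_LOOP_CAP = 10.0


@dataclass(frozen=True)
class RegionSpec:
    """An annular diagnostic region in units of the OD radius."""

    name: str
    inner_mult: float
    outer_mult: float

    def __post_init__(self) -> None:
        if not 0 <= self.inner_mult < self.outer_mult:
            raise ValueError("require 0 <= inner_mult < outer_mult")


REGIONS: dict[str, RegionSpec] = {
    "DR1": RegionSpec("DR1", 0.0, 4.0),
    "EDR1": RegionSpec("EDR1", 0.0, 6.0),
    "DR2": RegionSpec("DR2", 4.0, 8.0),
}


@dataclass
class FeatureVector:
    """Per-image, per-region classifier input."""

    image_id: str
    region: str
    T: float          # NaN when the region holds no open segment
    S: int
    n: int            # segments entering the top-quartile mean
    label: str | None = None
    method: str = ""


def region_mask(spec: RegionSpec, od: ODGeometry, eye_mask: np.ndarray,
                od_mask: np.ndarray) -> np.ndarray:
    """Rasterize one diagnostic annulus, minus the OD, within the eye."""
    rr, cc = np.ogrid[: eye_mask.shape[0], : eye_mask.shape[1]]
    r0, c0 = od.centroid
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    lo = (spec.inner_mult * od.radius) ** 2
    hi = (spec.outer_mult * od.radius) ** 2
    annulus = (d2 >= lo) & (d2 < hi)
    return annulus & eye_mask & ~od_mask


def assign_to_region(segments: SegmentSet, mask: np.ndarray) -> SegmentSet:
    """Keep segments with at least half their chain pixels inside the mask.

    The 50% majority rule is inclusive: a segment with exactly half its
    pixels inside counts as inside.
    """
    kept = []
    for seg in segments.segments:
        inside = mask[seg.chain[:, 0], seg.chain[:, 1]]
        if inside.sum() * 2 >= len(seg.chain):
            kept.append(seg)
    from dataclasses import replace
    return replace(segments, segments=kept)


def segment_tortuosity(seg: VesselSegment, mode: str = "arc_chord",
                       loop_cap: float = DEFAULT_LOOP_CAP) -> float:
    """Per-segment tortuosity index.

    ``arc_chord`` (default): arc length over chord length, >= 1 with
    equality exactly for collinear chains.  ``literal``: pixel count over
    squared chord length, provided for comparison with the index's other
    published rendering (its scale depends on segment length and it is
    not bounded below by 1).

    Closed loops (coincident endpoints, zero chord) receive ``loop_cap``,
    and every reported tortuosity is clamped at the same cap: a segment
    that curls back to nearly its own start is the open-segment limit of
    a loop, and an uncapped ratio (tens to hundreds) would let a single
    such segment dominate the image-level top-quartile mean.
    """
    if seg.closed or seg.chord_len == 0.0:
        return float(loop_cap)
    if mode == "arc_chord":
        t = seg.arc_len / seg.chord_len
    elif mode == "literal":
        t = seg.n_pixels / seg.chord_len**2
    else:
        raise ValueError(f"unknown tortuosity mode {mode!r}")
    return float(min(t, loop_cap))


def image_tortuosity(tortuosities, percentile: float = 75.0,
                     top_quartile_mean: bool = True) -> float:
    """Region-level T: mean of the tortuosities at or above the percentile.

    The percentile uses numpy's linear-interpolation convention; e.g. for
    {1.0, 1.1, 1.2, 2.0} the 75th percentile is 1.4 and T = 2.0.  With
    ``top_quartile_mean=False`` the interpolated percentile value itself
    is returned.
    """
    t = np.asarray(list(tortuosities), dtype=float)
    if t.size == 0:
        return float("nan")
    p = np.percentile(t, percentile)
    if not top_quartile_mean:
        return float(p)
    return float(t[t >= p].mean())


def segment_count(segments: SegmentSet) -> int:
    """S: the number of segments assigned to the region."""
    return len(segments.segments)


def compute_region_features(segments: SegmentSet, od: ODGeometry,
                            eye_mask: np.ndarray, od_mask: np.ndarray,
                            image_id: str = "", label: str | None = None,
                            mode: str = "arc_chord",
                            loop_cap: float = DEFAULT_LOOP_CAP,
                            percentile: float = 75.0,
                            regions: dict[str, RegionSpec] | None = None
                            ) -> list[FeatureVector]:
    """(T, S) per diagnostic region for one image."""
    regions = regions or REGIONS
    out = []
    for spec in regions.values():
        mask = region_mask(spec, od, eye_mask, od_mask)
        assigned = assign_to_region(segments, mask)
        torts = [segment_tortuosity(s, mode=mode, loop_cap=loop_cap)
                 for s in assigned.segments]
        T = image_tortuosity(torts, percentile=percentile)
        n_top = int(np.sum(np.asarray(torts) >= np.percentile(torts, percentile))) if torts else 0
        out.append(FeatureVector(image_id=image_id, region=spec.name, T=T,
                                 S=segment_count(assigned), n=n_top,
                                 label=label, method=segments.source_method))
    return out


def features_to_frame(features: list[FeatureVector]) -> pd.DataFrame:
    """Stack FeatureVectors into the canonical feature table."""
    return pd.DataFrame(
        [{"image_id": f.image_id, "label": f.label, "region": f.region,
          "T": f.T, "S": f.S, "n_segments": f.n, "method": f.method}
         for f in features]
    )
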