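"""Per-photo Sargassum coverage from a label mask.

Coverage is the Sargassum share of the *beach* pixels only: Other
pixels (sky, sea, vegetation, ...) are discarded, the Sargassum + Sand
pixel count is taken as 100 %, and

    coverage_pct = 100 * n_sargassum / (n_sargassum + n_sand).

A mask with no beach pixels at all yields an undefined coverage
(``None``), as does a mask whose beach fraction falls below
``min_beach_fraction`` — a proxy for the uninformative close-up photos
that are excluded from mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_dataset import Label, LabelMask

__all__ = ["CoverageResult", "coverage"]


@dataclass
class CoverageResult:
    image_id: str
    n_sargassum: int
    n_sand: int
    n_other: int
    coverage_pct: float | None

    @property
    def defined(self) -> bool:
        return self.coverage_pct is not None


def coverage(
    mask: LabelMask, image_id: str = "", min_beach_fraction: float = 0.05
) -> CoverageResult:
    """Count pixels per class and derive the coverage percentage.

    ``min_beach_fraction`` is the minimum (Sargassum + Sand) share of the
    image below which the result is marked undefined; set it to 0 to
    disable the exclusion. Undefined is a value, not an error.
    """
    if mask.labels.size == 0:
        raise ValueError("empty mask")
    counts = mask.counts()
    n_sarg = counts[Label.SARGASSUM]
    n_sand = counts[Label.SAND]
    n_other = counts[Label.OTHER]
    beach = n_sarg + n_sand
    total = mask.labels.size
    if beach == 0 or beach / total < min_beach_fraction:
        pct = None
    else:
        pct = 100.0 * n_sarg / beach
    return CoverageResult(
        image_id=image_id,
        n_sargassum=n_sarg,
        n_sand=n_sand,
        n_other=n_other,
        coverage_pct=pct,
    )
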