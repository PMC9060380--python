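"""Distance/age-indexed otolith profiles from corrected runs.

A corrected run (time-indexed) becomes an :class:`OtolithProfile`: cropped
core-to-edge, positions re-zeroed at the core, ⁸⁸Sr volts converted to Sr
concentration through the FEBs-1 standard, ratios optionally shifted onto
the global marine value, and a continuous age axis interpolated through the
annuli.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as C
from .reduction import RawAblationRun, ValidationError
from .classify import ClassifierConfig

log = logging.getLogger(__name__)

QUALITY_FLAGS = ("ok", "cracked", "excluded")


@dataclass(frozen=True)
class OtolithProfile:
    """Corrected ⁸⁷Sr/⁸⁶Sr transect indexed by distance from the core."""

    positions_um: np.ndarray
    ratio: np.ndarray
    v88: np.ndarray
    sr_mgkg: np.ndarray
    annuli_um: np.ndarray
    age: np.ndarray
    quality_flag: str = "ok"
    otolith_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arrays = (self.ratio, self.v88, self.sr_mgkg, self.age)
        n = len(self.positions_um)
        if any(len(a) != n for a in arrays):
            raise ValidationError("profile arrays must have equal length")
        if n == 0:
            raise ValidationError("profile is empty")
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValidationError("positions_um must be strictly increasing")
        ann = np.asarray(self.annuli_um, float)
        if len(ann) and (np.any(np.diff(ann) <= 0) or ann[0] <= 0
                         or ann[-1] >= self.positions_um[-1] + 1e-9):
            raise ValidationError(
                "annuli_um must be strictly increasing within (0, max position)")
        if np.any(np.diff(self.age) < -1e-9):
            raise ValidationError("age must be non-decreasing with position")
        if self.quality_flag not in QUALITY_FLAGS:
            raise ValidationError(f"quality_flag must be one of {QUALITY_FLAGS}")

    def __len__(self) -> int:
        return len(self.positions_um)


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of aligning a profile's marine plateau onto the GMV."""

    offset: float
    n_marine_points: int
    applied: bool


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def distance_to_age(positions_um: np.ndarray,
                    annuli_um: np.ndarray) -> np.ndarray:
    """Continuous age (years) from annulus positions.

    Piecewise linear through (0, 0) and (annulus_i, i); past the last
    annulus the last inter-annulus rate extrapolates, capped at one year
    beyond the last annulus (condensed outer annuli make further
    extrapolation unreliable).
    """
    ann = np.asarray(annuli_um, float)
    if len(ann) == 0:
        raise ValidationError("at least one annulus is required")
    if np.any(np.diff(ann) <= 0):
        raise ValidationError("annuli positions must be strictly increasing")
    if ann[0] <= 0:
        raise ValidationError("annuli must lie at positive positions")
    x = np.asarray(positions_um, float)
    nodes_x = np.concatenate([[0.0], ann])
    nodes_y = np.arange(len(ann) + 1, dtype=float)
    age = np.interp(x, nodes_x, nodes_y)
    last_rate = 1.0 / (ann[-1] - ann[-2]) if len(ann) > 1 else 1.0 / ann[-1]
    beyond = x > ann[-1]
    age[beyond] = np.minimum(len(ann) + (x[beyond] - ann[-1]) * last_rate,
                             len(ann) + 1.0)
    return age


def concentration_from_v88(v88, standard_mean_v88: float,
                           febs1_sr: float = C.FEBS1_SR_MGKG):
    """Otolith Sr (mg/kg) from the ⁸⁸Sr beam via the FEBs-1 standard.

    ``(febs1_sr / standard_mean_v88) × v88`` — linear in v88, anchored so
    the standard's own beam reads its certified concentration.
    """
    if standard_mean_v88 <= 0:
        raise ValidationError("standard_mean_v88 must be positive")
    v = np.asarray(v88, float)
    if np.any(v[np.isfinite(v)] < 0):
        raise ValidationError("v88 must be non-negative")
    out = (febs1_sr / standard_mean_v88) * v
    return float(out) if np.isscalar(v88) else out


def crop_profile(run: RawAblationRun, core_um: float, edge_um: float,
                 annuli_um: np.ndarray, quality_flag: str = "ok",
                 ) -> OtolithProfile:
    """Crop a reduced run from the estimated core to the edge.

    ``core_um``/``edge_um`` are distances along the ablation transect
    (elapsed ablation time × 5 µm/s); positions are re-zeroed at the core.
    ``annuli_um`` are measured from the core. Requires the run to carry the
    ``ratio_8786``/``v88_corrected`` columns added by the reduction chain.
    """
    if not (0 <= core_um < edge_um):
        raise ValidationError("need 0 <= core_um < edge_um")
    abl = run.ablation
    if "ratio_8786" not in abl.columns:
        raise ValidationError("run is not reduced (no ratio_8786 column); "
                              "run reduce_run first")
    dist = run.distances_um()
    if edge_um > dist[-1] + 1e-6:
        raise ValidationError(
            f"edge_um {edge_um} exceeds transect length {dist[-1]:.1f}")
    keep = (dist >= core_um - 1e-9) & (dist <= edge_um + 1e-9)
    if not keep.any():
        raise ValidationError("crop left no readings")
    pos = dist[keep] - core_um
    pos = pos - pos[0]
    ratio = abl["ratio_8786"].to_numpy(float)[keep]
    v88 = abl["v88_corrected"].to_numpy(float)[keep]
    febs1_v88 = run.meta.get("febs1_mean_v88")
    if febs1_v88:
        sr = concentration_from_v88(v88, febs1_v88)
    else:
        sr = np.full_like(v88, np.nan)
    ann = np.asarray(annuli_um, float)
    ann = ann[(ann > 0) & (ann < pos[-1])]
    age = distance_to_age(pos, ann)
    return OtolithProfile(
        positions_um=pos, ratio=ratio, v88=v88, sr_mgkg=sr,
        annuli_um=ann, age=age, quality_flag=quality_flag,
        otolith_id=str(run.meta.get("otolith_id", "")),
        meta={"core_um": float(core_um), "edge_um": float(edge_um)})


def _marine_run_mask(v88: np.ndarray, threshold: float,
                     min_run: int) -> np.ndarray:
    """Mask of readings inside runs of ≥ min_run consecutive v88 > threshold."""
    above = v88 > threshold
    mask = np.zeros_like(above)
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_run:
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


def gmv_align(profile: OtolithProfile,
              cfg: ClassifierConfig | None = None,
              ) -> tuple[OtolithProfile, AlignmentResult]:
    """Shift the ratio series so the marine plateau sits on the GMV.

    If at least one run of ``cfg.min_marine_points`` consecutive readings
    has v88 above the marine threshold, a single additive offset
    ``GMV − mean(ratio at those readings)`` is applied to the whole series
    (a pure shift: pairwise differences are preserved). Otherwise nothing
    changes. A multiplicative mode is available via ``cfg.align_mode``.
    After shifting, readings with sub-marine v88 that fall inside the GMV
    band are counted and logged (they should sit outside it).
    """
    cfg = cfg or ClassifierConfig()
    mask = _marine_run_mask(profile.v88, cfg.marine_threshold,
                            cfg.min_marine_points)
    n_marine = int(mask.sum())
    if n_marine == 0:
        return profile, AlignmentResult(0.0, 0, False)
    marine_mean = float(np.nanmean(profile.ratio[mask]))
    if cfg.align_mode == "multiplicative":
        factor = cfg.gmv / marine_mean
        new_ratio = profile.ratio * factor
        offset = factor - 1.0
    else:
        offset = cfg.gmv - marine_mean
        new_ratio = profile.ratio + offset
    inside = (~mask) & (np.abs(new_ratio - cfg.gmv) <= cfg.gmv_tol) \
        & np.isfinite(new_ratio)
    if inside.any():
        log.warning("%s: %d sub-marine reading(s) fall inside the GMV band "
                    "after alignment", profile.otolith_id, int(inside.sum()))
    aligned = replace(profile, ratio=new_ratio,
                      meta={**profile.meta, "gmv_offset": float(offset)})
    return aligned, AlignmentResult(float(offset), n_marine, True)


def flag_ratio_jumps(profile: OtolithProfile, jump: float = 0.002,
                     span: int = 3) -> np.ndarray:
    """Flag candidate crack artifacts: |Δratio| > ``jump`` within ``span``.

    Purely advisory — mirrors a visual crack screen. Returns a boolean mask;
    nothing is deleted.
    """
    r = profile.ratio
    flags = np.zeros(len(r), bool)
    for lag in range(1, span + 1):
        d = np.abs(r[lag:] - r[:-lag])
        hit = np.where(np.isfinite(d) & (d > jump))[0]
        flags[hit] = True
        flags[hit + lag] = True
    return flags
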