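"""Rule-based life-history classification of ⁸⁷Sr/⁸⁶Sr transects.

Habitat occupancy is read from the corrected ⁸⁸Sr beam (a salinity proxy):
below 6.13 V freshwater, between 6.13 and 12.26 V estuarine, above 12.26 V
marine, with a persistence filter so single noisy readings never flip a
state. Ratio criteria are evaluated on the penalized-spline fit. Each
otolith is assigned exactly one of six types:

1. early marine anadromous — first marine entry before age 1;
2. late freshwater anadromous — freshwater age-0, entry at age ≥ 1;
3. late transitional anadromous — fresh + estuarine age-0, entry ≥ 1;
4. semi-anadromous — natal-region ratio already at the global marine value;
5. freshwater–estuarine nonanadromous — brackish use, never marine;
6. freshwater resident — freshwater throughout.

The natal-GMV check takes precedence over the entry-age branches, so a fish
whose earliest readable chemistry is marine-like is semi-anadromous even if
it later shows marine plateaus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as C
from .reduction import ValidationError

log = logging.getLogger(__name__)

STATES = ("freshwater", "estuarine", "marine")


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and tolerances of the habitat/type rules."""

    fw_threshold: float = C.FW_THRESHOLD_V
    marine_threshold: float = C.MARINE_THRESHOLD_V
    gmv: float = C.GMV
    gmv_tol: float = C.GMV_TOL
    #: regions are isotopically distinct when |Δ mean ratio| strictly
    #: exceeds this.
    distinct_delta: float = 0.00005
    #: consecutive readings required to accept a habitat state / entry run.
    min_state_run: int = 10
    #: maximum core zone searched for a maternally derived signal, µm.
    maternal_skip_um: float = 60.0
    #: "relatively constant" natal ratio: rolling SD of the fit at most this.
    stability_tol: float = 0.00003
    #: readings in the rolling-SD stability window.
    stability_window: int = 10
    #: consecutive supra-marine readings required before GMV alignment.
    min_marine_points: int = 10
    align_mode: str = "additive"

    def __post_init__(self) -> None:
        if not 0 < self.fw_threshold < self.marine_threshold:
            raise ValidationError("need 0 < fw_threshold < marine_threshold")
        if self.gmv_tol <= 0 or self.distinct_delta <= 0:
            raise ValidationError("gmv_tol and distinct_delta must be positive")
        if self.min_state_run < 1:
            raise ValidationError("min_state_run must be >= 1")


@dataclass(frozen=True)
class Region:
    """A natal or juvenile otolith region with its fitted-ratio statistics."""

    start_um: float
    end_um: float
    mean_ratio: float
    se_ratio: float
    kind: str
    n: int = 0

    def __post_init__(self) -> None:
        if self.start_um >= self.end_um:
            raise ValidationError("region start must precede its end")
        if self.kind not in ("natal", "juvenile"):
            raise ValidationError("region kind must be 'natal' or 'juvenile'")


@dataclass(frozen=True)
class LifeHistoryCall:
    """One otolith's classification outcome.

    ``status`` is ``"ok"`` for a classified fish and ``"undetermined"`` when
    a rule could not be evaluated (the reason is recorded); undetermined
    calls are excluded from cohort summaries.
    """

    otolith_id: str
    type_id: int | None
    entry_age: int | None
    natal: Region | None
    juvenile: Region | None
    habitat_states: list = field(default_factory=list)
    status: str = "ok"
    reason: str = ""
    truth_label: int | None = None

    def __post_init__(self) -> None:
        if self.status == "ok":
            if self.type_id not in (1, 2, 3, 4, 5, 6):
                raise ValidationError("classified call needs type_id in 1-6")
            if self.type_id in (1, 2, 3) and self.entry_age is None:
                raise ValidationError("anadromous types require entry_age")
            if self.type_id in (5, 6) and self.entry_age is not None:
                raise ValidationError("nonanadromous types cannot have entry_age")
            if self.type_id == 6 and any(s != "freshwater"
                                         for _, _, s in self.habitat_states):
                raise ValidationError("freshwater residents cannot leave freshwater")


# ---------------------------------------------------------------------------
# habitat states
# ---------------------------------------------------------------------------

def habitat_state(v88: float, cfg: ClassifierConfig | None = None) -> str:
    """Habitat read from a single ⁸⁸Sr voltage.

    Strict inequalities as the thresholds are stated: a boundary value
    (exactly 6.13 or 12.26 V) belongs to the lower state.
    """
    cfg = cfg or ClassifierConfig()
    if not np.isfinite(v88):
        raise ValidationError("v88 must be finite")
    if v88 > cfg.marine_threshold:
        return "marine"
    if v88 > cfg.fw_threshold:
        return "estuarine"
    return "freshwater"


def habitat_state_codes(v88: np.ndarray,
                        cfg: ClassifierConfig) -> np.ndarray:
    """Vectorized per-reading states as codes 0=fresh, 1=estuarine, 2=marine."""
    v = np.asarray(v88, float)
    if not np.all(np.isfinite(v)):
        raise ValidationError("v88 must be finite")
    return ((v > cfg.fw_threshold).astype(int)
            + (v > cfg.marine_threshold).astype(int))


def merged_state_runs(v88: np.ndarray, cfg: ClassifierConfig,
                      ) -> list[tuple[int, int, str]]:
    """Run-length encoded states after persistence filtering.

    Runs shorter than ``cfg.min_state_run`` are absorbed into their longer
    neighbour (ties and leading runs merge rightward), so brief excursions —
    a noisy spike, the maternally derived core zone — never register as a
    habitat shift. Returns ``(start, stop, state)`` index triples.
    """
    codes = habitat_state_codes(v88, cfg)
    runs: list[list[int]] = []
    for i, c in enumerate(codes):
        if runs and runs[-1][2] == c:
            runs[-1][1] = i + 1
        else:
            runs.append([i, i + 1, int(c)])
    changed = True
    while changed and len(runs) > 1:
        changed = False
        lengths = [r[1] - r[0] for r in runs]
        j = int(np.argmin(lengths))
        if lengths[j] < cfg.min_state_run:
            if j == 0:
                runs[1][0] = runs[0][0]
            elif j == len(runs) - 1:
                runs[-2][1] = runs[-1][1]
            else:
                left = runs[j - 1][1] - runs[j - 1][0]
                right = runs[j + 1][1] - runs[j + 1][0]
                if left >= right:
                    runs[j - 1][1] = runs[j][1]
                else:
                    runs[j + 1][0] = runs[j][0]
            del runs[j]
            # coalesce equal neighbours
            k = 0
            while k < len(runs) - 1:
                if runs[k][2] == runs[k + 1][2]:
                    runs[k][1] = runs[k + 1][1]
                    del runs[k + 1]
                else:
                    k += 1
            changed = True
    return [(r[0], r[1], STATES[r[2]]) for r in runs]


def _expand_runs(runs, n) -> np.ndarray:
    out = np.empty(n, dtype=object)
    for s, e, state in runs:
        out[s:e] = state
    return out


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

def _rolling_sd(fit: np.ndarray, window: int) -> np.ndarray:
    return (pd.Series(fit).rolling(window, center=True, min_periods=2)
            .std(ddof=1).to_numpy())


def _region_from_slice(profile, fit, start: int, stop: int,
                       kind: str) -> Region:
    vals = fit[start:stop]
    vals = vals[np.isfinite(vals)]
    n = len(vals)
    mean = float(np.mean(vals))
    se = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return Region(start_um=float(profile.positions_um[start]),
                  end_um=float(profile.positions_um[stop - 1]),
                  mean_ratio=mean, se_ratio=se, kind=kind, n=n)


def detect_natal_region(profile, smoothed,
                        cfg: ClassifierConfig | None = None) -> Region:
    """Locate the natal region: stable, freshwater, past any maternal zone.

    The search skips a leading core zone whose state disagrees with the
    first persistent state (a maternally derived marine-like signal),
    restricted to ``maternal_skip_um``. It then returns the earliest
    stretch of at least ``min_state_run`` readings before age 1 whose
    persistent state is freshwater and whose rolling fit SD stays within
    ``stability_tol``, extended while both conditions hold. If no
    freshwater window exists before age 1 (the semi-anadromous case), the
    earliest stable window of any state is used.
    """
    cfg = cfg or ClassifierConfig()
    fit = smoothed.fit
    n = len(profile)
    runs = merged_state_runs(profile.v88, cfg)
    states = _expand_runs(runs, n)
    codes = habitat_state_codes(profile.v88, cfg)

    start = 0
    first_state = runs[0][2]
    first_code = STATES.index(first_state)
    limit = int(np.searchsorted(profile.positions_um, cfg.maternal_skip_um))
    i = 0
    while i < min(limit, n - 2):
        if np.all(codes[i:i + 3] == first_code):
            break
        i += 1
    start = i

    roll = _rolling_sd(fit, cfg.stability_window)
    age0_end = int(np.searchsorted(profile.age, 1.0))
    stable = np.zeros(n, bool)
    ok = np.isfinite(roll) & (roll <= cfg.stability_tol)
    stable[:age0_end] = ok[:age0_end]
    stable[:start] = False

    for require_fresh in (True, False):
        cand = stable.copy()
        if require_fresh:
            cand &= states == "freshwater"
        # earliest run of >= min_state_run candidate readings
        i = start
        while i < age0_end:
            if cand[i]:
                j = i
                while j < age0_end and cand[j]:
                    j += 1
                if j - i >= cfg.min_state_run:
                    return _region_from_slice(profile, fit, i, j, "natal")
                i = j
            else:
                i += 1
    raise ValidationError(
        f"{profile.otolith_id}: no stable natal window before age 1")


def detect_juvenile_region(profile, natal: Region,
                           entry_position_um: float | None,
                           cfg: ClassifierConfig | None = None,
                           fit: np.ndarray | None = None) -> Region | None:
    """Freshwater age-0 rearing: natal end to first annulus or marine entry."""
    cfg = cfg or ClassifierConfig()
    if fit is None:
        fit = profile.meta.get("_fit", profile.ratio)
    pos = profile.positions_um
    start = int(np.searchsorted(pos, natal.end_um, side="right"))
    end_um = pos[-1]
    if len(profile.annuli_um):
        end_um = min(end_um, profile.annuli_um[0])
    if entry_position_um is not None:
        end_um = min(end_um, entry_position_um)
    stop = int(np.searchsorted(pos, end_um, side="left"))
    if stop - start < cfg.min_state_run:
        return None
    return _region_from_slice(profile, fit, start, stop, "juvenile")


def regions_distinct(a: Region, b: Region,
                     cfg: ClassifierConfig | None = None) -> bool:
    """Strictly-greater-than test on the region mean difference."""
    cfg = cfg or ClassifierConfig()
    return abs(a.mean_ratio - b.mean_ratio) > cfg.distinct_delta


# ---------------------------------------------------------------------------
# marine entry and the decision tree
# ---------------------------------------------------------------------------

def marine_entry(profile, smoothed, cfg: ClassifierConfig | None = None,
                 ) -> tuple[int | None, float | None]:
    """First sustained marine residence: (floored age, position µm) or None.

    Requires ``min_state_run`` consecutive readings with v88 above the
    marine threshold and the fitted ratio within the GMV band.
    """
    cfg = cfg or ClassifierConfig()
    fit = smoothed.fit
    qual = (profile.v88 > cfg.marine_threshold) \
        & np.isfinite(fit) & (np.abs(fit - cfg.gmv) <= cfg.gmv_tol)
    n = len(qual)
    i = 0
    while i < n:
        if qual[i]:
            j = i
            while j < n and qual[j]:
                j += 1
            if j - i >= cfg.min_state_run:
                return (int(math.floor(profile.age[i])),
                        float(profile.positions_um[i]))
            i = j
        else:
            i += 1
    return None, None


def age_at_marine_entry(profile, smoothed,
                        cfg: ClassifierConfig | None = None) -> int | None:
    """Floored age at the first sustained marine residence, or None."""
    return marine_entry(profile, smoothed, cfg)[0]


def classify_life_history(profile, smoothed, natal: Region,
                          juvenile: Region | None, entry_age: int | None,
                          cfg: ClassifierConfig | None = None,
                          entry_position_um: float | None = None,
                          ) -> LifeHistoryCall:
    """Apply the six-type decision tree to one otolith's evidence."""
    cfg = cfg or ClassifierConfig()
    n = len(profile)
    runs = merged_state_runs(profile.v88, cfg)
    states = _expand_runs(runs, n)
    natal_start = int(np.searchsorted(profile.positions_um, natal.start_um))
    age0_end = int(np.searchsorted(profile.age, 1.0))

    if abs(natal.mean_ratio - cfg.gmv) <= cfg.gmv_tol:
        type_id = 4
    elif entry_age is not None:
        if entry_age < 1:
            type_id = 1
        else:
            age0 = states[natal_start:age0_end]
            n_est = int(np.sum(age0 == "estuarine"))
            type_id = 3 if n_est >= cfg.min_state_run else 2
    else:
        non_fresh = any(s != "freshwater" for _, _, s in runs)
        type_id = 5 if non_fresh else 6

    if type_id in (5, 6):
        entry_age = None
    habitat_states = [(float(profile.age[s]),
                       float(profile.age[e - 1]), state)
                      for s, e, state in runs]
    return LifeHistoryCall(
        otolith_id=profile.otolith_id, type_id=type_id, entry_age=entry_age,
        natal=natal, juvenile=juvenile, habitat_states=habitat_states,
        truth_label=profile.meta.get("truth_label"))


def classify_otolith(profile, smoothed,
                     cfg: ClassifierConfig | None = None) -> LifeHistoryCall:
    """Full per-otolith call: regions, entry age, then the decision tree.

    Failures (e.g. no stable natal window) yield an ``undetermined`` call
    rather than raising, so one bad otolith never aborts a cohort.
    """
    cfg = cfg or ClassifierConfig()
    try:
        natal = detect_natal_region(profile, smoothed, cfg)
        entry_age, entry_pos = marine_entry(profile, smoothed, cfg)
        juvenile = detect_juvenile_region(profile, natal, entry_pos, cfg,
                                          fit=smoothed.fit)
        return classify_life_history(profile, smoothed, natal, juvenile,
                                     entry_age, cfg,
                                     entry_position_um=entry_pos)
    except ValidationError as err:
        log.warning("%s: undetermined (%s)", profile.otolith_id, err)
        return LifeHistoryCall(
            otolith_id=profile.otolith_id, type_id=None, entry_age=None,
            natal=None, juvenile=None, status="undetermined",
            reason=str(err), truth_label=profile.meta.get("truth_label"))
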