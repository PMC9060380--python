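"""Reduction of raw LA-MC-ICP-MS beam voltages to corrected ⁸⁷Sr/⁸⁶Sr.

The chain is order-fixed:

1. gas-blank subtraction (per-mass means over the 30 s laser warm-up),
2. Ca-dimer (CaCa⁺) / Ca-argide (CaAr⁺) interference stripping anchored on
   the interference-only channels m/z 82 and 83,
3. ⁸⁷Rb peak stripping off m/z 87 via the monitor mass 85, assuming Rb
   fractionates like Sr,
4. instrumental isotopic fractionation (IIF) correction by standard/sample
   bracketing against SRM 987.

All operations take and return :class:`RawAblationRun` (or plain ratio
series) and never mutate their input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import constants as C

log = logging.getLogger(__name__)

RUN_COLUMNS = ["time_s", "phase"] + [f"v{m}" for m in C.CHANNELS]
PHASES = ("blank", "ablation")


class ValidationError(ValueError):
    """Raised when an input table or parameter violates its contract."""


@dataclass(frozen=True)
class RawAblationRun:
    """One ablation acquisition: a blank phase followed by ablation readings.

    ``data`` holds columns ``time_s``, ``phase`` (``blank``/``ablation``) and
    the beam voltages ``v82`` … ``v88``.
    """

    data: pd.DataFrame
    cadence_s: float = 0.5
    scan_speed: float = C.SCAN_SPEED_UM_S
    spot_um: float = C.SPOT_UM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RUN_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"run table missing column(s): {missing}")
        bad = set(self.data["phase"].unique()) - set(PHASES)
        if bad:
            raise ValidationError(f"unknown phase label(s): {sorted(bad)}")
        t = self.data["time_s"].to_numpy(float)
        if len(t) and np.any(np.diff(t) <= 0):
            i = int(np.argmax(np.diff(t) <= 0)) + 1
            raise ValidationError(f"time_s not strictly increasing at row {i}")
        v = self.data[[f"v{m}" for m in C.CHANNELS]].to_numpy(float)
        if not np.all(np.isfinite(v)):
            raise ValidationError("non-finite voltage in run table")
        if self.cadence_s <= 0:
            raise ValidationError("cadence_s must be positive")

    @property
    def blank(self) -> pd.DataFrame:
        return self.data[self.data["phase"] == "blank"]

    @property
    def ablation(self) -> pd.DataFrame:
        return self.data[self.data["phase"] == "ablation"]

    def distances_um(self) -> np.ndarray:
        """Distance along the transect for ablation readings (µm).

        Distance is elapsed ablation time × scan speed, zero at the first
        instant of ablation.
        """
        abl = self.ablation
        if abl.empty:
            return np.empty(0)
        t = abl["time_s"].to_numpy(float)
        return (t - t[0]) * self.scan_speed


@dataclass(frozen=True)
class StandardAcquisition:
    """A bracketing SRM 987 measurement on the run clock."""

    time_s: float
    measured_ratio: float
    certified_ratio: float = C.SRM987_RATIO

    def __post_init__(self) -> None:
        if self.measured_ratio <= 0 or self.certified_ratio <= 0:
            raise ValidationError("standard ratios must be positive")


def _normalized(table: dict[int, float], name: str) -> dict[int, float]:
    total = sum(table.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"{name} abundances sum to {total}, expected 1")
    return dict(table)


@dataclass(frozen=True)
class ReductionConfig:
    """Tables and anchors used by the reduction chain."""

    rb_abundance_ratio: float = C.RB_87_85
    ca_abundances: dict = field(default_factory=lambda: dict(C.CA_ABUNDANCE))
    ar_abundances: dict = field(default_factory=lambda: dict(C.AR_ABUNDANCE))
    atomic_masses: dict = field(default_factory=lambda: dict(C.ATOMIC_MASS))
    srm987_certified: float = C.SRM987_RATIO
    febs1_sr: float = C.FEBS1_SR_MGKG
    #: readings in the rolling window for dimer/argide amplitude estimation
    #: (1 = literal per-reading solve; the 2×2 system is near-degenerate, so
    #: a wide window is the default).
    ca_smooth_window: int = 101
    #: ratio gated where v86 < gate × SD of the v86 blank.
    v86_gate_blank_sd: float = 10.0

    def __post_init__(self) -> None:
        _normalized(self.ca_abundances, "Ca")
        _normalized(self.ar_abundances, "Ar")
        if self.febs1_sr <= 0:
            raise ValidationError("febs1_sr must be positive")
        d, a = self.interference_matrix()
        det = d[82] * a[83] - d[83] * a[82]
        if det == 0:
            raise ValidationError("degenerate dimer/argide abundance system")

    def interference_matrix(self) -> tuple[dict[int, float], dict[int, float]]:
        """Dimer and argide patterns normalized to m/z 82 and 83 resp."""
        dimer: dict[int, float] = {}
        iso = sorted(self.ca_abundances)
        for i, x in enumerate(iso):
            for y in iso[i:]:
                p = self.ca_abundances[x] * self.ca_abundances[y]
                if x != y:
                    p *= 2.0
                dimer[x + y] = dimer.get(x + y, 0.0) + p
        argide: dict[int, float] = {}
        for ca, pca in self.ca_abundances.items():
            for ar, par in self.ar_abundances.items():
                argide[ca + ar] = argide.get(ca + ar, 0.0) + pca * par
        if dimer.get(82, 0.0) <= 0 or argide.get(83, 0.0) <= 0:
            raise ValidationError(
                "abundance tables give no dimer signal at m/z 82 or no "
                "argide signal at m/z 83; interference system is degenerate")
        d82, a83 = dimer[82], argide[83]
        d = {m: dimer.get(m, 0.0) / d82 for m in C.CHANNELS}
        a = {m: argide.get(m, 0.0) / a83 for m in C.CHANNELS}
        return d, a


# ---------------------------------------------------------------------------
# 1. gas blank
# ---------------------------------------------------------------------------

def blank_means(run: RawAblationRun,
                window_s: float = C.BLANK_WINDOW_S) -> pd.Series:
    """Per-mass mean gas blank over the warm-up window.

    Only the last ``window_s`` seconds of the blank phase (the laser warm-up
    immediately preceding ablation) enter the mean, even if a longer blank
    was recorded.
    """
    blank = run.blank
    if blank.empty:
        raise ValidationError("run has no blank phase; cannot blank-correct")
    t = blank["time_s"].to_numpy(float)
    span = t[-1] - t[0] + run.cadence_s
    if span < window_s - 1e-9:
        raise ValidationError(
            f"blank phase spans {span:.1f}s, need >= {window_s:.0f}s")
    sel = blank[t > t[-1] - window_s]
    return sel[[f"v{m}" for m in C.CHANNELS]].mean()


def blank_sds(run: RawAblationRun,
              window_s: float = C.BLANK_WINDOW_S) -> pd.Series:
    """Per-mass SD of the gas blank over the warm-up window."""
    blank = run.blank
    t = blank["time_s"].to_numpy(float)
    sel = blank[t > t[-1] - window_s]
    return sel[[f"v{m}" for m in C.CHANNELS]].std(ddof=1).fillna(0.0)


def blank_correct(run: RawAblationRun,
                  window_s: float = C.BLANK_WINDOW_S) -> RawAblationRun:
    """Subtract the per-mass warm-up blank mean from ablation voltages.

    The blank phase is retained (uncorrected) for audit; negative corrected
    voltages are preserved so downstream means stay unbiased.
    """
    means = blank_means(run, window_s)
    data = run.data.copy()
    abl = data["phase"] == "ablation"
    for m in C.CHANNELS:
        data.loc[abl, f"v{m}"] -= means[f"v{m}"]
    meta = dict(run.meta)
    meta["blank_means"] = {m: float(means[f"v{m}"]) for m in C.CHANNELS}
    meta["blank_sds"] = {m: float(v) for m, v in
                         zip(C.CHANNELS, blank_sds(run, window_s))}
    meta["blank_corrected"] = True
    return replace(run, data=data, meta=meta)


# ---------------------------------------------------------------------------
# 2. Ca dimer / argide
# ---------------------------------------------------------------------------

def ca_interference_correct(run: RawAblationRun,
                            cfg: ReductionConfig) -> RawAblationRun:
    """Strip CaCa⁺/CaAr⁺ contributions from m/z 84–88.

    The two interference amplitudes are solved from the blank-corrected
    signals at m/z 82 and 83 (channels free of Sr and Rb), then their
    natural-abundance isotopologue patterns are subtracted at m/z 84–88.
    Because the 2×2 system is nearly degenerate, amplitudes are estimated
    from a centred rolling mean of v82/v83 (``cfg.ca_smooth_window``
    readings; window 1 reproduces the exact per-reading solve). Amplitudes
    are floored at zero.
    """
    d, a = cfg.interference_matrix()
    data = run.data.copy()
    abl = data["phase"] == "ablation"
    v82 = data.loc[abl, "v82"].to_numpy(float)
    v83 = data.loc[abl, "v83"].to_numpy(float)
    w = max(1, int(cfg.ca_smooth_window))
    if w > 1:
        s82 = pd.Series(v82).rolling(w, center=True, min_periods=1).mean().to_numpy()
        s83 = pd.Series(v83).rolling(w, center=True, min_periods=1).mean().to_numpy()
    else:
        s82, s83 = v82, v83
    det = d[82] * a[83] - d[83] * a[82]
    amp_d = (s82 * a[83] - s83 * a[82]) / det
    amp_a = (d[82] * s83 - d[83] * s82) / det
    # floor at zero; if one goes negative, attribute the reference channel
    # entirely to the other species.
    neg_d = amp_d < 0
    neg_a = amp_a < 0
    amp_d = np.where(neg_d, 0.0, amp_d)
    amp_a = np.where(neg_a, 0.0, amp_a)
    amp_a = np.where(neg_d & ~neg_a, s83 / a[83], amp_a)
    amp_d = np.where(neg_a & ~neg_d, s82 / d[82], amp_d)
    for m in (84, 85, 86, 87, 88):
        data.loc[abl, f"v{m}"] -= amp_d * d[m] + amp_a * a[m]
    meta = dict(run.meta)
    meta["ca_amp_dimer_mean"] = float(np.mean(amp_d)) if len(amp_d) else 0.0
    meta["ca_amp_argide_mean"] = float(np.mean(amp_a)) if len(amp_a) else 0.0
    meta["ca_corrected"] = True
    return replace(run, data=data, meta=meta)


# ---------------------------------------------------------------------------
# 3. mass bias (Russell exponential law) and Rb stripping
# ---------------------------------------------------------------------------

def russell_factor(measured_ratio: float, true_ratio: float,
                   mass_num: float, mass_den: float) -> float:
    """Exponential-law fractionation exponent β.

    Defined by ``R_true = R_meas · (m_num/m_den)**β``, i.e.
    ``β = ln(R_true/R_meas) / ln(m_num/m_den)``.
    """
    if measured_ratio <= 0 or true_ratio <= 0:
        raise ValidationError("ratios must be positive")
    if mass_num <= 0 or mass_den <= 0 or mass_num == mass_den:
        raise ValidationError("masses must be positive and distinct")
    return math.log(true_ratio / measured_ratio) / math.log(mass_num / mass_den)


def beta_series(standards: list[StandardAcquisition],
                cfg: ReductionConfig) -> tuple[np.ndarray, np.ndarray]:
    """β estimated per bracketing standard from its Sr ratio, with times."""
    if not standards:
        raise ValidationError("no bracketing standards provided")
    ts = np.array([s.time_s for s in standards], float)
    betas = np.array([
        russell_factor(s.measured_ratio, s.certified_ratio,
                       cfg.atomic_masses[87], cfg.atomic_masses[86])
        for s in standards
    ])
    order = np.argsort(ts)
    return ts[order], betas[order]


def rb_strip(run: RawAblationRun, beta, cfg: ReductionConfig) -> RawAblationRun:
    """Peak-strip the ⁸⁷Rb isobar off m/z 87 using the ⁸⁵Rb monitor.

    ``beta`` may be a scalar or a per-ablation-reading array (β interpolated
    from the bracketing standards). Rb is assumed to fractionate like Sr:
    the measured ⁸⁷Rb/⁸⁵Rb is the natural abundance ratio distorted by the
    same exponential law, so the predicted ⁸⁷Rb voltage is
    ``v85 · (87Rb/85Rb) · (m87Rb/m85Rb)**(−β)``.

    Negative v85 (possible after blank subtraction of a Rb-free run) is
    treated as zero Rb.
    """
    data = run.data.copy()
    abl = data["phase"] == "ablation"
    v85 = data.loc[abl, "v85"].to_numpy(float)
    if np.any(v85 < 0):
        log.warning("negative v85 in %d reading(s); treated as zero Rb",
                    int(np.sum(v85 < 0)))
    v85 = np.clip(v85, 0.0, None)
    beta = np.asarray(beta, float)
    mass_ratio = C.MASS_RB87 / cfg.atomic_masses[85]
    rb87 = v85 * cfg.rb_abundance_ratio * mass_ratio ** (-beta)
    data.loc[abl, "v87"] -= rb87
    meta = dict(run.meta)
    meta["rb87_stripped_mean"] = float(np.mean(rb87)) if len(rb87) else 0.0
    return replace(run, data=data, meta=meta)


# ---------------------------------------------------------------------------
# 4. bracketing IIF correction
# ---------------------------------------------------------------------------

def bracket_iif_correct(sample: list[tuple[float, float]],
                        standards: list[StandardAcquisition],
                        ) -> list[tuple[float, float]]:
    """Correct sample ⁸⁷Sr/⁸⁶Sr by standard/sample bracketing.

    Per reading, the correction factor is certified / (time-linear
    interpolation of the bracketing standards' measured ratios). Readings
    outside the standard time span use the nearest standard (logged).
    """
    if len(standards) < 2:
        raise ValidationError("bracketing needs at least two standards")
    ts = np.array([s.time_s for s in standards], float)
    meas = np.array([s.measured_ratio for s in standards], float)
    if np.any(meas <= 0):
        raise ValidationError("standard measured ratio must be positive")
    certified = standards[0].certified_ratio
    order = np.argsort(ts)
    ts, meas = ts[order], meas[order]
    t = np.array([p[0] for p in sample], float)
    r = np.array([p[1] for p in sample], float)
    if len(t) and (t.min() < ts[0] or t.max() > ts[-1]):
        log.warning("sample readings outside standard bracket span; "
                    "nearest standard used at the edges")
    interp = np.interp(t, ts, meas)
    corrected = r * (certified / interp)
    return list(zip(t.tolist(), corrected.tolist()))


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def ratio_8786(run: RawAblationRun, cfg: ReductionConfig) -> np.ndarray:
    """Raw 87/86 ratio per ablation reading, gated on the v86 blank SD.

    Readings where v86 ≤ ``cfg.v86_gate_blank_sd`` × the v86 blank SD are
    returned as NaN (ratio meaningless at blank level).
    """
    abl = run.ablation
    v86 = abl["v86"].to_numpy(float)
    v87 = abl["v87"].to_numpy(float)
    gate = cfg.v86_gate_blank_sd * run.meta.get("blank_sds", {}).get(86, 0.0)
    out = np.full(len(v86), np.nan)
    ok = v86 > max(gate, 0.0)
    out[ok] = v87[ok] / v86[ok]
    return out


def reduce_run(run: RawAblationRun,
               standards: list[StandardAcquisition],
               cfg: ReductionConfig | None = None) -> RawAblationRun:
    """Apply the full reduction chain: blank → Ca → Rb → bracketing.

    Returns a run whose ablation rows carry two extra columns:
    ``ratio_8786`` (fully corrected ⁸⁷Sr/⁸⁶Sr) and ``v88_corrected``.
    The chain is idempotent on an already-clean run (zero blanks, zero
    interference channels, standards reading certified).
    """
    cfg = cfg or ReductionConfig()
    step = blank_correct(run)
    step = ca_interference_correct(step, cfg)
    ts, betas = beta_series(standards, cfg)
    t_abl = step.ablation["time_s"].to_numpy(float)
    beta_t = np.interp(t_abl, ts, betas)
    step = rb_strip(step, beta_t, cfg)
    raw_ratio = ratio_8786(step, cfg)
    finite = np.isfinite(raw_ratio)
    corrected = np.full_like(raw_ratio, np.nan)
    if finite.any():
        pairs = bracket_iif_correct(
            list(zip(t_abl[finite].tolist(), raw_ratio[finite].tolist())),
            standards)
        corrected[finite] = [p[1] for p in pairs]
    data = step.data.copy()
    abl = data["phase"] == "ablation"
    data.loc[abl, "ratio_8786"] = corrected
    data.loc[abl, "v88_corrected"] = data.loc[abl, "v88"]
    meta = dict(step.meta)
    meta["beta_per_bracket"] = {float(t): float(b) for t, b in zip(ts, betas)}
    meta["reduced"] = True
    return replace(step, data=data, meta=meta)


def reduction_report(run: RawAblationRun) -> dict:
    """JSON-serializable audit of the corrections applied to ``run``."""
    keys = ("blank_means", "blank_sds", "ca_amp_dimer_mean",
            "ca_amp_argide_mean", "rb87_stripped_mean", "beta_per_bracket")
    return {k: run.meta[k] for k in keys if k in run.meta}
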